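"""Feature registry, extraction, triplet profiles and information-gain ranking."""

import numpy as np
import pytest

from mirduplex import (
    HairpinRecord,
    annotate_duplex,
    extract_features,
    feature_registry,
    featurize_interval,
    rank_information_gain,
    triplet_profile,
)
from mirduplex.errors import ContractError, TrainingError
from mirduplex.features import GROUP_COUNTS, information_gain

from helpers import perfect_hairpin


REG = feature_registry()
IDX = {name: i for i, name in enumerate(REG.names)}


# ---------------------------------------------------------------------------
# Registry conformance
# ---------------------------------------------------------------------------

def test_registry_has_100_unique_entries():
    assert len(REG) == 100
    assert len(set(REG.names)) == 100


@pytest.mark.parametrize("group,count", sorted(GROUP_COUNTS.items()))
def test_registry_group_counts(group, count):
    assert len(REG.group(group)) == count


def test_registry_contains_all_published_feature_names():
    """Every feature referenced by name in the reported rankings resolves to
    exactly one registry entry."""
    named = [
        "mean_paired_window_3", "mean_paired_window_5", "mean_paired_window_7",
        "longest_bulge_pct", "longest_bulge_nt", "dist_to_loop", "n_paired",
        "loop_overlap_nt", "duplex_mfe", "pct_gc_pairs", "pct_au_pairs",
        "pct_gu_pairs", "dist_to_hairpin_start", "in_loop",
        "perfect_stem_start_5", "longest_paired_run_nt", "longest_paired_run_pct",
        "gc_content", "length",
    ]
    for name in named:
        assert REG.names.count(name) == 1
    # the four "triplet N" families each have 8 fully-disambiguated patterns
    for nt in "ACGU":
        assert sum(n.startswith(f"triplet_{nt}_") for n in REG.names) == 8


def test_registry_fingerprint_is_stable():
    assert feature_registry().fingerprint() == feature_registry().fingerprint()


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

GC_STEM = "GCGCGCGCGCGCGCGCGCGC"  # 20 nt, GC only
GC_DB = "(" * 20 + "." * 6 + ")" * 20


def _gc_record():
    return HairpinRecord("gc", perfect_hairpin(GC_STEM, loop_len=6), GC_DB)


def test_gc_only_mirna_composition():
    fv = featurize_interval(_gc_record(), 0, 20)
    assert fv[IDX["gc_content"]] == 1.0
    assert fv[IDX["freq_A"]] == 0.0 and fv[IDX["freq_U"]] == 0.0
    assert fv[IDX["freq_G"]] + fv[IDX["freq_C"]] == 1.0


def test_perfect_stem_pairing_features():
    fv = featurize_interval(_gc_record(), 0, 20)
    assert fv[IDX["bulge_count"]] == 0
    assert fv[IDX["longest_bulge_nt"]] == 0
    assert fv[IDX["longest_paired_run_nt"]] == 20
    assert fv[IDX["longest_paired_run_pct"]] == 1.0
    assert fv[IDX["perfect_stem_ge10"]] == 1.0
    assert fv[IDX["perfect_stem_start_10"]] == 0.0
    assert fv[IDX["n_paired"]] == 20
    assert fv[IDX["pct_gc_pairs"]] == 1.0


def test_unpaired_candidate_degenerate_rule():
    """Zero paired positions: pairing and pair-type features are 0; the
    perfect-stem start positions are -1 (no such region)."""
    seq = "A" * 20 + perfect_hairpin(GC_STEM, loop_len=6)
    db = "." * 20 + GC_DB
    fv = featurize_interval(HairpinRecord("u", seq, db), 0, 18)
    assert fv[IDX["n_paired"]] == 0
    for name in ("mean_paired_window_3", "mean_paired_window_5", "mean_paired_window_7",
                 "pct_gc_pairs", "pct_au_pairs", "pct_gu_pairs",
                 "perfect_stem_ge5", "perfect_stem_ge10", "perfect_stem_ge20"):
        assert fv[IDX[name]] == 0.0, name
    for name in ("perfect_stem_start_5", "perfect_stem_start_10", "perfect_stem_start_20"):
        assert fv[IDX[name]] == -1.0, name


def test_extraction_deterministic_bitwise(small_corpus):
    p = small_corpus[0]
    a = featurize_interval(p.hairpin, p.start, p.length)
    b = featurize_interval(p.hairpin, p.start, p.length)
    assert np.array_equal(a, b)


def test_block_normalizations(small_corpus):
    """Mono-, di- and triplet-frequency blocks each sum to 1; first/last
    indicator blocks sum to exactly 1."""
    mono = [IDX[f"freq_{n}"] for n in "ACGU"]
    di = [IDX[f"freq_{a}{b}"] for a in "ACGU" for b in "ACGU"]
    trip = [i for i, d in enumerate(REG.entries) if d.group == "triplet"]
    first = [IDX[f"first_nt_{n}"] for n in "ACGU"]
    last = [IDX[f"last_nt_{n}"] for n in "ACGU"]
    for p in small_corpus[:25]:
        fv = featurize_interval(p.hairpin, p.start, p.length)
        assert abs(fv[mono].sum() - 1) < 1e-9
        assert abs(fv[di].sum() - 1) < 1e-9
        assert abs(fv[trip].sum() - 1) < 1e-9
        assert fv[first].sum() == 1.0 and fv[last].sum() == 1.0


def test_extract_requires_annotation():
    with pytest.raises(ContractError):
        extract_features(_gc_record(), None, None)


# ---------------------------------------------------------------------------
# Triplet profile
# ---------------------------------------------------------------------------

def test_triplet_profile_on_fully_paired_gc_stem():
    """All interior positions are paired with paired neighbors, so only the
    'ppp' patterns keyed by the middle base are populated, at 50% G / 50% C."""
    # miRNA = (GC)*11, 22 nt fully paired
    stem = "GC" * 11
    db = "(" * 22 + "." * 6 + ")" * 22
    rec = HairpinRecord("t", perfect_hairpin(stem, loop_len=6), db)
    cand, _ = annotate_duplex(rec, 0, 22)
    prof = triplet_profile(rec, cand)
    names = [f"triplet_{nt}_{pat}" for nt in "ACGU"
             for pat in ("uuu", "uup", "upu", "upp", "puu", "pup", "ppu", "ppp")]
    nonzero = {names[i]: v for i, v in enumerate(prof) if v > 0}
    assert nonzero == {"triplet_C_ppp": 0.5, "triplet_G_ppp": 0.5}


def test_triplet_profile_sums_to_one(small_corpus):
    for p in small_corpus[:10]:
        cand, _ = annotate_duplex(p.hairpin, p.start, p.length)
        assert abs(triplet_profile(p.hairpin, cand).sum() - 1) < 1e-9


def test_paired_base_with_unpaired_neighbors_counted():
    """A paired U flanked by two unpaired positions produces the 'upu'
    pattern keyed by U (hand-counted on a 20-mer with alternating pairing)."""
    #        position:  0123456789...
    seq = "GUAAGAUAGAAAAAAAAUCUAUCUAU"[:26]
    #      miRNA 0..8: pairing at odd positions only (hand-built)
    db = ".(.(.(.(.........).).).).."
    assert len(seq) == 26 and len(db) == 26
    rec = HairpinRecord("h", seq, db)
    cand, _ = annotate_duplex(rec, 0, 9)
    prof = triplet_profile(rec, cand)
    # interior positions 1..7: odd ones are paired with unpaired neighbors;
    # position 1 carries a U, giving exactly one 'upu' pattern keyed by U
    i_u_upu = REG.names.index("triplet_U_upu") - REG.names.index("triplet_A_uuu")
    assert prof[i_u_upu] == pytest.approx(1 / 7)


# ---------------------------------------------------------------------------
# Information gain
# ---------------------------------------------------------------------------

def _matrix_with_column(col, n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 100))
    X[:, 0] = col
    return X


def test_ig_of_label_equals_class_entropy():
    y = np.array([0, 1] * 100)
    X = _matrix_with_column(y.astype(float))
    df = rank_information_gain(X, y)
    row = df[df["name"] == REG.names[0]].iloc[0]
    assert abs(row["score"] - 1.0) < 1e-9  # H(class) = 1 bit, balanced
    assert row["rank"] == 1


def test_ig_of_constant_feature_is_zero():
    y = np.array([0, 1] * 100)
    X = _matrix_with_column(np.zeros(200))
    assert information_gain(X[:, 0], y) == 0.0


def test_ig_rejects_single_class():
    X = np.zeros((10, 100))
    with pytest.raises(TrainingError):
        rank_information_gain(X, np.ones(10))


def test_duplex_features_outrank_base_composition_on_planted_signal(small_training):
    """On planted-duplex data the discriminative signal is structural, so the
    best pairing-group feature must outrank every mononucleotide frequency."""
    X, y = small_training
    df = rank_information_gain(X, y)
    rank = dict(zip(df["name"], df["rank"]))
    best_pairing = min(rank[d.name] for d in REG.group("pairing"))
    worst_needed = min(rank[f"freq_{n}"] for n in "ACGU")
    assert best_pairing < worst_needed


def test_ranks_are_a_permutation():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(120, 100))
    y = np.array([0, 1] * 60)
    df = rank_information_gain(X, y)
    assert sorted(df["rank"]) == list(range(1, 101))
    assert (df["score"] >= 0).all()
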