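"""Training-set construction: loading, clade filtering, negatives, simulation."""

import numpy as np
import pytest

from mirduplex import (
    SyntheticSpec,
    build_examples,
    derive_star,
    filter_clade,
    load_pairs,
    make_negatives,
    parse_dot_bracket,
    simulate_hairpins,
)
from mirduplex.datasets import admissible_negative_starts
from mirduplex.errors import ContractError, InputError
from mirduplex.io import read_fasta, write_fasta, write_vienna, read_vienna


# ---------------------------------------------------------------------------
# load_pairs
# ---------------------------------------------------------------------------

HAIRPIN = ("cel-mir-1", "ACGGUAGCUUAUCAGACUGAAAACCCACAACACCAGUCGAUGGGCUG" + "AUAUGCAUGC")


def test_load_both_arms_of_one_hairpin():
    matures = [
        ("cel-miR-1-5p", HAIRPIN[1][0:20]),
        ("cel-miR-1-3p", HAIRPIN[1][27:47]),
    ]
    result = load_pairs([HAIRPIN], matures)
    assert len(result.pairs) == 2
    starts = sorted((p.start, p.length) for p in result.pairs)
    assert starts == [(0, 20), (27, 20)]
    assert all(p.species == "cel" for p in result.pairs)


def test_mature_absent_from_hairpin_is_skipped_and_counted():
    result = load_pairs([HAIRPIN], [("cel-miR-1-5p", "AAACCCGGGUUUAAACCCGG")])
    assert len(result.pairs) == 0
    assert result.n_unmatched == 1


def test_no_id_overlap_is_an_input_error():
    with pytest.raises(InputError):
        load_pairs([HAIRPIN], [("hsa-miR-9-5p", "ACGUACGUACGUACGUACGU")])


def test_fasta_round_trip_recovers_planted_intervals(tmp_path):
    pairs = simulate_hairpins(SyntheticSpec(n=10, seed=4, mismatch_rate=0.0))
    hp_path, mat_path = tmp_path / "hairpin.fa", tmp_path / "mature.fa"
    write_fasta(hp_path, [(p.hairpin.id, p.hairpin.seq) for p in pairs])
    write_fasta(mat_path, [(f"{p.hairpin.id}-5p", p.mirna_seq) for p in pairs])
    result = load_pairs(read_fasta(hp_path), read_fasta(mat_path))
    recovered = {(p.hairpin.id, p.start, p.length) for p in result.pairs}
    planted = {(p.hairpin.id, p.start, p.length) for p in pairs}
    assert recovered == planted


def test_vienna_round_trip_preserves_structure_and_energy(tmp_path):
    pairs = simulate_hairpins(SyntheticSpec(n=3, seed=4))
    recs = [p.hairpin for p in pairs]
    path = tmp_path / "hp.vienna"
    write_vienna(path, recs)
    back = read_vienna(path)
    assert [(r.id, r.seq, r.structure) for r in back] == \
           [(r.id, r.seq, r.structure) for r in recs]


# ---------------------------------------------------------------------------
# filter_clade
# ---------------------------------------------------------------------------

SPECIES_TABLE = {
    "bta": "Metazoa;Vertebrata;Mammalia;Ruminantia",
    "oar": "Metazoa;Vertebrata;Mammalia;Ruminantia",
    "hsa": "Metazoa;Vertebrata;Mammalia;Primates",
    "ath": "Viridiplantae;Embryophyta",
}


def _pairs_for(codes):
    out = []
    for i, code in enumerate(codes):
        hp = (f"{code}-mir-{i}", HAIRPIN[1])
        out += load_pairs([hp], [(f"{code}-miR-{i}-5p", HAIRPIN[1][:20])]).pairs
    return out


def test_clade_filter_matches_hand_partition():
    pairs = _pairs_for(["bta", "oar", "hsa", "ath"])
    assert len(filter_clade(pairs, SPECIES_TABLE, "Ruminantia")) == 2
    assert len(filter_clade(pairs, SPECIES_TABLE, "mammalia")) == 3  # case-insensitive
    assert len(filter_clade(pairs, SPECIES_TABLE, "Viridiplantae")) == 1


def test_clade_matching_all_is_identity():
    pairs = _pairs_for(["bta", "hsa"])
    assert filter_clade(pairs, SPECIES_TABLE, "Metazoa") == pairs


def test_unknown_clade_gives_empty_set_not_error():
    pairs = _pairs_for(["bta"])
    assert filter_clade(pairs, SPECIES_TABLE, "Fungi") == []


# ---------------------------------------------------------------------------
# make_negatives
# ---------------------------------------------------------------------------

def test_admissible_starts_exclude_annotated_position():
    starts = admissible_negative_starts(100, 22, [10])
    assert set(starts) == set(range(79)) - {10}


def test_negatives_avoid_annotated_starts_and_preserve_length():
    pairs = simulate_hairpins(SyntheticSpec(n=50, seed=9))
    negatives = make_negatives(pairs, seed=9)
    assert len(negatives) == len(pairs)
    truth = {p.hairpin.id: (p.start, p.length) for p in pairs}
    for neg in negatives:
        t_start, t_len = truth[neg.hairpin.id]
        assert neg.start != t_start
        assert neg.length == t_len
        assert neg.start + neg.length <= len(neg.hairpin)


def test_negatives_deterministic_for_seed():
    pairs = simulate_hairpins(SyntheticSpec(n=20, seed=9))
    a = make_negatives(pairs, seed=123)
    b = make_negatives(pairs, seed=123)
    c = make_negatives(pairs, seed=124)
    assert [(n.hairpin.id, n.start) for n in a] == [(n.hairpin.id, n.start) for n in b]
    assert [(n.hairpin.id, n.start) for n in a] != [(n.hairpin.id, n.start) for n in c]


def test_exclude_overlap_mode_forbids_any_overlap():
    pairs = simulate_hairpins(SyntheticSpec(n=30, seed=5))
    truth = {p.hairpin.id: (p.start, p.length) for p in pairs}
    for neg in make_negatives(pairs, seed=5, exclude_overlap=True):
        t_start, t_len = truth[neg.hairpin.id]
        assert neg.start + neg.length <= t_start or neg.start >= t_start + t_len


def test_balanced_examples():
    pairs = simulate_hairpins(SyntheticSpec(n=25, seed=2))
    examples = build_examples(pairs, seed=2)
    labels = [e.label for e in examples]
    assert labels.count(1) == labels.count(0) == 25


# ---------------------------------------------------------------------------
# simulate_hairpins
# ---------------------------------------------------------------------------

def test_clean_generator_plants_fully_paired_duplex():
    for p in simulate_hairpins(SyntheticSpec(n=20, seed=6, mismatch_rate=0.0, bulge_rate=0.0)):
        db = p.hairpin.structure
        planted = db[p.start:p.start + p.length]
        assert planted == "(" * p.length


def test_generator_bitwise_stable(tmp_path):
    a = simulate_hairpins(SyntheticSpec(n=200, seed=42))
    b = simulate_hairpins(SyntheticSpec(n=200, seed=42))
    assert [(p.hairpin.seq, p.hairpin.structure) for p in a] == \
           [(p.hairpin.seq, p.hairpin.structure) for p in b]
    pa, pb = tmp_path / "a.fa", tmp_path / "b.fa"
    write_vienna(pa, [p.hairpin for p in a])
    write_vienna(pb, [p.hairpin for p in b])
    assert pa.read_bytes() == pb.read_bytes()


def test_mismatch_rate_matches_binomial_law():
    """At rate 0.1 the mean unpaired fraction of planted miRNAs is within
    3 standard errors of 0.1 (binomial sampling)."""
    rate, n = 0.1, 500
    pairs = simulate_hairpins(SyntheticSpec(n=n, seed=13, mismatch_rate=rate))
    fracs, total_nt = [], 0
    for p in pairs:
        db = p.hairpin.structure[p.start:p.start + p.length]
        fracs.append(db.count(".") / len(db))
        total_nt += len(db)
    se = np.sqrt(rate * (1 - rate) / total_nt)
    assert abs(np.mean(fracs) - rate) < 3 * se + 0.005


def test_generator_truth_recovered_by_star_derivation():
    """With no mismatches, deriving the star from the emitted structure
    recovers the planted star interval up to the 2-nt 3' shift."""
    for p in simulate_hairpins(SyntheticSpec(n=30, seed=8, mismatch_rate=0.0, bulge_rate=0.0)):
        pt = parse_dot_bracket(p.hairpin.structure)
        star_start, star_length = derive_star(pt, p.start, p.length)
        db = p.hairpin.structure
        planted_star_start = db.index(")")
        planted_star_len = db.count(")")
        assert star_start == planted_star_start
        assert abs(star_length - planted_star_len) <= 2


def test_rates_outside_unit_interval_rejected():
    with pytest.raises(ContractError):
        SyntheticSpec(n=5, seed=1, mismatch_rate=1.5)
    with pytest.raises(ContractError):
        SyntheticSpec(n=5, seed=1, bulge_rate=-0.1)


def test_full_corpus_is_featurizable(small_corpus, small_training):
    """Every labeled example extracts to 100 finite values."""
    X, y = small_training
    assert X.shape == (2 * len(small_corpus), 100)
    assert np.all(np.isfinite(X))
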