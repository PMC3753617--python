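"""Labeled training sets: real (miRBase layout) and synthetic.

Positive examples are annotated mature miRNAs located inside their hairpin.
Negative examples are produced by relocating each miRNA uniformly at random
along the same hairpin, preserving its length but excluding the start
positions of all annotated miRNAs on that hairpin (an ``exclude_overlap``
switch offers the stricter rule that also forbids any overlap).

The synthetic generator plants an explicit miRNA:miRNA* duplex into each
hairpin — 5' flank + miRNA + loop + star + 3' flank, where the star is the
reverse complement of the miRNA with per-position mismatches and occasional
unpaired insertions — and emits the intended dot-bracket structure alongside,
so downstream tests do not depend on any folding backend.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import ContractError, InputError
from .structures import HairpinRecord, normalize_rna

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class PositivePair:
    """An annotated mature miRNA and its hairpin (0-based half-open interval)."""

    hairpin: HairpinRecord
    start: int
    length: int
    species: str = ""
    clades: tuple[str, ...] = ()

    def __post_init__(self):
        if not (0 <= self.start and self.start + self.length <= len(self.hairpin)):
            raise ContractError("miRNA interval outside hairpin")

    @property
    def mirna_seq(self) -> str:
        return self.hairpin.seq[self.start:self.start + self.length]


@dataclass(frozen=True)
class LabeledExample:
    """One (candidate interval, label) pair for classifier training."""

    hairpin: HairpinRecord
    start: int
    length: int
    label: int  # 1 positive, 0 negative
    origin: str  # "annotation" | "relocation"


@dataclass(frozen=True)
class LoadResult:
    pairs: tuple[PositivePair, ...]
    n_unmatched: int = 0
    n_multihit: int = 0


def _mature_key(mature_id: str) -> str:
    """Normalize a mature ID to its hairpin's ID under miRBase conventions:
    lowercase, strip a trailing -5p/-3p or ``*``."""
    key = mature_id.strip().lower().rstrip("*")
    for suffix in ("-5p", "-3p"):
        if key.endswith(suffix):
            key = key[: -len(suffix)]
    return key


def load_pairs(
    hairpins: Sequence[tuple[str, str]],
    matures: Sequence[tuple[str, str]],
) -> LoadResult:
    """Pair mature miRNAs with their hairpins by ID prefix and substring match.

    ``hairpins`` and ``matures`` are (id, sequence) lists as read from
    miRBase-layout ``hairpin.fa`` / ``mature.fa``.  Each mature is located in
    its hairpin by exact substring match; with multiple occurrences the
    5'-most hit is used and counted in ``n_multihit``; matures whose sequence
    is absent are skipped and counted in ``n_unmatched``.
    """
    by_key: dict[str, HairpinRecord] = {}
    for hid, hseq in hairpins:
        by_key[hid.strip().lower()] = HairpinRecord(hid.strip(), hseq, source="mirbase")
    pairs: list[PositivePair] = []
    n_unmatched = n_multihit = 0
    matched_any = False
    seen: set[tuple[str, int, int]] = set()
    for mid, mseq in matures:
        key = _mature_key(mid)
        hp = by_key.get(key)
        if hp is None:
            continue
        matched_any = True
        m = normalize_rna(mseq)
        pos = hp.seq.find(m)
        if pos < 0:
            n_unmatched += 1
            logger.warning("mature %s not found in hairpin %s", mid, hp.id)
            continue
        if hp.seq.find(m, pos + 1) >= 0:
            n_multihit += 1
            logger.warning("mature %s occurs multiple times in %s; using 5'-most", mid, hp.id)
        dedup = (hp.id, pos, len(m))
        if dedup in seen:
            continue
        seen.add(dedup)
        species = hp.id.split("-")[0].lower()
        pairs.append(PositivePair(hp, pos, len(m), species=species))
    if not matched_any:
        raise InputError("no mature ID matches any hairpin ID")
    return LoadResult(tuple(pairs), n_unmatched, n_multihit)


def load_organisms(path) -> dict[str, str]:
    """Read a miRBase-style organisms table (TSV: code, name, lineage)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 3:
                table[parts[0].strip().lower()] = parts[-1].strip()
    if not table:
        raise InputError(f"no organisms parsed from {path}")
    return table


def filter_clade(
    pairs: Iterable[PositivePair],
    species_table: dict[str, str],
    clade_name: str,
) -> list[PositivePair]:
    """Keep pairs whose species lineage contains ``clade_name`` (case-insensitive)."""
    needle = clade_name.strip().lower()
    out = []
    for p in pairs:
        lineage = species_table.get(p.species.lower(), "").lower()
        if needle in (tok.strip() for tok in lineage.replace(";", ",").split(",")):
            out.append(p)
    if not out:
        logger.warning("clade %r matches no species; empty training set", clade_name)
    return out


# ---------------------------------------------------------------------------
# Negatives by random relocation
# ---------------------------------------------------------------------------

def admissible_negative_starts(
    hairpin_length: int,
    mirna_length: int,
    annotated_starts: Sequence[int],
    annotated_intervals: Optional[Sequence[tuple[int, int]]] = None,
    exclude_overlap: bool = False,
) -> np.ndarray:
    """All starts where a relocated decoy of the same length may be placed."""
    starts = np.arange(0, hairpin_length - mirna_length + 1)
    keep = ~np.isin(starts, np.asarray(annotated_starts, dtype=int))
    if exclude_overlap and annotated_intervals:
        for a, alen in annotated_intervals:
            overlap = (starts < a + alen) & (starts + mirna_length > a)
            keep &= ~overlap
    return starts[keep]


def make_negatives(
    pairs: Sequence[PositivePair],
    seed: int,
    exclude_overlap: bool = False,
) -> list[LabeledExample]:
    """One length-matched relocated decoy per positive, reproducible by seed.

    Per-pair RNG substreams are derived from (seed, pair index) so results do
    not depend on iteration order or parallelism.
    """
    by_hairpin: dict[str, list[PositivePair]] = {}
    for p in pairs:
        by_hairpin.setdefault(p.hairpin.id, []).append(p)
    negatives: list[LabeledExample] = []
    for idx, p in enumerate(pairs):
        siblings = by_hairpin[p.hairpin.id]
        admissible = admissible_negative_starts(
            len(p.hairpin), p.length,
            [s.start for s in siblings],
            [(s.start, s.length) for s in siblings],
            exclude_overlap=exclude_overlap,
        )
        if len(admissible) == 0:
            logger.warning("no admissible decoy start on %s; pair skipped", p.hairpin.id)
            continue
        rng = np.random.default_rng([seed, idx])
        start = int(rng.choice(admissible))
        negatives.append(LabeledExample(p.hairpin, start, p.length, 0, "relocation"))
    return negatives


def build_examples(
    pairs: Sequence[PositivePair],
    seed: int,
    exclude_overlap: bool = False,
) -> list[LabeledExample]:
    """Balanced labeled set: every positive plus one relocated negative each."""
    pos = [LabeledExample(p.hairpin, p.start, p.length, 1, "annotation") for p in pairs]
    return pos + make_negatives(pairs, seed, exclude_overlap=exclude_overlap)


# ---------------------------------------------------------------------------
# Synthetic hairpins with a planted duplex
# ---------------------------------------------------------------------------

#: animal-like mature length law over 19-24 nt with its mode at 22
DEFAULT_LENGTH_LAW = {19: 0.05, 20: 0.12, 21: 0.20, 22: 0.35, 23: 0.18, 24: 0.10}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-duplex hairpin generator.

    Defaults emulate an animal pre-miRNA: a 19-24 nt miRNA (mode 22 nt) on
    the 5' arm, a terminal loop of 8-15 nt, unstructured flanks of 5-20 nt,
    a star strand with 10% mismatches and 5% unpaired insertions, and
    balanced GC content.
    """

    n: int
    seed: int
    length_law: tuple[tuple[int, float], ...] = tuple(sorted(DEFAULT_LENGTH_LAW.items()))
    loop_range: tuple[int, int] = (8, 15)
    flank_range: tuple[int, int] = (5, 20)
    mismatch_rate: float = 0.10
    bulge_rate: float = 0.05
    gc_bias: float = 0.50

    def __post_init__(self):
        for name in ("mismatch_rate", "bulge_rate", "gc_bias"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ContractError(f"{name}={r} outside [0, 1]")
        if self.n < 1:
            raise ContractError("n must be positive")
        probs = [p for _, p in self.length_law]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ContractError("length law probabilities must sum to 1")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G U
    return "".join(np.array(list("ACGU"))[rng.choice(4, size=n, p=p)]) if n else ""


def simulate_hairpins(spec: SyntheticSpec) -> list[PositivePair]:
    """Generate hairpins with a planted miRNA:miRNA* duplex and known truth.

    Each hairpin is 5'flank + miRNA + loop + star + 3'flank.  The star is the
    reverse complement of the miRNA; at each position a mismatch is planted
    with probability ``mismatch_rate`` (both strands unpaired there), and
    after each star base an extra unpaired base is inserted with probability
    ``bulge_rate``.  The intended dot-bracket structure is emitted with the
    record, and the planted miRNA interval is recorded as truth.
    """
    lengths = np.array([l for l, _ in spec.length_law])
    probs = np.array([p for _, p in spec.length_law])
    out: list[PositivePair] = []
    for i in range(spec.n):
        rng = np.random.default_rng([spec.seed, i])
        l = int(rng.choice(lengths, p=probs))
        mirna = _random_bases(rng, l, spec.gc_bias)
        loop_len = int(rng.integers(spec.loop_range[0], spec.loop_range[1] + 1))
        f5 = int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1))
        f3 = int(rng.integers(spec.flank_range[0], spec.flank_range[1] + 1))

        paired = rng.random(l) >= spec.mismatch_rate
        star_chars: list[str] = []
        star_db: list[str] = []
        # build star 5'->3': complements of miRNA positions in reverse order
        for j in range(l - 1, -1, -1):
            if paired[j]:
                star_chars.append(COMPLEMENT[mirna[j]])
                star_db.append(")")
            else:
                # mismatch: any base other than the complement
                choices = [b for b in "ACGU" if b != COMPLEMENT[mirna[j]]]
                star_chars.append(choices[int(rng.integers(3))])
                star_db.append(".")
            if rng.random() < spec.bulge_rate:
                star_chars.append(_random_bases(rng, 1, spec.gc_bias))
                star_db.append(".")

        seq = (
            _random_bases(rng, f5, spec.gc_bias)
            + mirna
            + _random_bases(rng, loop_len, spec.gc_bias)
            + "".join(star_chars)
            + _random_bases(rng, f3, spec.gc_bias)
        )
        db = (
            "." * f5
            + "".join("(" if paired[j] else "." for j in range(l))
            + "." * loop_len
            + "".join(star_db)
            + "." * f3
        )
        record = HairpinRecord(f"syn-{spec.seed}-{i:05d}", seq, db, source="synthetic")
        out.append(PositivePair(record, f5, l, species="syn", clades=("synthetic",)))
    return out
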