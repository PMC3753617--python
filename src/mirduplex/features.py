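"""The 100-feature descriptor of a candidate miRNA:miRNA* duplex.

Each candidate (start, length) on a hairpin is summarized by a fixed, ordered
registry of 100 numeric features in seven groups:

==========  =====  ==================================================
group       count  content
==========  =====  ==================================================
sequence       30  4 mononucleotide + 16 dinucleotide frequencies,
                   GC content, 4 first-nt + 4 last-nt indicators, length
triplet        32  sequence/structure triplets: middle nucleotide x
                   8 pairing patterns of (left, middle, right)
bulge          19  unpaired-position indicators at offsets -3..+3
                   around the miRNA start and end, bulge count, longest
                   bulge (nt and % of length), longest bulge-free run
                   (nt and %)
pairing        10  paired-base count, mean paired fraction in sliding
                   windows of 3/5/7, presence and start of perfect
                   stems of >=5/10/20 consecutive pairs
pairtype        3  % of GC, AU and GU pairs among paired positions
positional      5  distance to terminal loop, distance to hairpin
                   start, loop overlap (nt and %), included-in-loop
energy          1  duplex MFE (or the builtin surrogate)
==========  =====  ==================================================

Degenerate rule: a candidate with zero paired positions gets 0 for all
pairing and pair-type features and -1 for the perfect-stem start positions
(-1 conventionally means "no such region").
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, TrainingError
from .structures import (
    DuplexAnnotation,
    HairpinRecord,
    LoopRegion,
    MirnaCandidate,
    NoLoopError,
    PairTable,
    annotate_duplex,
    hairpin_loops,
    locate_terminal_loop,
    parse_dot_bracket,
)

NUCLEOTIDES = "ACGU"
_NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

#: the 8 pairing patterns of (left, middle, right); u = unpaired, p = paired
TRIPLET_PATTERNS = ["uuu", "uup", "upu", "upp", "puu", "pup", "ppu", "ppp"]

GROUP_COUNTS = {
    "sequence": 30,
    "triplet": 32,
    "bulge": 19,
    "pairing": 10,
    "pairtype": 3,
    "positional": 5,
    "energy": 1,
}


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    group: str


@dataclass(frozen=True)
class FeatureRegistry:
    entries: tuple[FeatureDescriptor, ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def group(self, group: str) -> list[FeatureDescriptor]:
        return [e for e in self.entries if e.group == group]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def fingerprint(self) -> str:
        h = hashlib.sha256("\n".join(self.names).encode()).hexdigest()
        return h[:16]


_REGISTRY: Optional[FeatureRegistry] = None


def feature_registry() -> FeatureRegistry:
    """The pinned, ordered registry of all 100 features."""
    global _REGISTRY
    if _REGISTRY is not None:
        return _REGISTRY
    e: list[FeatureDescriptor] = []

    def add(name, group):
        e.append(FeatureDescriptor(name, group))

    # --- sequence (30)
    for nt in NUCLEOTIDES:
        add(f"freq_{nt}", "sequence")
    for a in NUCLEOTIDES:
        for b in NUCLEOTIDES:
            add(f"freq_{a}{b}", "sequence")
    add("gc_content", "sequence")
    for nt in NUCLEOTIDES:
        add(f"first_nt_{nt}", "sequence")
    for nt in NUCLEOTIDES:
        add(f"last_nt_{nt}", "sequence")
    add("length", "sequence")

    # --- triplet (32)
    for nt in NUCLEOTIDES:
        for pat in TRIPLET_PATTERNS:
            add(f"triplet_{nt}_{pat}", "triplet")

    # --- bulge (19)
    for off in range(-3, 4):
        add(f"bulge_at_start_{off:+d}", "bulge")
    for off in range(-3, 4):
        add(f"bulge_at_end_{off:+d}", "bulge")
    add("bulge_count", "bulge")
    add("longest_bulge_nt", "bulge")
    add("longest_bulge_pct", "bulge")
    add("longest_paired_run_nt", "bulge")
    add("longest_paired_run_pct", "bulge")

    # --- pairing (10)
    add("n_paired", "pairing")
    for w in (3, 5, 7):
        add(f"mean_paired_window_{w}", "pairing")
    for k in (5, 10, 20):
        add(f"perfect_stem_ge{k}", "pairing")
    for k in (5, 10, 20):
        add(f"perfect_stem_start_{k}", "pairing")

    # --- pairtype (3)
    add("pct_gc_pairs", "pairtype")
    add("pct_au_pairs", "pairtype")
    add("pct_gu_pairs", "pairtype")

    # --- positional (5)
    add("dist_to_loop", "positional")
    add("dist_to_hairpin_start", "positional")
    add("loop_overlap_nt", "positional")
    add("loop_overlap_pct", "positional")
    add("in_loop", "positional")

    # --- energy (1)
    add("duplex_mfe", "energy")

    _REGISTRY = FeatureRegistry(tuple(e))
    assert len(_REGISTRY) == 100
    return _REGISTRY


def registry_fingerprint() -> str:
    return feature_registry().fingerprint()


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------

def _runs(mask: Sequence[bool], value: bool) -> list[tuple[int, int]]:
    """Maximal runs of `value` in mask as (start, length)."""
    out, start = [], None
    for i, m in enumerate(mask):
        if m == value and start is None:
            start = i
        elif m != value and start is not None:
            out.append((start, i - start))
            start = None
    if start is not None:
        out.append((start, len(mask) - start))
    return out


def triplet_profile(record: HairpinRecord, candidate: MirnaCandidate) -> np.ndarray:
    """32-vector of sequence/structure triplet frequencies.

    For each interior miRNA position i (local 1..l-2) the pattern is the
    pairing status (from the global structure) of positions i-1, i, i+1,
    keyed by the middle nucleotide; counts are normalized by l-2.
    """
    l = candidate.length
    if l < 3:
        raise ContractError("triplet profile needs length >= 3")
    record = record.with_structure()
    pt = parse_dot_bracket(record.structure)
    L = len(record)

    def paired(pos: int) -> bool:
        return 0 <= pos < L and pt.partner[pos] >= 0  # out-of-range pads unpaired

    counts = np.zeros(32)
    for li in range(1, l - 1):
        pos = candidate.start + li
        pat = (int(paired(pos - 1)) << 2) | (int(paired(pos)) << 1) | int(paired(pos + 1))
        nt = _NT_INDEX[record.seq[pos]]
        counts[nt * 8 + pat] += 1
    return counts / (l - 2)


def extract_features(
    record: HairpinRecord,
    candidate: MirnaCandidate,
    annotation: DuplexAnnotation,
) -> np.ndarray:
    """Compute the ordered 100-feature vector for an annotated candidate."""
    if candidate is None or annotation is None:
        raise ContractError("candidate must be annotated before feature extraction")
    record = record.with_structure()
    pt = parse_dot_bracket(record.structure)
    try:
        loop = locate_terminal_loop(pt, candidate.start, candidate.length)
    except NoLoopError:
        loop = LoopRegion(0, len(record))
    return _feature_values(record.seq, pt, loop, candidate, annotation)


def _feature_values(
    seq: str,
    pt: PairTable,
    loop: LoopRegion,
    cand: MirnaCandidate,
    ann: DuplexAnnotation,
) -> np.ndarray:
    l = cand.length
    start, end = cand.start, cand.start + l
    sub = seq[start:end]
    codes = np.fromiter((_NT_INDEX[c] for c in sub), dtype=np.int64, count=l)
    mask = np.asarray(cand.paired_mask, dtype=bool)
    v: list[float] = []

    # sequence (30)
    mono = np.bincount(codes, minlength=4) / l
    v.extend(mono)
    di = np.bincount(codes[:-1] * 4 + codes[1:], minlength=16) / (l - 1)
    v.extend(di)
    v.append(float(mono[1] + mono[2]))  # GC content
    first = np.zeros(4); first[codes[0]] = 1.0
    last = np.zeros(4); last[codes[-1]] = 1.0
    v.extend(first); v.extend(last)
    v.append(float(l))

    # triplet (32): global-structure pairing, padded unpaired past the hairpin
    L = len(seq)
    paired_global = np.zeros(l + 2, dtype=bool)  # positions start-1 .. end
    for k in range(-1, l + 1):
        pos = start + k
        paired_global[k + 1] = 0 <= pos < L and pt.partner[pos] >= 0
    trip = np.zeros(32)
    for li in range(1, l - 1):
        pat = (int(paired_global[li]) << 2) | (int(paired_global[li + 1]) << 1) | int(paired_global[li + 2])
        trip[codes[li] * 8 + pat] += 1
    v.extend(trip / (l - 2))

    # bulge (19): indicators use the duplex mask inside the miRNA and the
    # global structure just outside it (out-of-bounds counts as unpaired)
    def unpaired_at(off_from: int, off: int) -> float:
        pos = off_from + off
        if start <= pos < end:
            return 0.0 if mask[pos - start] else 1.0
        if 0 <= pos < L:
            return 0.0 if pt.partner[pos] >= 0 else 1.0
        return 1.0

    for off in range(-3, 4):
        v.append(unpaired_at(start, off))
    for off in range(-3, 4):
        v.append(unpaired_at(end - 1, off))
    bulge_runs = _runs(mask, False)
    paired_runs = _runs(mask, True)
    longest_bulge = max((r for _, r in bulge_runs), default=0)
    longest_run = max((r for _, r in paired_runs), default=0)
    v.append(float(len(bulge_runs)))
    v.append(float(longest_bulge))
    v.append(longest_bulge / l)
    v.append(float(longest_run))
    v.append(longest_run / l)

    # pairing (10)
    n_paired = int(mask.sum())
    v.append(float(n_paired))
    cum = np.concatenate([[0], np.cumsum(mask)])
    for w in (3, 5, 7):
        if l >= w and n_paired > 0:
            sums = cum[w:] - cum[:-w]
            v.append(float(sums.mean() / w))
        else:
            v.append(0.0)
    for k in (5, 10, 20):
        v.append(1.0 if longest_run >= k else 0.0)
    for k in (5, 10, 20):
        pos = next((s for s, r in paired_runs if r >= k), -1)
        v.append(float(pos))

    # pairtype (3)
    gc = au = gu = 0
    for off in range(l):
        if mask[off]:
            i = start + off
            pair = frozenset((seq[i], seq[int(pt.partner[i])]))
            if pair == frozenset("GC"):
                gc += 1
            elif pair == frozenset("AU"):
                au += 1
            elif pair == frozenset("GU"):
                gu += 1
    if n_paired:
        v.extend([gc / n_paired, au / n_paired, gu / n_paired])
    else:
        v.extend([0.0, 0.0, 0.0])

    # positional (5)
    v.append(float(ann.loop_distance))
    v.append(float(start))
    v.append(float(ann.loop_overlap))
    v.append(ann.loop_overlap / l)
    v.append(1.0 if (start >= loop.start and end <= loop.end) else 0.0)

    # energy (1)
    v.append(float(ann.duplex_energy))

    out = np.asarray(v, dtype=np.float64)
    assert out.shape == (100,) and np.all(np.isfinite(out))
    return out


class HairpinFeaturizer:
    """Featurize many candidate intervals on one hairpin efficiently.

    Parses the structure and locates loops once; each call to
    :meth:`vector` annotates and featurizes a single (start, length).
    """

    def __init__(self, record: HairpinRecord, backend: str = "builtin"):
        self.record = record.with_structure(backend=backend)
        self.backend = backend
        self.pt = parse_dot_bracket(self.record.structure)
        self._loops = hairpin_loops(self.pt)

    def annotate(self, start: int, length: int) -> tuple[MirnaCandidate, DuplexAnnotation]:
        return annotate_duplex(self.record, start, length, backend=self.backend)

    def vector(self, start: int, length: int) -> np.ndarray:
        cand, ann = self.annotate(start, length)
        try:
            loop = locate_terminal_loop(self.pt, start, length)
        except NoLoopError:
            loop = LoopRegion(0, len(self.record))
        return _feature_values(self.record.seq, self.pt, loop, cand, ann)

    def matrix(self, intervals: Sequence[tuple[int, int]]) -> np.ndarray:
        return np.vstack([self.vector(p, l) for p, l in intervals])


def featurize_interval(
    record: HairpinRecord, start: int, length: int, backend: str = "builtin"
) -> np.ndarray:
    """Convenience: annotate and featurize one interval in a single call."""
    cand, ann = annotate_duplex(record, start, length, backend=backend)
    return extract_features(record, cand, ann)


# ---------------------------------------------------------------------------
# Information-gain ranking
# ---------------------------------------------------------------------------

def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def information_gain(column: np.ndarray, labels: np.ndarray, bins: int = 10) -> float:
    """IG of one feature: H(class) - H(class | feature binned into
    equal-frequency bins)."""
    edges = np.unique(np.quantile(column, np.linspace(0, 1, bins + 1)[1:-1]))
    binned = np.digitize(column, edges)
    h = _entropy(labels)
    cond = 0.0
    n = len(labels)
    for b in np.unique(binned):
        sel = binned == b
        cond += sel.sum() / n * _entropy(labels[sel])
    return max(0.0, h - cond)


def rank_information_gain(
    matrix: np.ndarray, labels: Sequence, bins: int = 10
) -> pd.DataFrame:
    """Rank all registry features by information gain against binary labels.

    Returns a DataFrame (name, group, score, rank) sorted by rank; ties are
    broken by registry order.  Raises :class:`TrainingError` on single-class
    labels.
    """
    labels = np.asarray(labels)
    matrix = np.asarray(matrix, dtype=np.float64)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise TrainingError("information gain undefined for single-class labels")
    if counts.min() < 2:
        raise TrainingError("need at least 2 examples per class")
    reg = feature_registry()
    if matrix.shape[1] != len(reg):
        raise ContractError(f"expected {len(reg)} columns, got {matrix.shape[1]}")
    scores = np.array([information_gain(matrix[:, j], labels, bins) for j in range(matrix.shape[1])])
    order = np.lexsort((np.arange(len(scores)), -scores))  # stable: registry order on ties
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    return pd.DataFrame({
        "name": reg.names,
        "group": [d.group for d in reg.entries],
        "score": scores,
        "rank": rank,
    }).sort_values("rank").reset_index(drop=True)
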