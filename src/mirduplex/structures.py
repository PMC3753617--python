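"""Hairpin secondary structures and miRNA:miRNA* duplex geometry.

A pre-miRNA folds into a stem--loop (hairpin).  The mature miRNA sits on one
arm of the stem and pairs with its star strand (miRNA*) on the opposite arm;
the star is offset so that each strand of the excised duplex carries a 2-nt
3' overhang.  This module parses Vienna dot-bracket strings into pair tables,
folds sequences with either an RNAfold-compatible external backend or a
deterministic builtin maximum-weight-pairing dynamic program, locates the
terminal loop relevant to a candidate interval, derives the star interval for
a candidate miRNA, and annotates the resulting duplex (pairing mask, bulges,
energy surrogate, distances to loop and hairpin edge).

Coordinates are 0-based half-open throughout this module; user-facing layers
convert to 1-based inclusive.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    AlphabetError,
    ContractError,
    NoLoopError,
    NoStarError,
    StructureParseError,
)

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: weights of the builtin folder: strong GC, medium AU, weak GU wobble
PAIR_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}

#: minimum hairpin loop size: no pair (i, j) with j - i < MIN_LOOP + 1
MIN_LOOP = 3


def normalize_rna(seq: str) -> str:
    """Uppercase, convert T to U and validate the alphabet.

    Raises :class:`AlphabetError` for anything outside {A, C, G, U} after
    normalization (IUPAC ambiguity codes are not supported).
    """
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad or not s:
        raise AlphabetError(
            f"invalid RNA sequence (offending characters: {sorted(bad) if bad else 'empty'})"
        )
    return s


def pair_weight(a: str, b: str) -> int:
    return PAIR_WEIGHTS.get((a, b), 0)


# ---------------------------------------------------------------------------
# Pair table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairTable:
    """Partner array of a secondary structure.

    ``partner[i]`` is the 0-based index paired with ``i`` or -1 if unpaired.
    The table is an involution: ``partner[partner[i]] == i`` for paired i.
    """

    partner: np.ndarray

    def __len__(self) -> int:
        return len(self.partner)

    def paired(self, i: int) -> bool:
        return self.partner[i] >= 0

    def n_pairs(self) -> int:
        return int((self.partner >= 0).sum()) // 2

    def pairs(self) -> list[tuple[int, int]]:
        """Sorted list of (i, j) pairs with i < j."""
        return [
            (i, int(j)) for i, j in enumerate(self.partner) if j > i
        ]


def parse_dot_bracket(structure: str) -> PairTable:
    """Parse a Vienna dot-bracket string into a :class:`PairTable`.

    Only ``(``, ``)`` and ``.`` are accepted.  An unbalanced bracket raises
    :class:`StructureParseError` naming the offending index.
    """
    partner = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureParseError("unbalanced ')'", i)
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise StructureParseError(f"illegal character {ch!r}", i)
    if stack:
        raise StructureParseError("unmatched '('", stack[0])
    return PairTable(partner)


def pair_table_to_dot_bracket(pt: PairTable) -> str:
    out = []
    for i, j in enumerate(pt.partner):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


# ---------------------------------------------------------------------------
# Hairpin record
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HairpinRecord:
    """A pre-miRNA sequence with an optional dot-bracket structure."""

    id: str
    seq: str
    structure: Optional[str] = None
    source: str = "user"  # user | mirbase | synthetic
    energy: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if self.structure is not None:
            if len(self.structure) != len(self.seq):
                raise StructureParseError(
                    "structure length differs from sequence length", len(self.structure)
                )
            parse_dot_bracket(self.structure)  # validates balance

    def __len__(self) -> int:
        return len(self.seq)

    def with_structure(self, backend: str = "builtin") -> "HairpinRecord":
        """Return a record guaranteed to carry a structure, folding if needed."""
        if self.structure is not None:
            return self
        db, energy = fold_hairpin(self.seq, backend=backend)
        return HairpinRecord(self.id, self.seq, db, self.source, energy)


# ---------------------------------------------------------------------------
# Folding: builtin maximum-weight pairing DP + optional external backend
# ---------------------------------------------------------------------------

def _mwp_table(seq: str) -> np.ndarray:
    """Maximum-weight-pairing DP table.

    M[i][j] = best total pair weight on seq[i..j] (inclusive), with a minimum
    hairpin loop of MIN_LOOP unpaired bases between any pair.
    """
    n = len(seq)
    M = np.zeros((n + 1, n + 1), dtype=np.int64)  # M[i][j] over i..j inclusive, j<n
    w = pair_weight
    for span in range(MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            si = seq[i]
            for k in range(i + MIN_LOOP + 1, j + 1):
                wk = w(si, seq[k])
                if wk:
                    cand = wk + M[i + 1][k - 1] + (M[k + 1][j] if k < j else 0)
                    if cand > best:
                        best = cand
            M[i][j] = best
    return M


def _mwp_traceback(seq: str, M: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback preferring 5'-most pairs.

    Among all maximum-weight pairings this yields the lexicographically
    smallest sorted pair list: at each interval the leftmost base is paired
    whenever some optimal pairing pairs it, to the smallest admissible partner.
    """
    pairs: list[tuple[int, int]] = []
    stack = [(0, len(seq) - 1)]
    w = pair_weight
    while stack:
        i, j = stack.pop()
        while i < j:
            target = M[i][j]
            if target == 0:
                break
            chosen = None
            si = seq[i]
            for k in range(i + MIN_LOOP + 1, j + 1):
                wk = w(si, seq[k])
                if not wk:
                    continue
                inner = M[i + 1][k - 1]
                outer = M[k + 1][j] if k < j else 0
                if wk + inner + outer == target:
                    chosen = k
                    break
            if chosen is None:
                # i must be unpaired in every optimal pairing
                i += 1
                continue
            pairs.append((i, chosen))
            if chosen < j:
                stack.append((chosen + 1, j))
            i, j = i + 1, chosen - 1
    return sorted(pairs)


def fold_builtin(seq: str) -> tuple[str, float]:
    """Fold with the builtin maximum-weight pairing dynamic program.

    Pair weights GC=3, AU=2, GU=1, minimum loop 3.  Returns the dot-bracket
    string and the negated pairing score as a pseudo-energy (pseudo-kcal/mol),
    so that more paired / more stable structures score lower, matching the
    sign convention of thermodynamic folders.
    """
    M = _mwp_table(seq)
    pairs = _mwp_traceback(seq, M)
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    score = sum(pair_weight(seq[i], seq[j]) for i, j in pairs)
    return "".join(db), -float(score)


def _rnafold_available() -> bool:
    return shutil.which("RNAfold") is not None


def fold_external(seq: str) -> tuple[str, float]:
    """Delegate to an RNAfold-compatible executable with default parameters."""
    if not _rnafold_available():
        raise RuntimeError("no RNAfold-compatible executable on PATH")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout.splitlines()
    # second line: dot-bracket followed by ( energy )
    line = out[1]
    db = line.split(None, 1)[0]
    energy = float(line.rsplit("(", 1)[1].rstrip(")").strip())
    return db, energy


def fold_hairpin(seq: str, backend: str = "builtin") -> tuple[str, float]:
    """Fold an RNA sequence into a dot-bracket structure.

    ``backend='builtin'`` uses the deterministic maximum-weight pairing DP;
    ``backend='external'`` delegates to RNAfold when available, falling back
    to the builtin folder otherwise.
    """
    s = normalize_rna(seq)
    if len(s) < 10:
        raise ContractError(f"sequence too short to fold ({len(s)} < 10 nt)")
    if backend == "external":
        if _rnafold_available():
            return fold_external(s)
        logger.warning("external folding backend unavailable; using builtin folder")
        return fold_builtin(s)
    if backend != "builtin":
        raise ContractError(f"unknown folding backend {backend!r}")
    return fold_builtin(s)


# ---------------------------------------------------------------------------
# Terminal loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoopRegion:
    """0-based half-open interval of a terminal (hairpin) loop."""

    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start

    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0


def hairpin_loops(pt: PairTable) -> list[LoopRegion]:
    """All hairpin loops: maximal unpaired runs [a, b) closed by the pair (a-1, b)."""
    loops = []
    for i, j in pt.pairs():
        if j - i >= MIN_LOOP + 1 and all(pt.partner[k] < 0 for k in range(i + 1, j)):
            loops.append(LoopRegion(i + 1, j))
    return loops


def locate_terminal_loop(pt: PairTable, start: int, length: int) -> LoopRegion:
    """Terminal loop relevant to the candidate interval [start, start+length).

    For a single hairpin this is *the* loop.  For multiloop structures the
    nearest hairpin loop to the candidate midpoint is returned (ties broken
    towards the 5' loop).  Raises :class:`NoLoopError` when the structure has
    no base pairs at all.
    """
    loops = hairpin_loops(pt)
    if not loops:
        raise NoLoopError("structure has no hairpin loop")
    mid = start + (length - 1) / 2.0

    def dist(lp: LoopRegion) -> float:
        if lp.start <= mid < lp.end:
            return 0.0
        return min(abs(mid - lp.start), abs(mid - (lp.end - 1)))

    return min(loops, key=lambda lp: (dist(lp), lp.start))


# ---------------------------------------------------------------------------
# Candidate / star / duplex annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MirnaCandidate:
    """A candidate mature miRNA interval on a hairpin, with its derived star."""

    hairpin_id: str
    start: int
    length: int
    arm: str  # 5p | 3p | loop-spanning
    star_start: int
    star_length: int
    paired_mask: tuple[bool, ...]

    @property
    def end(self) -> int:
        """0-based exclusive end."""
        return self.start + self.length


@dataclass(frozen=True)
class DuplexAnnotation:
    """Structural annotation of the miRNA:miRNA* duplex for one candidate."""

    bulges: tuple[tuple[int, int], ...]  # (start offset in miRNA, run length)
    n_paired: int
    duplex_energy: float  # kcal/mol (external) or pseudo-kcal/mol surrogate
    loop_distance: int
    loop_overlap: int
    hairpin_edge_distance: int

    def __post_init__(self):
        total = self.n_paired + sum(run for _, run in self.bulges)
        # conservation: every miRNA position is either paired or in a bulge
        assert total >= 0


def candidate_arm(start: int, length: int, loop: LoopRegion) -> str:
    end = start + length
    if end <= loop.start:
        return "5p"
    if start >= loop.end:
        return "3p"
    return "loop-spanning"


def derive_star(pt: PairTable, start: int, length: int) -> tuple[int, int]:
    """Derive the miRNA* interval for a candidate miRNA.

    The star spans from the partner of the miRNA's last paired base to the
    partner of its first paired base, extended by 2 nt at the star's 3' end
    (the biological duplex leaves a 2-nt 3' overhang on each strand), clamped
    to the hairpin.  Returns (star_start, star_length), 0-based half-open.

    Raises :class:`NoStarError` if no miRNA position is paired.
    """
    L = len(pt)
    if start < 0 or start + length > L:
        raise ContractError("candidate interval outside hairpin")
    paired_idx = [i for i in range(start, start + length) if pt.partner[i] >= 0]
    if not paired_idx:
        raise NoStarError("candidate has no paired position")
    a = int(pt.partner[paired_idx[-1]])
    b = int(pt.partner[paired_idx[0]])
    lo, hi = min(a, b), max(a, b) + 1
    hi = min(L, hi + 2)  # 2-nt extension at the star's 3' end
    return lo, hi - lo


def _reflected_interval(start: int, length: int, loop: LoopRegion, L: int) -> tuple[int, int]:
    """Mirror a fully-unpaired candidate about the loop midpoint (fallback star)."""
    m = loop.midpoint()
    r_end = int(round(2 * m - start)) + 1
    r_start = max(0, r_end - length)
    r_start = min(r_start, max(0, L - length))
    return r_start, min(length, L - r_start)


def annotate_duplex(
    record: HairpinRecord,
    start: int,
    length: int,
    backend: str = "builtin",
) -> tuple[MirnaCandidate, DuplexAnnotation]:
    """Annotate the duplex formed by a candidate interval on a hairpin.

    Pairing is read from the hairpin's global structure restricted to the
    (miRNA, star) intervals.  A position of the candidate counts as paired
    only when its partner lies inside the star interval.  Fully unpaired
    candidates get an all-false mask and a star reflected about the loop
    midpoint, so that negative examples landing in unstructured regions
    remain featurizable.
    """
    record = record.with_structure(backend=backend)
    L = len(record)
    if start < 0 or start + length > L:
        raise ContractError(
            f"candidate [{start}, {start + length}) outside hairpin of length {L}"
        )
    pt = parse_dot_bracket(record.structure)

    try:
        loop = locate_terminal_loop(pt, start, length)
    except NoLoopError:
        loop = LoopRegion(0, L)  # unstructured: whole sequence as the loop

    try:
        star_start, star_length = derive_star(pt, start, length)
        no_star = False
    except NoStarError:
        star_start, star_length = _reflected_interval(start, length, loop, L)
        no_star = True
        logger.debug("candidate %s:[%d,%d) fully unpaired; using reflected star",
                     record.id, start, start + length)

    star_lo, star_hi = star_start, star_start + star_length
    mask = []
    for i in range(start, start + length):
        j = pt.partner[i]
        mask.append(bool(j >= 0 and star_lo <= j < star_hi) and not no_star)
    mask = tuple(mask)

    bulges: list[tuple[int, int]] = []
    run_start = None
    for off, paired in enumerate(mask):
        if not paired and run_start is None:
            run_start = off
        elif paired and run_start is not None:
            bulges.append((run_start, off - run_start))
            run_start = None
    if run_start is not None:
        bulges.append((run_start, length - run_start))

    n_paired = sum(mask)
    energy = _duplex_energy(record, start, length, pt, mask, backend)

    end = start + length
    if end <= loop.start:
        loop_distance, loop_overlap = loop.start - end, 0
    elif start >= loop.end:
        loop_distance, loop_overlap = start - loop.end, 0
    else:
        loop_distance = 0
        loop_overlap = min(end, loop.end) - max(start, loop.start)

    arm = candidate_arm(start, length, loop)
    if arm == "5p":
        edge = start
    elif arm == "3p":
        edge = L - end
    else:
        edge = min(start, L - end)

    cand = MirnaCandidate(record.id, start, length, arm, star_start, star_length, mask)
    ann = DuplexAnnotation(tuple(bulges), n_paired, energy,
                           loop_distance, loop_overlap, edge)
    return cand, ann


def _duplex_energy(record, start, length, pt, mask, backend) -> float:
    """Duplex MFE via RNAduplex when the external backend is active, else the
    builtin surrogate -(3*GC + 2*AU + 1*GU) over paired candidate positions."""
    if backend == "external" and shutil.which("RNAduplex") is not None:
        try:
            star = derive_star(pt, start, length)
            mir_seq = record.seq[start:start + length]
            star_seq = record.seq[star[0]:star[0] + star[1]]
            out = subprocess.run(
                ["RNAduplex"], input=f"{mir_seq}\n{star_seq}\n",
                capture_output=True, text=True, check=True,
            ).stdout
            return float(out.rsplit("(", 1)[1].split(")")[0])
        except (NoStarError, subprocess.SubprocessError, ValueError, IndexError):
            pass
    total = 0
    for off, paired in enumerate(mask):
        if paired:
            i = start + off
            total += pair_weight(record.seq[i], record.seq[int(pt.partner[i])])
    return -float(total)
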