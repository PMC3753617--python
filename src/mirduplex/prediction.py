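"""Mature-miRNA localization by positional consensus over candidate scores.

Prediction mode scores every candidate (start p, length l) with
16 <= l <= 30 on a hairpin of length L, then aggregates per-position
consensus scores: S(p) sums scores over all lengths sharing a start, and
E(e) sums scores over all candidates sharing an end.  The reported duplex is
the admissible (p, l) maximizing S(p) + E(p + l - 1) (ties towards smaller
p, then smaller l).  The star interval of the selected candidate is derived
from the structure; the higher-scoring of the two intervals is reported as
the miRNA, the other as the miRNA*.

Validation mode simply scores one given interval and applies a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .classifier import DuplexModel
from .errors import ContractError
from .features import HairpinFeaturizer
from .structures import HairpinRecord, MirnaCandidate

logger = logging.getLogger(__name__)

MIN_LEN = 16
MAX_LEN = 30


def enumerate_candidates(L: int) -> list[tuple[int, int]]:
    """All (start, length) with 16 <= length <= 30 fitting in L, row-major
    (start-major, then length).  Empty with a warning when L < 16."""
    if L < MIN_LEN:
        logger.warning("hairpin of length %d is shorter than %d nt; no candidates", L, MIN_LEN)
        return []
    return [
        (p, l)
        for p in range(L - MIN_LEN + 1)
        for l in range(MIN_LEN, min(MAX_LEN, L - p) + 1)
    ]


@dataclass
class CandidateGrid:
    """Scores over the candidate lattice; ``scores[p, l-16]`` is NaN where
    p + l > L (inadmissible)."""

    L: int
    scores: np.ndarray  # shape (L - 15, 15)

    @classmethod
    def empty(cls, L: int) -> "CandidateGrid":
        if L < MIN_LEN:
            raise ContractError(f"hairpin too short ({L} < {MIN_LEN})")
        g = np.full((L - MIN_LEN + 1, MAX_LEN - MIN_LEN + 1), np.nan)
        return cls(L, g)

    def set(self, p: int, l: int, value: float) -> None:
        self.scores[p, l - MIN_LEN] = value

    def get(self, p: int, l: int) -> float:
        return float(self.scores[p, l - MIN_LEN])

    def cells(self) -> list[tuple[int, int, float]]:
        out = []
        for p, l in enumerate_candidates(self.L):
            v = self.scores[p, l - MIN_LEN]
            if not np.isnan(v):
                out.append((p, l, float(v)))
        return out


@dataclass(frozen=True)
class ConsensusProfile:
    """Per-position consensus: S indexed by start, E indexed by end (0-based),
    and the selected (best_start, best_length)."""

    S: np.ndarray
    E: np.ndarray
    best_start: int
    best_length: int


def consensus(grid: CandidateGrid, mode: str = "sum") -> ConsensusProfile:
    """Aggregate the score grid into start/end consensus profiles and select
    the admissible (p, l) maximizing S(p) + E(p + l - 1).

    ``mode='mean'`` divides each profile entry by the number of admissible
    cells contributing to it (sensitivity check; 'sum' is the default).
    """
    if mode not in ("sum", "mean"):
        raise ContractError(f"unknown consensus mode {mode!r}")
    sc = grid.scores
    if sc.size == 0 or np.all(np.isnan(sc)):
        raise ContractError("empty candidate grid")
    L = grid.L
    admissible = ~np.isnan(sc)
    filled = np.where(admissible, sc, 0.0)

    S = filled.sum(axis=1)
    S_n = admissible.sum(axis=1)
    E = np.zeros(L)
    E_n = np.zeros(L)
    n_p = sc.shape[0]
    for p in range(n_p):
        for li in range(MAX_LEN - MIN_LEN + 1):
            if admissible[p, li]:
                e = p + (li + MIN_LEN) - 1
                E[e] += sc[p, li]
                E_n[e] += 1
    if mode == "mean":
        S = np.divide(S, S_n, out=np.zeros_like(S), where=S_n > 0)
        E = np.divide(E, E_n, out=np.zeros_like(E), where=E_n > 0)

    best = None
    for p in range(n_p):
        for li in range(MAX_LEN - MIN_LEN + 1):
            if not admissible[p, li]:
                continue
            l = li + MIN_LEN
            obj = S[p] + E[p + l - 1]
            if best is None or obj > best[0]:
                best = (obj, p, l)
    _, p_star, l_star = best
    return ConsensusProfile(S, E, p_star, l_star)


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of prediction mode on one hairpin."""

    hairpin_id: str
    mirna: MirnaCandidate        # the higher-scoring interval of the duplex
    mirna_score: float
    star_start: int              # 0-based half-open companion interval
    star_length: int
    star_score: float
    selected: MirnaCandidate     # the consensus-selected candidate (pre-relabel)
    profile: ConsensusProfile


def score_grid(
    model: DuplexModel, record: HairpinRecord, backend: str = "builtin"
) -> CandidateGrid:
    """Featurize and score every admissible candidate on a hairpin."""
    record = record.with_structure(backend=backend)
    L = len(record)
    cands = enumerate_candidates(L)
    if not cands:
        raise ContractError(f"hairpin {record.id} shorter than {MIN_LEN} nt")
    fz = HairpinFeaturizer(record, backend=backend)
    X = fz.matrix(cands)
    scores = model.score_matrix(X)
    grid = CandidateGrid.empty(L)
    for (p, l), s in zip(cands, scores):
        grid.set(p, l, float(s))
    return grid


def predict(
    model: DuplexModel,
    record: HairpinRecord,
    backend: str = "builtin",
    mode: str = "sum",
) -> PredictionResult:
    """Locate the most likely miRNA duplex on a hairpin.

    The consensus-selected interval and its derived star are both scored;
    the higher-scoring one is labeled miRNA and the other miRNA*.
    """
    record = record.with_structure(backend=backend)
    grid = score_grid(model, record, backend=backend)
    prof = consensus(grid, mode=mode)
    p, l = prof.best_start, prof.best_length
    fz = HairpinFeaturizer(record, backend=backend)
    cand, _ = fz.annotate(p, l)
    cand_score = grid.get(p, l)
    star_score = float(model.score_matrix(
        fz.vector(cand.star_start, cand.star_length).reshape(1, -1)
    )[0]) if MIN_LEN <= cand.star_length <= MAX_LEN else _score_any(model, fz, cand)
    if star_score > cand_score:
        star_cand, _ = fz.annotate(cand.star_start, cand.star_length)
        return PredictionResult(
            record.id, star_cand, star_score,
            cand.start, cand.length, cand_score, cand, prof,
        )
    return PredictionResult(
        record.id, cand, cand_score,
        cand.star_start, cand.star_length, star_score, cand, prof,
    )


def _score_any(model: DuplexModel, fz: HairpinFeaturizer, cand: MirnaCandidate) -> float:
    """Score a star interval whose length falls outside [16, 30] (warned,
    not clamped)."""
    logger.warning(
        "star interval length %d outside [%d, %d]; scoring anyway",
        cand.star_length, MIN_LEN, MAX_LEN,
    )
    return float(model.score_matrix(
        fz.vector(cand.star_start, cand.star_length).reshape(1, -1)
    )[0])


def validate(
    model: DuplexModel,
    record: HairpinRecord,
    start: int,
    length: int,
    backend: str = "builtin",
    threshold: float = 0.5,
) -> tuple[float, bool]:
    """Score one candidate interval; verdict = score >= threshold.

    Lengths outside [16, 30] are scored with a logged warning, not clamped.
    """
    record = record.with_structure(backend=backend)
    if start < 0 or start + length > len(record):
        raise ContractError("candidate interval outside the hairpin")
    if not (MIN_LEN <= length <= MAX_LEN):
        logger.warning("candidate length %d outside [%d, %d]", length, MIN_LEN, MAX_LEN)
    fz = HairpinFeaturizer(record, backend=backend)
    s = float(model.score_matrix(fz.vector(start, length).reshape(1, -1))[0])
    return s, s >= threshold


def localization_error(
    true_start: int,
    true_end: int,
    pred_start: int,
    pred_end: int,
    star_start: int,
    star_end: int,
) -> tuple[int, int]:
    """Minimum distance of the true start/end to the predicted miRNA or its
    star (ends are 0-based inclusive or 1-based inclusive — any consistent
    convention works since only differences are taken)."""
    d_start = min(abs(pred_start - true_start), abs(star_start - true_start))
    d_end = min(abs(pred_end - true_end), abs(star_end - true_end))
    return d_start, d_end


def evaluate_localization(
    model: DuplexModel,
    truth_pairs,
    backend: str = "builtin",
    mode: str = "sum",
) -> "pd.DataFrame":
    """Predict each hairpin in a truth corpus and tabulate start/end errors."""
    import pandas as pd

    rows = []
    for pair in truth_pairs:
        res = predict(model, pair.hairpin, backend=backend, mode=mode)
        m = res.mirna
        d_start, d_end = localization_error(
            pair.start, pair.start + pair.length - 1,
            m.start, m.start + m.length - 1,
            res.star_start, res.star_start + res.star_length - 1,
        )
        rows.append({
            "hairpin_id": pair.hairpin.id,
            "true_start": pair.start + 1,
            "true_end": pair.start + pair.length,
            "pred_start": m.start + 1,
            "pred_end": m.start + m.length,
            "pred_arm": m.arm,
            "score": res.mirna_score,
            "d_start": d_start,
            "d_end": d_end,
        })
    return pd.DataFrame(rows)


def cumulative_error_curve(errors: Sequence[int], max_d: int = 10) -> np.ndarray:
    """Fraction of cases with error <= d for d = 0..max_d."""
    e = np.asarray(errors)
    return np.array([(e <= d).mean() for d in range(max_d + 1)])
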