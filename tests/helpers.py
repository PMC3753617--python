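"""Independent oracles used by the test suite.

These deliberately re-derive results by brute force (exhaustive enumeration)
so they stay independent of the implementation paths they check.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from mirduplex.structures import MIN_LOOP, pair_weight


def exhaustive_best_pairing(seq: str) -> tuple[int, list[tuple[int, int]]]:
    """Maximum total pair weight over all valid pairings (min loop 3) and the
    lexicographically smallest sorted pair list among the maxima."""

    def enum(i: int, j: int):
        if i >= j:
            yield ()
            return
        for rest in enum(i + 1, j):
            yield rest
        for k in range(i + MIN_LOOP + 1, j + 1):
            if pair_weight(seq[i], seq[k]):
                for inner in enum(i + 1, k - 1):
                    for outer in enum(k + 1, j):
                        yield ((i, k),) + inner + outer

    best_w, best_list = -1, None
    for pl in enum(0, len(seq) - 1):
        w = sum(pair_weight(seq[i], seq[j]) for i, j in pl)
        sl = tuple(sorted(pl))
        if w > best_w or (w == best_w and sl < best_list):
            best_w, best_list = w, sl
    return best_w, list(best_list)


def brute_force_argmax(grid, mode: str = "sum") -> tuple[int, int]:
    """Re-derive the consensus selection by explicit summation over all cells."""
    cells = grid.cells()
    S, E = defaultdict(float), defaultdict(float)
    Sn, En = defaultdict(int), defaultdict(int)
    for p, l, v in cells:
        S[p] += v
        Sn[p] += 1
        E[p + l - 1] += v
        En[p + l - 1] += 1
    if mode == "mean":
        S = {p: S[p] / Sn[p] for p in S}
        E = {e: E[e] / En[e] for e in E}
    best, best_obj = None, None
    for p, l, _ in sorted(cells, key=lambda c: (c[0], c[1])):
        obj = S[p] + E[p + l - 1]
        if best_obj is None or obj > best_obj:
            best_obj, best = obj, (p, l)
    return best


def random_balanced_dot_bracket(rng: np.random.Generator, n: int) -> str:
    """A random balanced dot-bracket string of length n."""
    out, depth = [], 0
    for i in range(n):
        remaining = n - i
        if depth == remaining:
            ch = ")"  # forced: just enough room to close what is open
        else:
            choices = ["a", "."]  # bias towards dots
            if remaining >= depth + 2:
                choices.append("(")
            if depth > 0:
                choices.append(")")
            ch = choices[int(rng.integers(len(choices)))]
            if ch == "a":
                ch = "."
        out.append(ch)
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
    assert depth == 0
    return "".join(out)


def perfect_hairpin(stem: str, loop_len: int = 6) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    rc = "".join(comp[c] for c in reversed(stem))
    return stem + "A" * loop_len + rc
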