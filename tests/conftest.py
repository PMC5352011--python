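"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
formula evaluation) and independent of the library code paths they
check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from mazeline import transcript_io as tio


def parse_line(line: str, activity: str = "Play", child_id: str = "kid"):
    """Parse one dialect line into its (single) utterance."""
    t = tio.parse_transcript(f"+Activity: {activity}\n{line}\n", child_id)
    assert len(t.utterances) == 1
    return t.utterances[0]


@pytest.fixture
def parse_one():
    return parse_line


# ---------------------------------------------------------------------------
# brute-force minimum-edit-distance oracle (no DP: exhaustive recursion)


def brute_edit_cost(a: tuple[str, ...], b: tuple[str, ...]) -> int:
    """Minimum unit-cost edit distance by exhaustive recursion."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    costs = [
        brute_edit_cost(a[1:], b[1:]) + (0 if a[0] == b[0] else 1),  # match/sub
        brute_edit_cost(a[1:], b) + 1,  # delete a[0]
        brute_edit_cost(a, b[1:]) + 1,  # insert b[0]
    ]
    return min(costs)


def is_proper_subsequence(sub: tuple[str, ...], seq: tuple[str, ...]) -> bool:
    if len(sub) >= len(seq):
        return False
    it = iter(seq)
    return all(w in it for w in sub)


def all_word_pairs(vocab=("a", "b"), max_len=4):
    seqs = [
        tuple(s)
        for n in range(max_len + 1)
        for s in itertools.product(vocab, repeat=n)
    ]
    return [(x, y) for x in seqs for y in seqs]


# ---------------------------------------------------------------------------
# direct-formula statistical oracles


def kendall_tau_b_oracle(x, y) -> float:
    """Pairwise enumeration with tie correction."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = np.sign(x[j] - x[i])
            dy = np.sign(y[j] - y[i])
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx == dy:
                conc += 1
            else:
                disc += 1
    denom = math.sqrt((conc + disc + tx) * (conc + disc + ty))
    return (conc - disc) / denom


def bh_oracle(pvals) -> np.ndarray:
    """Step-up Benjamini-Hochberg by the textbook recursion."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def welch_oracle(x, y) -> tuple[float, float]:
    """Welch t and Satterthwaite dof from the definitional formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(vx + vy)
    dof = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return t, dof


def cohen_kappa_oracle(a, b) -> float:
    labels = sorted(set(a) | set(b))
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    pe = sum(
        (sum(x == l for x in a) / n) * (sum(y == l for y in b) / n) for l in labels
    )
    if pe >= 1.0:  # both annotators constant on the same label
        return 1.0
    return (po - pe) / (1 - pe)


def anderson_darling_2s_oracle(x, y) -> float:
    """Standardized two-sample Anderson-Darling statistic (midrank version).

    Direct evaluation of the Scholz-Stephens rank formulas: the
    tie-adjusted statistic A2akN over distinct pooled values, then the
    k-sample normalization (A2 - (k-1)) / sigma_N.
    """
    samples = [np.sort(np.asarray(s, float)) for s in (x, y)]
    pooled = np.sort(np.concatenate(samples))
    Z, counts = np.unique(pooled, return_counts=True)
    N = len(pooled)
    k = 2
    A2 = 0.0
    for i, s in enumerate(samples):
        n_i = len(s)
        inner = 0.0
        Baj = 0.0
        for z_j, l_j in zip(Z, counts):
            Baj_mid = Baj + l_j / 2.0
            f_ij = np.sum(s == z_j)
            M_ij = np.sum(s < z_j) + f_ij / 2.0
            denom = Baj_mid * (N - Baj_mid) - N * l_j / 4.0
            if denom > 0:
                inner += (l_j / N) * (N * M_ij - n_i * Baj_mid) ** 2 / denom
            Baj += l_j
        A2 += inner / n_i
    A2 *= (N - 1.0) / N

    # variance of A2kN under H0 (Scholz & Stephens)
    H = sum(1.0 / len(s) for s in samples)
    h = sum(1.0 / i for i in range(1, N))
    g = sum(
        1.0 / ((N - i) * j)
        for i in range(1, N - 1)
        for j in range(i + 1, N)
    )
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return (A2 - (k - 1)) / math.sqrt(var)
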