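"""Independent oracles and scenario samplers shared by the test suite.

The alignment oracles deliberately do not share code with the package: one
is a plain three-matrix Gotoh dynamic program, the other literally
enumerates every monotone alignment and scores its gap runs.
"""

from __future__ import annotations

import numpy as np

from oryzatools import AlignScoring, Sd1ScenarioConfig


def gotoh_oracle_score(a: str, b: str, sc: AlignScoring) -> float:
    """Affine-gap global alignment score by an independent DP."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = sc.gap_cost(i)
    for j in range(1, m + 1):
        Y[0][j] = sc.gap_cost(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.score_pair(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] + sc.gap_open,
                X[i - 1][j] + sc.gap_extend,
                Y[i - 1][j] + sc.gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] + sc.gap_open,
                X[i][j - 1] + sc.gap_open,
                Y[i][j - 1] + sc.gap_extend,
            )
    return max(M[n][m], X[n][m], Y[n][m])


def enumerate_oracle_score(a: str, b: str, sc: AlignScoring) -> float:
    """Best score over an exhaustive enumeration of all global alignments."""
    best = [float("-inf")]

    def rec(i: int, j: int, last: str, score: float) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + sc.score_pair(a[i], b[j]))
        if i < len(a):
            rec(i + 1, j, "X",
                score + (sc.gap_extend if last == "X" else sc.gap_open))
        if j < len(b):
            rec(i, j + 1, "Y",
                score + (sc.gap_extend if last == "Y" else sc.gap_open))

    rec(0, 0, "", 0.0)
    return best[0]


def random_sd1_config(rng: np.random.Generator) -> Sd1ScenarioConfig:
    """A valid random deletion scenario: block inside exon 1, optional novel
    intron, 0-2 anchored bases."""
    exon1 = int(rng.integers(500, 1100))
    span = int(rng.integers(30, min(400, exon1 - 30)))
    start = int(rng.integers(4, exon1 - span - 2))
    if span > 40 and rng.random() < 0.5:
        i1 = int(rng.integers(5, span - 25))
    else:
        i1 = 0
    lo, hi = start + i1 + 2, start + span - 3
    n_anchor = int(rng.integers(0, 3))
    while n_anchor and hi - lo < 8 * (n_anchor + 1):
        n_anchor -= 1
    anchors = [
        lo + (k + 1) * (hi - lo) // (n_anchor + 1) for k in range(n_anchor)
    ]
    exon2 = int(rng.integers(200, 800))
    intron = int(rng.integers(80, 400))
    return Sd1ScenarioConfig(
        ref_gene_length=exon1 + intron + exon2,
        exon_lengths_ref=[exon1, exon2],
        intron_lengths_ref=[intron],
        deletion_span=span,
        deletion_start=start,
        anchored_positions=anchors,
        derived_intron1_length=i1,
        seed=int(rng.integers(2**31)),
    )
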