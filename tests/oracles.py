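"""Independent brute-force reference implementations used by the tests.

These deliberately share no code with the package: frequencies are
counted with dictionaries, entropies summed term by term, and the matrix
transforms written as explicit loops, so agreement with the vectorized
implementations is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

GAP = "-"
LOG_BASE = 21.0


def _entropy(freqs: dict, n: int) -> float:
    h = 0.0
    for count in freqs.values():
        f = count / n
        if f > 0:
            h -= f * math.log(f, LOG_BASE)
    return h


def brute_mi_pair(col_x: str, col_y: str) -> tuple[float, float, float]:
    """(MI, nMI, joint entropy) for two alignment columns.

    Gap counts as an ordinary 21st symbol.  MI is clamped at zero and
    nMI uses the 0/0 -> 0 convention.
    """
    n = len(col_x)
    hx = _entropy(Counter(col_x), n)
    hy = _entropy(Counter(col_y), n)
    hxy = _entropy(Counter(zip(col_x, col_y)), n)
    mi = max(0.0, hx + hy - hxy)
    nmi = mi / hxy if hxy > 0 else 0.0
    return mi, nmi, hxy


def gap_heavy(col: str) -> bool:
    return col.count(GAP) / len(col) >= 0.80


def brute_mi_matrices(cols_a: list[str], cols_b: list[str]) -> tuple[list, list]:
    """MI and nMI matrices over all column pairs, with the gap rule."""
    mi = [[0.0] * len(cols_b) for _ in cols_a]
    nmi = [[0.0] * len(cols_b) for _ in cols_a]
    for i, x in enumerate(cols_a):
        for j, y in enumerate(cols_b):
            if gap_heavy(x) or gap_heavy(y):
                continue
            mi[i][j], nmi[i][j], _ = brute_mi_pair(x, y)
    return mi, nmi


def _mean(v) -> float:
    return sum(v) / len(v)


def _psd(v) -> float:
    m = _mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / len(v))


def brute_clr(mat: list[list[float]]) -> list[list[float]]:
    """Row/column clipped z-scores combined by root-sum-square.

    Population standard deviation; a zero deviation makes its z-score 0.
    """
    m, n = len(mat), len(mat[0])
    out = [[0.0] * n for _ in range(m)]
    for i in range(m):
        row = mat[i]
        for j in range(n):
            col = [mat[k][j] for k in range(m)]
            zr = 0.0
            if _psd(row) > 0:
                zr = max(0.0, (mat[i][j] - _mean(row)) / _psd(row))
            zc = 0.0
            if _psd(col) > 0:
                zc = max(0.0, (mat[i][j] - _mean(col)) / _psd(col))
            out[i][j] = math.sqrt(zr * zr + zc * zc)
    return out


def brute_mip(mat: list[list[float]]) -> list[list[float]]:
    """MI - APC with all means over the full rectangular matrix."""
    m, n = len(mat), len(mat[0])
    overall = _mean([x for row in mat for x in row])
    out = [[0.0] * n for _ in range(m)]
    if overall == 0:
        return out
    for i in range(m):
        for j in range(n):
            row_mean = _mean(mat[i])
            col_mean = _mean([mat[k][j] for k in range(m)])
            out[i][j] = mat[i][j] - row_mean * col_mean / overall
    return out


def columns_of(family_sequences: list[str]) -> list[str]:
    width = len(family_sequences[0])
    return ["".join(s[i] for s in family_sequences) for i in range(width)]
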