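"""Inter-protein residue covariation matrices.

Covariation between every exposed column of family A and every exposed
column of family B is summarized in a rectangular m x n score matrix
(rows = columns of A, columns = columns of B).  Four scores are
supported:

* **MI** — mutual information MI(x, y) = H(x) + H(y) - H(x, y), with
  marginal and joint entropies computed from raw relative frequencies
  over the 21-symbol alphabet (20 amino acids + gap) and logarithms in
  base 21, so entropies and MI live in [0, 1].
* **nMI** — MI normalized by the joint entropy, MI / H(x, y), with the
  0/0 case defined as 0.
* **CLR** — context likelihood of relatedness: each nMI entry is
  z-scored against its row distribution and against its column
  distribution (population standard deviation, no diagonal exclusions
  on the rectangular matrix), negatives clipped to 0, and the two
  z-scores combined by root-sum-square.
* **MIp** — average product correction: MIp = MI - APC where
  APC(a, b) = (mean of row a) x (mean of column b) / (overall mean).
  By default MIp is applied to the normalized MI matrix for pipeline
  consistency with CLR; ``on_raw=True`` applies it to raw MI instead
  (the original formulation).

Gap handling: any column with >= 80% gap characters is treated as
carrying no signal — every pair involving it scores exactly 0, and the
zeros propagate into the CLR/MIp inputs.

CCMpred (pseudo-likelihood DCA) is never re-implemented; its square raw
score matrix over the concatenated alignment is consumed via
:func:`extract_inter_block`, which trims the inter-protein block out of
the intra- and inter-protein couplings.

All 0/0 conventions (normalized MI, APC with zero mean, z-score with
zero standard deviation) resolve to 0: no signal in, no signal out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numba
import numpy as np

from .asa import ERMSAPair
from .msa import GAP_CODE, N_SYMBOLS

Method = Literal["MI", "nMI", "MIp", "CLR", "CCMpred"]

#: a column with at least this fraction of gaps carries no signal
GAP_COLUMN_FRACTION = 0.80

_LN21 = math.log(N_SYMBOLS)


class CovariationError(ValueError):
    """Raised for malformed covariation inputs."""


@dataclass
class CovariationMatrix:
    """Rectangular inter-protein score matrix for one dimer.

    ``row_columns``/``col_columns`` map matrix rows/columns back to the
    original (0-based) alignment columns of family A / family B.
    """

    dimer_id: str
    method: str
    threshold: float
    scores: np.ndarray
    row_columns: np.ndarray
    col_columns: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.row_columns = np.asarray(self.row_columns, dtype=int)
        self.col_columns = np.asarray(self.col_columns, dtype=int)
        if self.scores.ndim != 2 or min(self.scores.shape) < 1:
            raise CovariationError(
                f"{self.dimer_id}: scores must be a nonempty 2-D matrix"
            )
        m, n = self.scores.shape
        if self.row_columns.size != m or self.col_columns.size != n:
            raise CovariationError(
                f"{self.dimer_id}: column maps do not match matrix shape"
            )
        if np.isnan(self.scores).any():
            raise CovariationError(f"{self.dimer_id}: scores contain NaN")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape


# --- MI engine -------------------------------------------------------------


def _entropy_terms(n: int) -> np.ndarray:
    """Lookup table T[c] = c * ln(c) for integer counts 0..n."""
    t = np.zeros(n + 1)
    k = np.arange(1, n + 1, dtype=float)
    t[1:] = k * np.log(k)
    return t


@numba.njit(cache=False)
def _joint_entropy_sums(
    codes_a: np.ndarray, codes_b: np.ndarray, table: np.ndarray
) -> np.ndarray:  # pragma: no cover - exercised through mi_matrices
    """sum(c * ln c) over the 21x21 joint count table of every column pair."""
    m, n_seq = codes_a.shape
    n = codes_b.shape[0]
    out = np.zeros((m, n))
    counts = np.zeros((21, 21), dtype=np.int32)
    for i in range(m):
        col_a = codes_a[i]
        for j in range(n):
            col_b = codes_b[j]
            counts[:, :] = 0
            for s in range(n_seq):
                counts[col_a[s], col_b[s]] += 1
            tot = 0.0
            for x in range(21):
                for y in range(21):
                    c = counts[x, y]
                    if c > 1:  # c*ln(c) vanishes for 0 and 1
                        tot += table[c]
            out[i, j] = tot
    return out


def _mi_core(codes_a: np.ndarray, codes_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MI and joint entropy for all column pairs, both (m, n) float64.

    ``codes_a`` is (m, N) and ``codes_b`` (n, N), entries 0..20.
    Entropies come from exact integer counts via
    H = (ln N - sum(c ln c) / N) / ln 21.
    """
    m, n_seq = codes_a.shape
    n = codes_b.shape[0]
    table = _entropy_terms(n_seq)
    ln_n = math.log(n_seq)

    s_joint = _joint_entropy_sums(
        np.ascontiguousarray(codes_a), np.ascontiguousarray(codes_b), table
    )
    h_joint = (ln_n - s_joint / n_seq) / _LN21

    counts_a = np.stack(
        [np.bincount(row, minlength=N_SYMBOLS) for row in codes_a]
    )
    counts_b = np.stack(
        [np.bincount(row, minlength=N_SYMBOLS) for row in codes_b]
    )
    h_a = (ln_n - table[counts_a].sum(axis=1) / n_seq) / _LN21
    h_b = (ln_n - table[counts_b].sum(axis=1) / n_seq) / _LN21

    mi = h_a[:, None] + h_b[None, :] - h_joint
    np.maximum(mi, 0.0, out=mi)  # clamp floating-point negatives
    return mi, h_joint


def _gap_heavy(codes: np.ndarray) -> np.ndarray:
    """Boolean mask over columns with >= 80% gap characters."""
    return (codes == GAP_CODE).mean(axis=1) >= GAP_COLUMN_FRACTION


def mi_matrices(e: ERMSAPair) -> tuple[CovariationMatrix, CovariationMatrix]:
    """Raw and joint-entropy-normalized MI in one pass.

    Returns ``(mi, nmi)``; both have the gap rule applied (any pair with
    a >= 80%-gap member scores 0) and the 0/0 normalization convention.
    """
    codes_a = e.family_a_exposed.to_codes().T.copy()  # (m, N)
    codes_b = e.family_b_exposed.to_codes().T.copy()  # (n, N)
    mi, h_joint = _mi_core(codes_a, codes_b)

    bad_a = _gap_heavy(codes_a)
    bad_b = _gap_heavy(codes_b)
    mi[bad_a, :] = 0.0
    mi[:, bad_b] = 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(h_joint > 0.0, mi / np.where(h_joint > 0.0, h_joint, 1.0), 0.0)

    common = dict(
        dimer_id=e.dimer_id,
        threshold=e.threshold,
        row_columns=e.column_map_a,
        col_columns=e.column_map_b,
    )
    return (
        CovariationMatrix(method="MI", scores=mi, **common),
        CovariationMatrix(method="nMI", scores=nmi, **common),
    )


def mi_matrix(e: ERMSAPair, normalized: bool = False) -> CovariationMatrix:
    """Mutual information over all inter-protein column pairs.

    With ``normalized=True`` each entry is divided by the pair's joint
    entropy (0/0 -> 0), bounding scores in [0, 1].
    """
    mi, nmi = mi_matrices(e)
    return nmi if normalized else mi


# --- matrix transforms -----------------------------------------------------


def clr_transform(nmi: CovariationMatrix) -> CovariationMatrix:
    """Context likelihood of relatedness over the rectangular nMI matrix.

    Entry (i, j) combines two clipped z-scores — against the
    distribution of row i and of column j, means and population standard
    deviations taken over the whole row/column with no diagonal
    exclusions — as sqrt(Zi^2 + Zj^2).  A zero standard deviation makes
    the corresponding z-score 0.
    """
    if nmi.method != "nMI":
        raise CovariationError(
            f"CLR expects the normalized MI matrix, got method {nmi.method!r}"
        )
    s = nmi.scores
    mu_row = s.mean(axis=1, keepdims=True)
    sd_row = s.std(axis=1, keepdims=True)  # population sd (ddof=0)
    mu_col = s.mean(axis=0, keepdims=True)
    sd_col = s.std(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_row = np.where(sd_row > 0.0, (s - mu_row) / np.where(sd_row > 0.0, sd_row, 1.0), 0.0)
        z_col = np.where(sd_col > 0.0, (s - mu_col) / np.where(sd_col > 0.0, sd_col, 1.0), 0.0)
    z_row = np.maximum(z_row, 0.0)
    z_col = np.maximum(z_col, 0.0)
    out = np.sqrt(z_row**2 + z_col**2)
    return CovariationMatrix(
        dimer_id=nmi.dimer_id,
        method="CLR",
        threshold=nmi.threshold,
        scores=out,
        row_columns=nmi.row_columns,
        col_columns=nmi.col_columns,
    )


def mip_transform(mi: CovariationMatrix) -> CovariationMatrix:
    """Average-product-corrected MI over the rectangular matrix.

    APC(a, b) = (mean of row a) x (mean of column b) / (overall mean),
    all means over the full matrix with no diagonal exclusions; when the
    overall mean is 0 the result is the zero matrix.  Accepts the raw MI
    or the normalized MI matrix.
    """
    if mi.method not in ("MI", "nMI"):
        raise CovariationError(
            f"MIp expects an MI or nMI matrix, got method {mi.method!r}"
        )
    s = mi.scores
    overall = s.mean()
    if overall == 0.0:
        out = np.zeros_like(s)
    else:
        apc = np.outer(s.mean(axis=1), s.mean(axis=0)) / overall
        out = s - apc
    return CovariationMatrix(
        dimer_id=mi.dimer_id,
        method="MIp",
        threshold=mi.threshold,
        scores=out,
        row_columns=mi.row_columns,
        col_columns=mi.col_columns,
    )


# --- CCMpred adapter -------------------------------------------------------


def read_ccmpred_matrix(path) -> np.ndarray:
    """Parse a CCMpred raw score file: an L x L whitespace-delimited
    real matrix over the concatenated alignment columns."""
    raw = np.loadtxt(path, dtype=float)
    raw = np.atleast_2d(raw)
    if raw.shape[0] != raw.shape[1]:
        raise CovariationError(
            f"CCMpred matrix is {raw.shape[0]}x{raw.shape[1]}, expected square"
        )
    return raw


def extract_inter_block(
    raw: np.ndarray,
    width_a: int,
    width_b: int,
    dimer_id: str = "",
    threshold: float = -1.0,
    column_map_a: Optional[np.ndarray] = None,
    column_map_b: Optional[np.ndarray] = None,
    rtol: float = 1e-8,
) -> CovariationMatrix:
    """Trim the inter-protein block from a square concatenated-alignment
    score matrix.

    The block is rows 0..width_a-1, columns width_a..width_a+width_b-1.
    When the raw matrix is asymmetric beyond tolerance the block is
    averaged with the transpose of the mirror (lower-left) block.
    """
    raw = np.asarray(raw, dtype=float)
    total = width_a + width_b
    if raw.shape != (total, total):
        raise CovariationError(
            f"raw matrix is {raw.shape}, expected ({total}, {total}) for "
            f"widths {width_a}+{width_b}"
        )
    upper = raw[:width_a, width_a:]
    lower = raw[width_a:, :width_a]
    scale = max(np.abs(raw).max(), 1.0)
    if not np.allclose(upper, lower.T, rtol=0.0, atol=rtol * scale):
        upper = 0.5 * (upper + lower.T)
    return CovariationMatrix(
        dimer_id=dimer_id,
        method="CCMpred",
        threshold=threshold,
        scores=upper,
        row_columns=(
            column_map_a if column_map_a is not None else np.arange(width_a)
        ),
        col_columns=(
            column_map_b if column_map_b is not None else np.arange(width_b)
        ),
    )


# --- serialization ---------------------------------------------------------


def write_matrix_tsv(m: CovariationMatrix, path) -> None:
    """Write a score matrix as TSV with 1-based query-position headers."""
    with open(path, "w") as fh:
        header = "\t".join(str(c + 1) for c in m.col_columns)
        fh.write(f"#dimer={m.dimer_id}\tmethod={m.method}\tthreshold={m.threshold}\n")
        fh.write("pos\t" + header + "\n")
        for r, row in zip(m.row_columns, m.scores):
            fh.write(str(r + 1) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
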