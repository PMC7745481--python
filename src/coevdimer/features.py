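"""Frobenius-norm feature tables.

Each inter-protein covariation matrix is collapsed to its Frobenius norm
sqrt(sum |a_ij|^2): squaring attenuates the many weak indirect signals
relative to the few strong direct couplings, so one number summarizes a
whole dimer at one ASA threshold.  Norms across the ten thresholds form
the per-dimer feature vector fed to the classifier.

Feature tables are kept raw here; any standardization belongs to the
classifier stage, where it can be fit on the training split only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .asa import (
    ASAProfile,
    DEFAULT_THRESHOLDS,
    exposed_mask,
    all_columns_ermsa,
)
from .covariation import (
    CovariationMatrix,
    clr_transform,
    extract_inter_block,
    mi_matrices,
    mip_transform,
)
from .msa import PairedMSA

MI_METHODS = ("MI", "nMI", "MIp", "CLR")


class FeatureError(ValueError):
    """Raised for missing cells or malformed norm tables."""


def frobenius_norm(m: CovariationMatrix | np.ndarray) -> float:
    """sqrt of the sum of squared entries, over the whole matrix."""
    scores = m.scores if isinstance(m, CovariationMatrix) else np.asarray(m)
    if scores.size == 0:
        raise FeatureError("empty matrix has no Frobenius norm")
    return float(np.linalg.norm(scores))


def feature_range(
    start: float,
    end: float = 0.75,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> tuple[float, ...]:
    """The contiguous threshold group [start, end] (e.g. 0.35-0.75).

    Multiple-feature models use groups that start anywhere in the
    threshold ladder and end at the top (0.75 by default).
    """
    sel = tuple(t for t in thresholds if start <= t <= end)
    if not sel:
        raise FeatureError(f"no thresholds in [{start}, {end}]")
    return sel


def compute_dimer_norms(
    p: PairedMSA,
    asa_a: ASAProfile,
    asa_b: ASAProfile,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    methods: Sequence[str] = MI_METHODS,
    mip_on_raw: bool = False,
    ccmpred_raw: Optional[Mapping[float, np.ndarray]] = None,
) -> pd.DataFrame:
    """Norms of all requested (method, threshold) matrices for one dimer.

    MI is computed once over the full alignment and sliced per
    threshold — per-column-pair MI and the gap rule are independent of
    which other columns are retained — while CLR and MIp are recomputed
    on each threshold's submatrix because their row/column statistics
    change with the retained set.  CCMpred norms require one raw square
    matrix per threshold (over the concatenated ER-MSA of exactly that
    threshold), supplied via ``ccmpred_raw``.

    Returns a long-format frame: dimer_id, label, method, threshold, norm.
    """
    unknown = set(methods) - set(MI_METHODS) - {"CCMpred"}
    if unknown:
        raise FeatureError(f"unknown methods: {sorted(unknown)}")
    want_mi = [m for m in methods if m in MI_METHODS]
    rows: list[tuple] = []

    if want_mi:
        full = all_columns_ermsa(p)
        mi_full, nmi_full = mi_matrices(full)
        for t in thresholds:
            idx_a = np.flatnonzero(exposed_mask(asa_a, t))
            idx_b = np.flatnonzero(exposed_mask(asa_b, t))
            if idx_a.size == 0 or idx_b.size == 0:
                raise FeatureError(
                    f"{p.dimer_id}: empty interface at threshold {t}"
                )
            sub = dict(
                dimer_id=p.dimer_id,
                threshold=t,
                row_columns=idx_a,
                col_columns=idx_b,
            )
            mi_t = CovariationMatrix(
                method="MI", scores=mi_full.scores[np.ix_(idx_a, idx_b)], **sub
            )
            nmi_t = CovariationMatrix(
                method="nMI", scores=nmi_full.scores[np.ix_(idx_a, idx_b)], **sub
            )
            per_method = {}
            if "MI" in want_mi:
                per_method["MI"] = mi_t
            if "nMI" in want_mi:
                per_method["nMI"] = nmi_t
            if "MIp" in want_mi:
                per_method["MIp"] = mip_transform(mi_t if mip_on_raw else nmi_t)
            if "CLR" in want_mi:
                per_method["CLR"] = clr_transform(nmi_t)
            for name, mat in per_method.items():
                rows.append((p.dimer_id, p.label, name, t, frobenius_norm(mat)))

    if "CCMpred" in methods:
        if ccmpred_raw is None:
            raise FeatureError(
                f"{p.dimer_id}: CCMpred norms need raw score matrices"
            )
        for t in thresholds:
            if t not in ccmpred_raw:
                raise FeatureError(
                    f"{p.dimer_id}: no CCMpred matrix for threshold {t}"
                )
            idx_a = np.flatnonzero(exposed_mask(asa_a, t))
            idx_b = np.flatnonzero(exposed_mask(asa_b, t))
            block = extract_inter_block(
                ccmpred_raw[t],
                width_a=idx_a.size,
                width_b=idx_b.size,
                dimer_id=p.dimer_id,
                threshold=t,
                column_map_a=idx_a,
                column_map_b=idx_b,
            )
            rows.append((p.dimer_id, p.label, "CCMpred", t, frobenius_norm(block)))

    return pd.DataFrame(
        rows, columns=["dimer_id", "label", "method", "threshold", "norm"]
    )


@dataclass
class NormFeatureTable:
    """Wide per-dimer feature matrix: columns are (method, threshold).

    ``features`` is indexed by dimer_id with a two-level column index
    ordered by method then ascending threshold; ``labels`` (optional)
    aligns with the index and takes values "positive"/"negative".
    """

    features: pd.DataFrame
    labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.features.isna().any().any():
            raise FeatureError("feature table contains missing cells")
        if (self.features < 0).any().any():
            raise FeatureError("Frobenius norms must be non-negative")
        if self.labels is not None:
            if not self.labels.index.equals(self.features.index):
                raise FeatureError("labels index does not match features")
            bad = set(self.labels.unique()) - {"positive", "negative"}
            if bad:
                raise FeatureError(f"bad labels: {sorted(bad)}")

    @property
    def n_dimers(self) -> int:
        return len(self.features)


def build_feature_table(
    norms: pd.DataFrame,
    methods: Optional[Sequence[str]] = None,
    thresholds: Optional[Sequence[float]] = None,
) -> NormFeatureTable:
    """Pivot long-format norms into a deterministic wide feature table.

    Rows are sorted by dimer_id; columns are (method, threshold) in the
    requested method order with thresholds ascending.  Every requested
    cell must exist — a missing one raises an error naming the
    dimer/method/threshold.
    """
    required = {"dimer_id", "method", "threshold", "norm"}
    if not required.issubset(norms.columns):
        raise FeatureError(f"norm table needs columns {sorted(required)}")
    methods = list(methods) if methods is not None else sorted(norms["method"].unique())
    thresholds = (
        sorted(thresholds)
        if thresholds is not None
        else sorted(norms["threshold"].unique())
    )
    wide = norms.pivot_table(
        index="dimer_id", columns=["method", "threshold"], values="norm",
        aggfunc="first",
    )
    dimers = sorted(norms["dimer_id"].unique())
    cols = [(m, t) for m in methods for t in thresholds]
    for m, t in cols:
        if (m, t) not in wide.columns:
            raise FeatureError(f"no norms computed for method={m} threshold={t}")
    wide = wide.loc[dimers, cols]
    for (m, t) in cols:
        missing = wide[(m, t)].isna()
        if missing.any():
            d = wide.index[missing][0]
            raise FeatureError(
                f"missing norm for dimer={d} method={m} threshold={t}"
            )
    labels = None
    if "label" in norms.columns and norms["label"].notna().any():
        lab = (
            norms.drop_duplicates("dimer_id")
            .set_index("dimer_id")["label"]
            .loc[dimers]
        )
        if lab.notna().all():
            labels = lab
    return NormFeatureTable(features=wide, labels=labels)


def save_norm_table(norms: pd.DataFrame, path: str | Path) -> None:
    """Write long-format norms as TSV (dimer_id, label, method,
    threshold, norm)."""
    norms.to_csv(path, sep="\t", index=False)


def load_norm_table(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Read a long-format norm TSV/CSV.

    ``column_map`` renames external column layouts (e.g. a published
    supplementary norm table) onto the canonical names dimer_id, label,
    method, threshold, norm.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = {"dimer_id", "method", "threshold", "norm"}
    missing = required - set(df.columns)
    if missing:
        raise FeatureError(
            f"norm table at {path} lacks columns {sorted(missing)} "
            "(use column_map to adapt external layouts)"
        )
    if "label" not in df.columns:
        df["label"] = None
    return df[["dimer_id", "label", "method", "threshold", "norm"]]
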