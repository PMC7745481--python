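"""Solvent accessibility profiles and exposed-residue MSA extraction.

Binding interfaces live on protein surfaces, so covariation is computed
only between exposed alignment columns.  Each query position carries a
relative accessible surface area (RSA) in [0, 1], typically averaged
over several sequence-based predictors; a column is *exposed* at
threshold t when its RSA is strictly greater than t.  Restricting a
paired MSA to exposed columns yields an exposed-residue MSA (ER-MSA),
one per threshold.

RSA inputs must already be relative; absolute accessibilities in square
angstroms are out of scope and must be normalized by the caller.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .msa import AlignedFamily, PairedMSA

#: the ten RSA cut-offs at which ER-MSAs are extracted
DEFAULT_THRESHOLDS = (0.0, 0.05, 0.15, 0.2, 0.25, 0.35, 0.45, 0.55, 0.65, 0.75)


class AsaError(ValueError):
    """Raised for malformed accessibility input."""


class EmptyInterfaceError(AsaError):
    """No exposed column survives the threshold in one of the families."""


@dataclass
class ASAProfile:
    """Per-residue relative accessibility for one query protein."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise AsaError(f"{self.protein_id}: profile must be a nonempty 1-D array")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise AsaError(f"{self.protein_id}: RSA values outside [0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class ThresholdSet:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise AsaError("empty threshold set")
        if any(not 0.0 <= x < 1.0 for x in t):
            raise AsaError("thresholds must lie in [0, 1)")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise AsaError("thresholds must be strictly increasing")


def average_asa_profiles(profiles: Sequence[ASAProfile]) -> ASAProfile:
    """Position-wise arithmetic mean over predictor profiles."""
    if not profiles:
        raise AsaError("no profiles to average")
    length = len(profiles[0])
    for p in profiles[1:]:
        if len(p) != length:
            raise AsaError(
                f"profile length mismatch: {len(p)} vs {length} "
                f"({p.protein_id} vs {profiles[0].protein_id})"
            )
    mean = np.mean([p.values for p in profiles], axis=0)
    return ASAProfile(protein_id=profiles[0].protein_id, values=mean)


def exposed_mask(profile: ASAProfile, threshold: float) -> np.ndarray:
    """Boolean mask of exposed positions: RSA strictly above the cut-off.

    The strict inequality means threshold 0.0 drops only positions with
    RSA exactly 0, and a value equal to any threshold counts as buried.
    """
    if not 0.0 <= threshold < 1.0:
        raise AsaError(f"threshold {threshold} outside [0, 1)")
    return profile.values > threshold


@dataclass
class ERMSAPair:
    """A paired MSA restricted to exposed columns at one threshold.

    ``column_map_a``/``column_map_b`` give, for each retained column,
    its original (0-based) column index in the full alignment.
    """

    dimer_id: str
    threshold: float
    family_a_exposed: AlignedFamily
    family_b_exposed: AlignedFamily
    column_map_a: np.ndarray
    column_map_b: np.ndarray

    def __post_init__(self) -> None:
        self.column_map_a = np.asarray(self.column_map_a, dtype=int)
        self.column_map_b = np.asarray(self.column_map_b, dtype=int)
        if self.column_map_a.size != self.family_a_exposed.width:
            raise AsaError(f"{self.dimer_id}: column_map_a size mismatch")
        if self.column_map_b.size != self.family_b_exposed.width:
            raise AsaError(f"{self.dimer_id}: column_map_b size mismatch")
        for name, cm in (("a", self.column_map_a), ("b", self.column_map_b)):
            if cm.size > 1 and np.any(np.diff(cm) <= 0):
                raise AsaError(
                    f"{self.dimer_id}: column_map_{name} not strictly increasing"
                )


def _restrict_columns(f: AlignedFamily, keep: np.ndarray) -> AlignedFamily:
    idx = np.flatnonzero(keep)
    seqs = ["".join(s[i] for i in idx) for s in f.sequences]
    return AlignedFamily(
        family_id=f.family_id,
        sequences=seqs,
        species=list(f.species),
        query_index=f.query_index,
    )


def extract_ermsa(
    p: PairedMSA, asa_a: ASAProfile, asa_b: ASAProfile, threshold: float
) -> ERMSAPair:
    """Restrict both families of a dimer to their exposed columns.

    Raises :class:`EmptyInterfaceError` when either family retains no
    column (a covariation matrix would be degenerate).
    """
    if len(asa_a) != p.family_a.width:
        raise AsaError(
            f"{p.dimer_id}: ASA profile length {len(asa_a)} != family A width "
            f"{p.family_a.width}"
        )
    if len(asa_b) != p.family_b.width:
        raise AsaError(
            f"{p.dimer_id}: ASA profile length {len(asa_b)} != family B width "
            f"{p.family_b.width}"
        )
    mask_a = exposed_mask(asa_a, threshold)
    mask_b = exposed_mask(asa_b, threshold)
    if not mask_a.any() or not mask_b.any():
        raise EmptyInterfaceError(
            f"{p.dimer_id}: empty interface at threshold {threshold} "
            f"(exposed columns: A={int(mask_a.sum())}, B={int(mask_b.sum())})"
        )
    return ERMSAPair(
        dimer_id=p.dimer_id,
        threshold=threshold,
        family_a_exposed=_restrict_columns(p.family_a, mask_a),
        family_b_exposed=_restrict_columns(p.family_b, mask_b),
        column_map_a=np.flatnonzero(mask_a),
        column_map_b=np.flatnonzero(mask_b),
    )


def all_columns_ermsa(p: PairedMSA) -> ERMSAPair:
    """The trivial restriction keeping every column (threshold sentinel -1).

    Useful for computing a full-width covariation matrix once and slicing
    it per threshold: per-column-pair scores do not depend on which other
    columns were retained.
    """
    return ERMSAPair(
        dimer_id=p.dimer_id,
        threshold=-1.0,
        family_a_exposed=p.family_a,
        family_b_exposed=p.family_b,
        column_map_a=np.arange(p.family_a.width),
        column_map_b=np.arange(p.family_b.width),
    )


# --- tabular IO ------------------------------------------------------------


def read_asa_tsv(path: str | Path) -> dict[str, list[ASAProfile]]:
    """Read predictor RSA profiles from a TSV.

    Columns: protein_id, position (1-based over the query sequence),
    predictor, rsa_value.  Returns one profile per (protein, predictor);
    positions must cover 1..length for each pair.
    """
    raw: dict[tuple[str, str], dict[int, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "protein_id":
                continue
            if len(row) != 4:
                raise AsaError(f"ASA row needs 4 fields, got {row!r}")
            key = (row[0], row[2])
            raw.setdefault(key, {})[int(row[1])] = float(row[3])
    out: dict[str, list[ASAProfile]] = {}
    for (protein, predictor), positions in raw.items():
        length = max(positions)
        if sorted(positions) != list(range(1, length + 1)):
            raise AsaError(
                f"{protein}/{predictor}: positions must cover 1..{length} "
                "without holes"
            )
        values = np.array([positions[i] for i in range(1, length + 1)])
        out.setdefault(protein, []).append(
            ASAProfile(protein_id=protein, values=values)
        )
    return out


def write_asa_tsv(
    path: str | Path, profiles: dict[str, Sequence[ASAProfile]],
    predictor_names: dict[str, Sequence[str]] | None = None,
) -> None:
    """Write profiles in the schema accepted by :func:`read_asa_tsv`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "position", "predictor", "rsa_value"])
        for protein, plist in profiles.items():
            names = (
                predictor_names.get(protein)
                if predictor_names
                else None
            ) or [f"pred{k + 1}" for k in range(len(plist))]
            for name, prof in zip(names, plist):
                for i, v in enumerate(prof.values, start=1):
                    w.writerow([protein, i, name, f"{v:.6f}"])
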