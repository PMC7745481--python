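"""Dataset-construction gates.

Reusable implementations of the filters used to assemble the dimer
dataset: per-hit homolog filtration (sequence length, identity, bit
score, e-value, alignment overlap), the geometric-mean dimer-length
gate, the alignment-depth gate, the N/L shallowness descriptor, and
GO-term identity statistics used to audit orthology.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .msa import PairedMSA, AlignedFamily

GO_ASPECTS = ("molecular_function", "biological_process", "cellular_component")

#: fixed order in which filtration criteria are checked; a rejected hit
#: is labelled with the first criterion it fails.
CRITERIA_ORDER = ("length", "identity", "bit_score", "e_value", "overlap")


class FilterError(ValueError):
    """Raised for malformed hits, policies or annotation tables."""


@dataclass(frozen=True)
class HomologHit:
    """One homolog-search hit (blast-style tabular row plus lengths)."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_length: int
    bit_score: float
    e_value: float
    query_length: int
    subject_length: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity_pct <= 100.0:
            raise FilterError(
                f"{self.query_id}/{self.subject_id}: identity_pct "
                f"{self.identity_pct} outside [0, 100]"
            )
        if min(self.align_length, self.query_length, self.subject_length) < 1:
            raise FilterError(
                f"{self.query_id}/{self.subject_id}: lengths must be >= 1"
            )
        if not self.e_value > 0:
            raise FilterError(
                f"{self.query_id}/{self.subject_id}: e_value must be > 0"
            )


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds of the homolog filtration criteria.

    Defaults are the standard gates: subject length at least 80% of the
    query, identity at least 40%, bit score at least 0.5 x query length,
    e-value below 1e-4, and alignment overlap covering at least 90% of
    the query.  ``relaxed()`` builds the alternative "special cases"
    policy; relaxation is always caller-selected, never automatic.
    """

    min_length_frac: float = 0.80
    min_identity_pct: float = 40.0
    bit_score_coef: float = 0.5
    max_evalue: float = 1e-4
    min_overlap_frac: float = 0.90
    relaxed: bool = False

    #: identity / overlap alternates permitted under the relaxed policy
    RELAXED_IDENTITY = (25.0, 30.0, 35.0)
    RELAXED_OVERLAP = (0.70, 0.80, 0.85)

    def __post_init__(self) -> None:
        for name in ("min_length_frac", "min_overlap_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise FilterError(f"{name}={v} outside (0, 1]")
        if self.bit_score_coef <= 0 or self.max_evalue <= 0:
            raise FilterError("bit_score_coef and max_evalue must be > 0")
        if not 0.0 <= self.min_identity_pct <= 100.0:
            raise FilterError("min_identity_pct outside [0, 100]")

    @classmethod
    def default(cls) -> "FilterPolicy":
        return cls()

    @classmethod
    def make_relaxed(
        cls, min_identity_pct: float = 25.0, min_overlap_frac: float = 0.70
    ) -> "FilterPolicy":
        """The "special cases" alternates: 78% length, looser identity
        (25/30/35%), 0.45 x length bit score, and looser overlap
        (70/80/85%)."""
        if min_identity_pct not in cls.RELAXED_IDENTITY:
            raise FilterError(
                f"relaxed identity must be one of {cls.RELAXED_IDENTITY}"
            )
        if min_overlap_frac not in cls.RELAXED_OVERLAP:
            raise FilterError(
                f"relaxed overlap must be one of {cls.RELAXED_OVERLAP}"
            )
        return cls(
            min_length_frac=0.78,
            min_identity_pct=min_identity_pct,
            bit_score_coef=0.45,
            max_evalue=1e-4,
            min_overlap_frac=min_overlap_frac,
            relaxed=True,
        )


def _first_failure(hit: HomologHit, policy: FilterPolicy) -> Optional[str]:
    if hit.subject_length < policy.min_length_frac * hit.query_length:
        return "length"
    if hit.identity_pct < policy.min_identity_pct:
        return "identity"
    # "monomer sequence length" read as the QUERY length
    if hit.bit_score < policy.bit_score_coef * hit.query_length:
        return "bit_score"
    if not hit.e_value < policy.max_evalue:
        return "e_value"
    if hit.align_length / hit.query_length < policy.min_overlap_frac:
        return "overlap"
    return None


def filter_hits(
    hits: Sequence[HomologHit], policy: FilterPolicy | None = None
) -> tuple[list[HomologHit], list[Optional[str]]]:
    """Apply all five filtration criteria to each hit.

    Returns the kept hits and a per-hit list of rejection reasons
    (``None`` for kept hits; otherwise the first failing criterion in
    the fixed order length, identity, bit_score, e_value, overlap).
    """
    policy = policy or FilterPolicy()
    reasons = [_first_failure(h, policy) for h in hits]
    kept = [h for h, r in zip(hits, reasons) if r is None]
    return kept, reasons


def dimer_length(l1: int, l2: int) -> tuple[float, bool]:
    """Dimer length L = sqrt(l1 * l2) and the [90, 550] keep gate.

    Dimers with L below 90 or above 550 are removed; the boundaries are
    kept (inclusive).
    """
    if l1 < 1 or l2 < 1:
        raise FilterError("protein lengths must be >= 1")
    L = math.sqrt(l1 * l2)
    return L, 90.0 <= L <= 550.0


def depth_stats(p: PairedMSA) -> tuple[int, float, float, bool]:
    """Depth N, dimer length L, shallowness N/L, and the N >= 50 gate."""
    n = p.n
    L, _ = dimer_length(p.family_a.width, p.family_b.width)
    return n, L, n / L, n >= 50


# --- GO identity -----------------------------------------------------------


@dataclass
class GOAnnotationTable:
    """Per-sequence GO term sets, keyed by aspect, in alignment row order."""

    ids: list[str]
    annotations: list[dict[str, frozenset[str]]]
    organism_known: list[bool]

    def __post_init__(self) -> None:
        if not (len(self.ids) == len(self.annotations) == len(self.organism_known)):
            raise FilterError("GO table columns have inconsistent lengths")
        for ann in self.annotations:
            for aspect in ann:
                if aspect not in GO_ASPECTS:
                    raise FilterError(f"unknown GO aspect {aspect!r}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    def unknown_fraction(self) -> float:
        if not self.organism_known:
            return 0.0
        return sum(not k for k in self.organism_known) / len(self.organism_known)


def go_identity_frequency(
    table: GOAnnotationTable, query_index: int, aspect: str
) -> tuple[float, bool]:
    """Fraction of non-query sequences sharing >= 1 GO term with the query.

    ``evaluable`` is False when more than 15% of the organisms in the
    table are unknown, in which case the frequency should not enter
    orthology statistics.
    """
    if aspect not in GO_ASPECTS:
        raise FilterError(f"unknown GO aspect {aspect!r}")
    if table.n_sequences == 0:
        raise FilterError("empty GO table")
    if not 0 <= query_index < table.n_sequences:
        raise FilterError("query_index out of range")
    query_terms = table.annotations[query_index].get(aspect, frozenset())
    if not query_terms:
        raise FilterError(
            f"query sequence has no annotation in aspect {aspect!r}"
        )
    others = [
        ann.get(aspect, frozenset())
        for k, ann in enumerate(table.annotations)
        if k != query_index
    ]
    if not others:
        raise FilterError("GO table contains only the query sequence")
    shared = sum(bool(terms & query_terms) for terms in others)
    rel_freq = shared / len(others)
    evaluable = table.unknown_fraction() <= 0.15
    return rel_freq, evaluable


def drop_sequences(p: PairedMSA, exclude_species: Iterable[str]) -> PairedMSA:
    """Remove matched rows by species label from both families.

    Hook for externally supplied outlier lists: outlier detection itself
    is not implemented here, only the removal of a given exclusion set
    (the query row can never be removed).
    """
    exclude = set(exclude_species)
    keep = [
        k
        for k, sp in enumerate(p.family_a.species)
        if sp not in exclude or k == p.family_a.query_index
    ]
    if len(keep) == p.n:
        return p

    def restrict(f: AlignedFamily) -> AlignedFamily:
        return AlignedFamily(
            family_id=f.family_id,
            sequences=[f.sequences[k] for k in keep],
            species=[f.species[k] for k in keep],
            query_index=keep.index(f.query_index),
        )

    return PairedMSA(
        dimer_id=p.dimer_id,
        family_a=restrict(p.family_a),
        family_b=restrict(p.family_b),
        label=p.label,
    )


# --- tabular IO ------------------------------------------------------------

HIT_COLUMNS = (
    "query_id",
    "subject_id",
    "identity_pct",
    "align_length",
    "bit_score",
    "e_value",
    "query_length",
    "subject_length",
)


def read_hit_table(path: str | Path) -> list[HomologHit]:
    """Read a TSV of homolog hits (blast outfmt-6 order plus two length
    columns); a header row naming the columns is optional."""
    hits = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "query_id":
                continue
            if len(row) != len(HIT_COLUMNS):
                raise FilterError(
                    f"hit row has {len(row)} fields, expected {len(HIT_COLUMNS)}: {row!r}"
                )
            hits.append(
                HomologHit(
                    query_id=row[0],
                    subject_id=row[1],
                    identity_pct=float(row[2]),
                    align_length=int(row[3]),
                    bit_score=float(row[4]),
                    e_value=float(row[5]),
                    query_length=int(row[6]),
                    subject_length=int(row[7]),
                )
            )
    return hits


def read_go_table(path: str | Path) -> GOAnnotationTable:
    """Read a GO TSV: sequence id, aspect, term id[, known|unknown].

    Sequence order follows first appearance in the file.
    """
    ids: list[str] = []
    index: dict[str, int] = {}
    anns: list[dict[str, set[str]]] = []
    known: list[bool] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            seq_id, aspect, term = row[0], row[1], row[2]
            if aspect not in GO_ASPECTS:
                raise FilterError(f"unknown GO aspect {aspect!r} in {path}")
            if seq_id not in index:
                index[seq_id] = len(ids)
                ids.append(seq_id)
                anns.append({})
                known.append(True)
            k = index[seq_id]
            anns[k].setdefault(aspect, set()).add(term)
            if len(row) > 3 and row[3].lower() == "unknown":
                known[k] = False
    return GOAnnotationTable(
        ids=ids,
        annotations=[
            {a: frozenset(t) for a, t in ann.items()} for ann in anns
        ],
        organism_known=known,
    )
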