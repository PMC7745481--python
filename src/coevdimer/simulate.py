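"""Synthetic dimer datasets with planted inter-protein covariation.

The generator emulates the study conditions the pipeline is built for:
a balanced set of 83 positive and 83 negative dimers; shallow paired
alignments (N between 50 and 950 matched rows); per-protein widths
giving dimer lengths L = sqrt(l1 l2) inside the [90, 550] gate; gap
characters sprinkled at a low per-cell rate; and RSA profiles spread
over [0, 1] so every ASA threshold keeps a nonempty, strictly shrinking
exposed-column set.

Positive dimers carry *planted covariation*: a fraction of column pairs
(one column in each family) evolve through a paired-state substitution
table — each sequence draws the family-A residue from the column's
background distribution and, with probability ``coupling_strength``,
the family-B partner is the image of that residue under a pair-specific
permutation of the 20 amino acids; otherwise the partner is drawn
independently.  Negative dimers have fully independent columns.  Both
classes share the same depth, width, background and gap distributions,
so covariation is the only signal separating them.

This is deliberately not a phylogenetic or Potts-model simulator: it
plants mutual information with a known, seedable mechanism and nothing
else.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .asa import ASAProfile, write_asa_tsv
from .filters import GOAnnotationTable, GO_ASPECTS
from .msa import ALPHABET, GAP_CODE, AlignedFamily, PairedMSA, write_family


class SimulationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generator settings; defaults are the study conditions.

    ``coupling_fraction`` is the fraction of min(l1, l2) column pairs
    that co-evolve in positive dimers; ``coupling_strength`` is the
    probability that a coupled partner follows the paired-state table
    rather than mutating independently.  ``alphabet_concentration`` is
    the Dirichlet concentration of the per-column background residue
    distribution (values < 1 give realistic partially conserved
    columns).
    """

    n_positive: int = 83
    n_negative: int = 83
    depth_range: tuple[int, int] = (50, 950)
    width_range: tuple[int, int] = (90, 180)
    coupling_fraction: float = 0.3
    coupling_strength: float = 0.9
    gap_rate: float = 0.05
    alphabet_concentration: float = 0.5
    #: RSA mixture: buried component Beta(2, 8) with this weight,
    #: exposed component Beta(4, 2) with the rest
    asa_buried_weight: float = 0.35
    seed: int = 0
    strict_gates: bool = True

    def __post_init__(self) -> None:
        if min(self.n_positive, self.n_negative) < 1:
            raise SimulationError("need at least one dimer per class")
        for name in ("coupling_fraction", "coupling_strength", "gap_rate",
                     "asa_buried_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.depth_range
        if not 1 <= lo <= hi:
            raise SimulationError(f"bad depth_range {self.depth_range}")
        wlo, whi = self.width_range
        if not 1 <= wlo <= whi:
            raise SimulationError(f"bad width_range {self.width_range}")
        if self.alphabet_concentration <= 0:
            raise SimulationError("alphabet_concentration must be > 0")
        if self.strict_gates:
            if lo < 50:
                raise SimulationError(
                    "depth_range violates the N >= 50 gate (strict_gates on)"
                )
            if wlo < 90 or whi > 550:
                raise SimulationError(
                    "width_range violates the L in [90, 550] gate "
                    "(strict_gates on)"
                )


_CHAR_LUT = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    return [bytes(_CHAR_LUT[row]).decode("ascii") for row in codes]


def _sample_family_codes(
    rng: np.random.Generator, n_seq: int, width: int, concentration: float
) -> np.ndarray:
    """(n_seq, width) residue codes 0..19, column-specific backgrounds."""
    probs = rng.dirichlet(np.full(20, concentration), size=width)  # (width, 20)
    cum = probs.cumsum(axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n_seq, width))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2).astype(np.uint8)


def generate_asa_profiles(
    widths: tuple[int, int],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    protein_ids: tuple[str, str] = ("protA", "protB"),
) -> tuple[ASAProfile, ASAProfile]:
    """RSA profiles from a buried/exposed beta mixture.

    The mixture (Beta(2, 8) buried, Beta(4, 2) exposed) keeps the
    expected exposed fraction strictly decreasing across the threshold
    ladder while leaving a healthy exposed set even at 0.75.
    """
    if min(widths) < 1:
        raise SimulationError("widths must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    for pid, w in zip(protein_ids, widths):
        buried = rng.random(w) < cfg.asa_buried_weight
        vals = np.where(buried, rng.beta(2.0, 8.0, size=w), rng.beta(4.0, 2.0, size=w))
        out.append(ASAProfile(protein_id=pid, values=np.clip(vals, 0.0, 1.0)))
    return out[0], out[1]


def _generate_dimer(
    rng: np.random.Generator, cfg: SimulationConfig, dimer_id: str, label: str
) -> tuple[PairedMSA, ASAProfile, ASAProfile]:
    lo, hi = cfg.depth_range
    n_seq = int(rng.integers(lo, hi + 1))
    wlo, whi = cfg.width_range
    l1 = int(rng.integers(wlo, whi + 1))
    l2 = int(rng.integers(wlo, whi + 1))

    codes_a = _sample_family_codes(rng, n_seq, l1, cfg.alphabet_concentration)
    codes_b = _sample_family_codes(rng, n_seq, l2, cfg.alphabet_concentration)

    if label == "positive" and cfg.coupling_fraction > 0:
        k = int(round(cfg.coupling_fraction * min(l1, l2)))
        k = min(k, l1, l2)
        cols_a = rng.choice(l1, size=k, replace=False)
        cols_b = rng.choice(l2, size=k, replace=False)
        for ia, ib in zip(cols_a, cols_b):
            perm = rng.permutation(20).astype(np.uint8)
            follow = rng.random(n_seq) < cfg.coupling_strength
            codes_b[follow, ib] = perm[codes_a[follow, ia]]

    # gaps everywhere except the query row (row 0)
    for codes in (codes_a, codes_b):
        gaps = rng.random(codes.shape) < cfg.gap_rate
        gaps[0, :] = False
        codes[gaps] = GAP_CODE

    species = [f"sp{k + 1:04d}" for k in range(n_seq)]
    fam_a = AlignedFamily(
        family_id=f"{dimer_id}_A",
        sequences=_codes_to_strings(codes_a),
        species=species,
        query_index=0,
    )
    fam_b = AlignedFamily(
        family_id=f"{dimer_id}_B",
        sequences=_codes_to_strings(codes_b),
        species=list(species),
        query_index=0,
    )
    pmsa = PairedMSA(
        dimer_id=dimer_id, family_a=fam_a, family_b=fam_b, label=label
    )
    asa_a, asa_b = generate_asa_profiles(
        (l1, l2), cfg, rng=rng,
        protein_ids=(f"{dimer_id}_A", f"{dimer_id}_B"),
    )
    return pmsa, asa_a, asa_b


def generate_dimer_set(
    cfg: SimulationConfig,
) -> tuple[list[PairedMSA], list[tuple[ASAProfile, ASAProfile]]]:
    """Generate the labeled dimer set and matching RSA profile pairs.

    Positives come first (pos0001..), then negatives; everything is
    reproducible from ``cfg.seed`` alone.
    """
    rng = np.random.default_rng(cfg.seed)
    dimers: list[PairedMSA] = []
    profiles: list[tuple[ASAProfile, ASAProfile]] = []
    for k in range(cfg.n_positive):
        p, a, b = _generate_dimer(rng, cfg, f"pos{k + 1:04d}", "positive")
        dimers.append(p)
        profiles.append((a, b))
    for k in range(cfg.n_negative):
        p, a, b = _generate_dimer(rng, cfg, f"neg{k + 1:04d}", "negative")
        dimers.append(p)
        profiles.append((a, b))
    return dimers, profiles


def generate_go_table(
    n_sequences: int,
    identity_frequency: float = 0.8,
    unknown_fraction: float = 0.0,
    seed: int = 0,
) -> GOAnnotationTable:
    """A synthetic GO table whose non-query rows share a term with the
    query at the given frequency, to exercise GO-identity statistics."""
    rng = np.random.default_rng(seed)
    ids = [f"sp{k + 1:04d}" for k in range(n_sequences)]
    anns = []
    for k in range(n_sequences):
        ann = {}
        for a_idx, aspect in enumerate(GO_ASPECTS):
            shared = f"GO:{a_idx:07d}"
            if k == 0 or rng.random() < identity_frequency:
                ann[aspect] = frozenset({shared})
            else:
                ann[aspect] = frozenset({f"GO:{a_idx}{k:06d}"})
        anns.append(ann)
    known = [bool(rng.random() >= unknown_fraction) for _ in range(n_sequences)]
    known[0] = True
    return GOAnnotationTable(ids=ids, annotations=anns, organism_known=known)


def write_dataset(
    dimers: Sequence[PairedMSA],
    profiles: Sequence[tuple[ASAProfile, ASAProfile]],
    out_dir: str | Path,
    cfg: Optional[SimulationConfig] = None,
    format: str = "fasta",
) -> Path:
    """Write a generated dataset as FASTA/Clustal pairs, RSA TSVs and a
    manifest JSON consumable by the pipeline."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = "fa" if format == "fasta" else "aln"
    entries = []
    for p, (asa_a, asa_b) in zip(dimers, profiles):
        path_a = out / f"{p.dimer_id}_A.{ext}"
        path_b = out / f"{p.dimer_id}_B.{ext}"
        asa_path = out / f"{p.dimer_id}_asa.tsv"
        write_family(p.family_a, path_a, format)
        write_family(p.family_b, path_b, format)
        write_asa_tsv(
            asa_path,
            {asa_a.protein_id: [asa_a], asa_b.protein_id: [asa_b]},
        )
        entries.append(
            {
                "dimer_id": p.dimer_id,
                "label": p.label,
                "msa_a": path_a.name,
                "msa_b": path_b.name,
                "format": format,
                "asa": asa_path.name,
                "asa_id_a": asa_a.protein_id,
                "asa_id_b": asa_b.protein_id,
            }
        )
    manifest = {
        "dimers": entries,
        "config": asdict(cfg) if cfg else None,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
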