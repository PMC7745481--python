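"""End-to-end workflow orchestration.

``run_pipeline`` drives the whole chain for a manifest of dimers:
paired-MSA loading and validation, RSA averaging, ER-MSA extraction per
ASA threshold, covariation matrices, Frobenius norms, and — when labels
are present — the SVM discrimination protocol.  Every stage writes
stable filenames under the run directory and a manifest records the
configuration hash and seed, so a rerun with the same config reproduces
the norm table bit-for-bit.

``synthetic_norm_table`` and ``evaluate_feature_sets`` are the in-memory
equivalents used for simulation studies, where writing thousands of
intermediate matrices would be pointless.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .asa import (
    ASAProfile,
    DEFAULT_THRESHOLDS,
    average_asa_profiles,
    extract_ermsa,
    read_asa_tsv,
)
from .classify import EvaluationReport, SplitPlan, train_eval_protocol
from .covariation import (
    clr_transform,
    mi_matrices,
    mip_transform,
    read_ccmpred_matrix,
    write_matrix_tsv,
)
from .features import (
    build_feature_table,
    compute_dimer_norms,
    feature_range,
    save_norm_table,
)
from .msa import PairedMSA, read_paired_msa, write_family
from .simulate import SimulationConfig, generate_dimer_set

logger = logging.getLogger("coevdimer")


class PipelineError(RuntimeError):
    """A stage failed; the message names the dimer and stage."""


@dataclass
class PipelineConfig:
    """Declarative configuration for one run."""

    manifest: str
    out_dir: str
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    methods: tuple[str, ...] = ("MI", "nMI", "MIp", "CLR")
    feature_method: Optional[str] = None  # method used for classification
    feature_start: float = 0.0  # feature group [start, 0.75]
    seed: int = 0
    save_ermsa: bool = True
    save_matrices: bool = True
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise PipelineError(f"{path}: config must be a mapping")
    for key in ("thresholds", "methods"):
        if key in data:
            data[key] = tuple(data[key])
    return PipelineConfig(**data)


def _load_manifest(path: Path) -> list[dict]:
    data = json.loads(path.read_text())
    dimers = data.get("dimers")
    if not dimers:
        raise PipelineError(f"{path}: manifest lists no dimers")
    return dimers


def _load_dimer(entry: dict, base: Path) -> tuple[PairedMSA, ASAProfile, ASAProfile]:
    dimer_id = entry.get("dimer_id", "<unnamed>")
    for key in ("msa_a", "msa_b", "asa"):
        if key not in entry:
            raise PipelineError(f"dimer {dimer_id}: manifest entry lacks {key!r}")
        if not (base / entry[key]).exists():
            raise PipelineError(
                f"dimer {dimer_id}: missing file {entry[key]!r}"
            )
    p = read_paired_msa(
        base / entry["msa_a"],
        base / entry["msa_b"],
        format=entry.get("format", "fasta"),
        dimer_id=dimer_id,
        label=entry.get("label"),
    )
    profiles = read_asa_tsv(base / entry["asa"])
    try:
        asa_a = average_asa_profiles(profiles[entry["asa_id_a"]])
        asa_b = average_asa_profiles(profiles[entry["asa_id_b"]])
    except KeyError as exc:
        raise PipelineError(f"dimer {dimer_id}: ASA id {exc} not in {entry['asa']}")
    return p, asa_a, asa_b


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the full workflow for a manifest; returns the run directory."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(cfg.manifest)
    entries = _load_manifest(manifest_path)
    base = manifest_path.parent

    norms = []
    for entry in entries:
        t_start = time.perf_counter()
        dimer_id = entry.get("dimer_id", "<unnamed>")
        try:
            p, asa_a, asa_b = _load_dimer(entry, base)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"dimer {dimer_id}: load failed: {exc}") from exc

        ccm = None
        if "CCMpred" in cfg.methods:
            raw_paths = entry.get("ccmpred", {})
            ccm = {}
            for t in cfg.thresholds:
                key = str(t)
                if key not in raw_paths:
                    raise PipelineError(
                        f"dimer {dimer_id}: no CCMpred matrix for threshold {t}"
                    )
                ccm[t] = read_ccmpred_matrix(base / raw_paths[key])

        try:
            if cfg.save_ermsa or cfg.save_matrices:
                _save_stage_outputs(cfg, out, p, asa_a, asa_b)
            df = compute_dimer_norms(
                p, asa_a, asa_b,
                thresholds=cfg.thresholds,
                methods=cfg.methods,
                ccmpred_raw=ccm,
            )
        except Exception as exc:
            raise PipelineError(
                f"dimer {dimer_id}: covariation stage failed: {exc}"
            ) from exc
        norms.append(df)
        logger.info(
            "dimer %s: norms done in %.2fs", dimer_id,
            time.perf_counter() - t_start,
        )

    norm_table = pd.concat(norms, ignore_index=True)
    norm_table = norm_table.sort_values(
        ["dimer_id", "method", "threshold"]
    ).reset_index(drop=True)
    save_norm_table(norm_table, out / "norms.tsv")

    report = None
    labels = norm_table["label"].dropna().unique()
    if len(labels) == 2:
        method = cfg.feature_method or cfg.methods[0]
        table = build_feature_table(
            norm_table,
            methods=[method],
            thresholds=feature_range(cfg.feature_start, thresholds=cfg.thresholds),
        )
        try:
            report = train_eval_protocol(
                table, SplitPlan(random_seed=cfg.seed)
            )
            (out / "report.json").write_text(report.to_json(indent=2))
        except Exception as exc:
            logger.warning("classification skipped: %s", exc)

    run_manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "n_dimers": len(entries),
        "outputs": {
            "norms": "norms.tsv",
            "report": "report.json" if report is not None else None,
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return out


def _save_stage_outputs(cfg, out: Path, p, asa_a, asa_b) -> None:
    er_dir = out / "ermsa"
    mat_dir = out / "matrices"
    for t in cfg.thresholds:
        e = extract_ermsa(p, asa_a, asa_b, t)
        tag = f"{p.dimer_id}_t{t:g}"
        if cfg.save_ermsa:
            er_dir.mkdir(parents=True, exist_ok=True)
            write_family(e.family_a_exposed, er_dir / f"{tag}_A.fa", "fasta")
            write_family(e.family_b_exposed, er_dir / f"{tag}_B.fa", "fasta")
        if cfg.save_matrices:
            mat_dir.mkdir(parents=True, exist_ok=True)
            mi, nmi = mi_matrices(e)
            for mat in (mi, nmi, mip_transform(nmi), clr_transform(nmi)):
                if mat.method in cfg.methods:
                    write_matrix_tsv(mat, mat_dir / f"{tag}_{mat.method}.tsv")


# --- simulation studies ----------------------------------------------------


def synthetic_norm_table(
    sim_cfg: SimulationConfig,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    methods: Sequence[str] = ("MIp",),
) -> pd.DataFrame:
    """Generate a synthetic dimer set and compute its norm table in memory."""
    dimers, profiles = generate_dimer_set(sim_cfg)
    frames = [
        compute_dimer_norms(p, a, b, thresholds=thresholds, methods=methods)
        for p, (a, b) in zip(dimers, profiles)
    ]
    return pd.concat(frames, ignore_index=True)


def evaluate_feature_sets(
    norm_table: pd.DataFrame,
    method: str,
    seed: int,
    feature_starts: Sequence[float] = (0.0,),
    single_thresholds: Sequence[float] = (),
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[str, EvaluationReport]:
    """Run the discrimination protocol for multiple- and single-feature
    models over one norm table.

    Keys are ``multi:<start>-0.75`` for contiguous groups and
    ``single:<t>`` for single-threshold models.
    """
    reports: dict[str, EvaluationReport] = {}
    plan = SplitPlan(random_seed=seed)
    for start in feature_starts:
        group = feature_range(start, thresholds=thresholds)
        table = build_feature_table(norm_table, methods=[method], thresholds=group)
        reports[f"multi:{start:g}-0.75"] = train_eval_protocol(table, plan)
    for t in single_thresholds:
        table = build_feature_table(norm_table, methods=[method], thresholds=[t])
        reports[f"single:{t:g}"] = train_eval_protocol(table, plan)
    return reports
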