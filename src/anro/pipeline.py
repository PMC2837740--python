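"""End-to-end driver: simulate/ingest -> preprocess -> DE -> waves -> GSMA ->
concordance -> direct targets, under one configuration with a reproducible
run manifest.

Every stage writes plain TSV/GMT/JSON artifacts into the run directory and
records each file's SHA-256 in the manifest, so a rerun with an identical
config and seed is verifiably hash-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform as _platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import concordance, differential, gsma, preprocess, simulate, timecourse
from .differential import SignificanceThresholds
from .simulate import SimConfig

__all__ = ["RunConfig", "validate_inputs", "run_pipeline"]

logger = logging.getLogger("anro")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``sim`` (synthetic experiment) or all three input paths
    (``nro_matrix``/``total_matrix``/``annotation``) must be given.  When
    simulating, gene sets, a second platform and a ChIP list are generated
    alongside unless disabled; for real inputs, ``gmt`` and ``chip_list``
    are optional files and their stages are skipped when absent.
    """

    outdir: Path
    sim: SimConfig | None = None
    nro_matrix: Path | None = None
    total_matrix: Path | None = None
    annotation: Path | None = None
    gmt: Path | None = None
    chip_list: Path | None = None
    baseline_hr: float = 0.0
    detection_threshold: float = preprocess.DETECTION_THRESHOLD
    thresholds: SignificanceThresholds = field(default_factory=SignificanceThresholds)
    gsma_universe: str = "all"  # 'all' or 'de'
    gsma_sort_z: float = 2.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.sim is None and not (self.nro_matrix and self.total_matrix and self.annotation):
            raise ValueError("provide either a SimConfig or paths to both matrices and annotation")
        if self.gsma_universe not in ("all", "de"):
            raise ValueError("gsma_universe must be 'all' or 'de'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim_raw = dict(raw["sim"])
            if "wave_mix" in sim_raw:
                sim_raw["wave_mix"] = dict(sim_raw["wave_mix"])
            raw["sim"] = SimConfig(**sim_raw)
        if "thresholds" in raw:
            raw["thresholds"] = SignificanceThresholds(**raw["thresholds"])
        for key in ("nro_matrix", "total_matrix", "annotation", "gmt", "chip_list"):
            if raw.get(key):
                raw[key] = Path(raw[key])
        return cls(**raw)


def validate_inputs(
    matrix: preprocess.ExpressionMatrix,
    annotation: pd.DataFrame,
    thresholds: SignificanceThresholds | None = None,
) -> list[dict[str, str]]:
    """Machine-readable consistency report; empty list means clean."""
    issues: list[dict[str, str]] = []
    annotated = set(annotation["sample_id"])
    for sid in matrix.samples:
        if sid not in annotated:
            issues.append({"kind": "missing_annotation", "detail": f"sample {sid} has no annotation row"})
    dup = annotation["sample_id"][annotation["sample_id"].duplicated()]
    for sid in dup:
        issues.append({"kind": "duplicate_annotation", "detail": f"sample {sid} annotated more than once"})
    vals = matrix.intensities.to_numpy()
    if np.any(vals <= 0):
        gi, si = np.argwhere(vals <= 0)[0]
        issues.append(
            {
                "kind": "nonpositive_intensity",
                "detail": f"gene {matrix.genes[gi]} sample {matrix.samples[si]} has non-positive intensity",
            }
        )
    if matrix.genes.has_duplicates:
        issues.append({"kind": "duplicate_symbols", "detail": "gene symbols are not unique; average duplicates first"})
    tps = annotation.loc[annotation["sample_id"].isin(matrix.samples), "timepoint_hr"]
    if len(tps) and tps.min() != 0.0:
        issues.append({"kind": "no_baseline", "detail": "no 0-hr baseline timepoint in annotation"})
    if thresholds is not None:
        for name in ("p_max", "fdr_max", "fold_min", "zratio_min"):
            if getattr(thresholds, name) <= 0:
                issues.append({"kind": "bad_threshold", "detail": f"{name} must be positive"})
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, config: RunConfig):
        self.data: dict[str, Any] = {
            "tool": "anro",
            "version": __version__,
            "python": _platform.python_version(),
            "seed": config.seed,
            "parameters": _echo_params(config),
            "stages": {},
        }

    def record(self, stage: str, files: dict[str, Path], status: str = "completed", **extra: Any) -> None:
        self.data["stages"][stage] = {
            "status": status,
            "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()},
            **extra,
        }

    def skip(self, stage: str, reason: str) -> None:
        self.data["stages"][stage] = {"status": "skipped", "reason": reason, "outputs": {}}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")


def _echo_params(config: RunConfig) -> dict[str, Any]:
    thr = config.thresholds
    out: dict[str, Any] = {
        "baseline_hr": config.baseline_hr,
        "detection_threshold": config.detection_threshold,
        "thresholds": {"p_max": thr.p_max, "fdr_max": thr.fdr_max, "fold_min": thr.fold_min, "zratio_min": thr.zratio_min},
        "gsma_universe": config.gsma_universe,
        "gsma_sort_z": config.gsma_sort_z,
    }
    if config.sim is not None:
        sim = config.sim
        out["sim"] = {
            "n_genes": sim.n_genes,
            "timepoints_hr": list(sim.timepoints_hr),
            "replicates_per_timepoint": sim.replicates_per_timepoint,
            "replicate_overrides": {str(k): v for k, v in sim.replicate_overrides.items()},
            "fraction_regulated": sim.fraction_regulated,
            "wave_mix": dict(sim.wave_mix),
            "effect_log2": sim.effect_log2,
            "lag_steps": sim.lag_steps,
            "noise_sd_log": sim.noise_sd_log,
            "fraction_background": sim.fraction_background,
            "seed": sim.seed,
        }
    return out


def _write_tsv(df: pd.DataFrame, path: Path, index_name: str = "gene") -> Path:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
    return path


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure raises with the stage name attached.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest = _Manifest(config)
    stage = "ingest"
    try:
        # ---- stage 1: simulate or ingest -------------------------------
        if config.sim is not None:
            stage = "simulate"
            sim = SimConfig(**{**config.sim.__dict__, "seed": config.seed})
            nro, total, annot, truth = simulate.generate_experiment(sim)
            files = {}
            for name, mat in (("nro", nro), ("total", total)):
                mat.to_tsv(outdir / f"{name}_intensities.tsv", outdir / f"{name}_detection.tsv")
                files[f"{name}_intensities"] = outdir / f"{name}_intensities.tsv"
                files[f"{name}_detection"] = outdir / f"{name}_detection.tsv"
            preprocess.write_annotation(annot, outdir / "annotation.tsv")
            files["annotation"] = outdir / "annotation.tsv"
            files["truth"] = _write_tsv(truth, outdir / "truth.tsv")
            manifest.record("simulate", files)
        else:
            nro = preprocess.ExpressionMatrix.from_tsv(config.nro_matrix, rna_source="NRO")
            total = preprocess.ExpressionMatrix.from_tsv(config.total_matrix, rna_source="TOTAL")
            annot = preprocess.read_annotation(config.annotation)
            truth = None
            manifest.record("ingest", {})

        stage = "validate"
        issues = validate_inputs(nro, annot, config.thresholds) + validate_inputs(total, annot)
        if issues:
            raise ValueError(f"input validation failed: {issues}")

        # ---- stage 2: preprocess ---------------------------------------
        stage = "preprocess"
        z_mats, logratios, filtered = {}, {}, {}
        files = {}
        for name, mat in (("nro", nro), ("total", total)):
            fmat = (
                preprocess.filter_undetected(mat, config.detection_threshold)
                if mat.detection is not None
                else mat
            )
            filtered[name] = fmat
            z_mats[name] = preprocess.ztransform_array(fmat)
            logratios[name] = preprocess.log_ratio(fmat, annot, config.baseline_hr)
            files[f"{name}_zscores"] = _write_tsv(z_mats[name], outdir / f"{name}_zscores.tsv")
            files[f"{name}_logratios"] = _write_tsv(logratios[name], outdir / f"{name}_logratios.tsv")
        manifest.record("preprocess", files, n_genes={k: len(v.genes) for k, v in filtered.items()})

        # ---- stage 3: differential per timepoint -----------------------
        stage = "differential"
        de: dict[str, dict[float, pd.DataFrame]] = {}
        files = {}
        for name in ("nro", "total"):
            de[name] = differential.timepoint_de_tables(
                z_mats[name], filtered[name], annot, config.baseline_hr, config.thresholds
            )
            for t, tbl in de[name].items():
                p = _write_tsv(tbl, outdir / f"de_{name}_{t:g}h.tsv")
                files[f"de_{name}_{t:g}h"] = p
        manifest.record("differential", files)

        # ---- stage 4: waves --------------------------------------------
        stage = "waves"
        waves = timecourse.wave_table(de["nro"], de["total"])
        summary = timecourse.lead_lag(waves)
        files = {"wave_table": _write_tsv(waves, outdir / "wave_table.tsv")}
        manifest.record("waves", files, lead_summary=summary)

        # ---- stage 5: GSMA ---------------------------------------------
        stage = "gsma"
        collection = None
        if config.gmt is not None:
            collection = gsma.read_gmt(config.gmt)
        elif truth is not None and truth["regulated"].any():
            # scale planted-set size to the smallest usable wave-class pool
            class_sizes = truth.loc[truth["regulated"], "wave"].value_counts()
            set_size = int(min(20, class_sizes.max()))
            if set_size >= 2:
                collection = simulate.generate_genesets(
                    truth, n_planted=8, n_null=8, set_size=set_size, seed=config.seed + 1
                )
                gsma.write_gmt(collection, outdir / "genesets.gmt")
        if collection is None:
            manifest.skip("gsma", "no gene sets provided")
        else:
            lr_cols, meta_rows = {}, []
            for name in ("nro", "total"):
                for t in sorted(de[name]):
                    col = f"{name.upper()}_{t:g}h"
                    lr_cols[col] = logratios[name][t]
                    meta_rows.append(
                        {"contrast": col, "rna_source": name.upper(), "timepoint_hr": t}
                    )
            lr_table = pd.DataFrame(lr_cols)
            if config.gsma_universe == "de":
                keep = pd.Index([])
                for name in ("nro", "total"):
                    for tbl in de[name].values():
                        keep = keep.union(tbl.index[tbl["passes_filter"]])
                lr_table = lr_table.loc[lr_table.index.intersection(keep)]
            result = gsma.enrichment_significance(gsma.gsma_matrix(collection, lr_table))
            order = gsma.sort_by_first_appearance(
                result, pd.DataFrame(meta_rows), config.gsma_sort_z
            )
            result.z = result.z.loc[order]
            result.sm = result.sm.loc[order]
            result.m = result.m.loc[order]
            result.missing = result.missing.loc[order]
            result.p = result.p.loc[order]
            result.q = result.q.loc[order]
            result.to_tsv(outdir / "gsma.tsv")
            files = {"gsma": outdir / "gsma.tsv"}
            if (outdir / "genesets.gmt").exists():
                files["genesets"] = outdir / "genesets.gmt"
            manifest.record("gsma", files, row_order=order)

        # ---- stage 6: concordance --------------------------------------
        stage = "concordance"
        final_t = max(de["nro"])
        if truth is not None:
            a, b = simulate.generate_two_platforms(
                truth,
                shared_genes=min(len(truth), 2000),
                platform_noise_sd=max(float(simulate.steady_state_logratio(truth).std(ddof=0)), 1e-6),
                seed=config.seed + 2,
            )
            joined = concordance.join_platforms({"A": a, "B": b})
        else:
            joined = concordance.join_platforms(
                {"NRO": logratios["nro"][final_t], "TOTAL": logratios["total"][final_t]}
            )
        corr = concordance.correlation_matrix(joined)
        files = {
            "joined": _write_tsv(joined, outdir / "joined_logratios.tsv"),
            "correlation": _write_tsv(corr, outdir / "correlation_matrix.tsv", index_name="column"),
        }
        manifest.record("concordance", files)

        # ---- stage 7: direct targets -----------------------------------
        stage = "targets"
        if config.chip_list is not None:
            bound = concordance.read_gene_list(config.chip_list)
        elif truth is not None and truth["regulated"].any():
            bound = simulate.generate_chip_list(truth, coverage=0.8, n_decoys=100, seed=config.seed + 3)
        else:
            bound = None
        if bound is None:
            manifest.skip("targets", "no ChIP-bound gene list provided")
        else:
            final_nro = de["nro"][final_t]
            sig = final_nro[final_nro["passes_filter"]]
            up = sig.index[sig["direction"] == "up"]
            down = sig.index[sig["direction"] == "down"]
            targets = concordance.direct_targets(bound, up, down)
            concordance.write_gene_list(targets.up_targets, outdir / "direct_targets_up.txt")
            concordance.write_gene_list(targets.down_targets, outdir / "direct_targets_down.txt")
            manifest.record(
                "targets",
                {
                    "up": outdir / "direct_targets_up.txt",
                    "down": outdir / "direct_targets_down.txt",
                },
                n_up=len(targets.up_targets),
                n_down=len(targets.down_targets),
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    logger.info("pipeline complete: %s", outdir / "manifest.json")
    return manifest.data
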