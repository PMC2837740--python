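"""Detection filtering, per-array Z-score normalization, and baseline log-ratios.

Nuclear run-on (NRO) and total-RNA bead-array intensities arrive on a raw
positive scale with an optional per-gene, per-sample detection score ``D`` in
[0, 1].  The stages here are deliberately simple and order-dependent:

1. ``filter_undetected`` drops genes that never rise above background
   (``D`` below threshold in *every* sample).
2. ``ztransform_array`` standardizes ``log10`` intensities within each array
   independently (mean 0, sample SD 1), which removes per-array scale and
   brightness differences without any between-array fitting.
3. ``log_ratio`` computes per-gene ``log2`` ratios of raw-scale replicate
   means at each timepoint relative to the 0-hr baseline.

Z-scores drive the differential statistics; log-ratios drive fold changes,
heatmaps and gene-set enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_annotation",
    "write_annotation",
    "filter_undetected",
    "ztransform_array",
    "log_ratio",
]

#: RNA source labels accepted throughout the pipeline.
RNA_SOURCES = ("NRO", "TOTAL")

#: Default Illumina-style detection threshold.
DETECTION_THRESHOLD = 0.98


@dataclass
class ExpressionMatrix:
    """Genes x samples raw intensities with optional detection scores.

    Parameters
    ----------
    intensities
        DataFrame indexed by uppercase gene symbol, one column per sample,
        strictly positive raw-scale values.
    detection
        Optional DataFrame of the same shape with detection scores in [0, 1].
    rna_source
        ``"NRO"`` (nascent, nuclear run-on) or ``"TOTAL"`` (steady-state).
    platform
        Free-text platform label used in joins and output headers.
    """

    intensities: pd.DataFrame
    detection: pd.DataFrame | None = None
    rna_source: str = "TOTAL"
    platform: str = "synthetic"

    def __post_init__(self) -> None:
        if self.rna_source not in RNA_SOURCES:
            raise ValueError(f"rna_source must be one of {RNA_SOURCES}, got {self.rna_source!r}")
        if not np.all(self.intensities.to_numpy() > 0):
            raise ValueError("intensities must be strictly positive (log transform follows)")
        if self.detection is not None:
            if self.detection.shape != self.intensities.shape:
                raise ValueError("detection scores must match intensity matrix shape")
            d = self.detection.to_numpy()
            if np.any((d < 0) | (d > 1)):
                raise ValueError("detection scores must lie in [0, 1]")
        # normalize symbols once so every downstream join sees the same keys
        self.intensities = self.intensities.copy()
        self.intensities.index = self.intensities.index.astype(str).str.strip().str.upper()
        self.intensities.index.name = "gene"
        if self.detection is not None:
            self.detection = self.detection.copy()
            self.detection.index = self.intensities.index

    @property
    def genes(self) -> pd.Index:
        return self.intensities.index

    @property
    def samples(self) -> pd.Index:
        return self.intensities.columns

    def to_tsv(self, path: str | Path, detection_path: str | Path | None = None) -> None:
        """Write intensities (and optionally detection) as gene-rows TSV."""
        out = self.intensities.copy()
        out.index.name = "gene"
        # %.17g round-trips IEEE doubles exactly through text
        out.to_csv(path, sep="\t", float_format="%.17g")
        if detection_path is not None:
            if self.detection is None:
                raise ValueError("matrix has no detection scores to write")
            det = self.detection.copy()
            det.index.name = "gene"
            det.to_csv(detection_path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        detection_path: str | Path | None = None,
        rna_source: str = "TOTAL",
        platform: str = "unknown",
    ) -> "ExpressionMatrix":
        intens = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
        det = None
        if detection_path is not None:
            det = pd.read_csv(
                detection_path, sep="\t", index_col=0, float_precision="round_trip"
            )
            det = det.loc[intens.index, intens.columns]
        return cls(intensities=intens, detection=det, rna_source=rna_source, platform=platform)


ANNOTATION_COLUMNS = ["sample_id", "timepoint_hr", "replicate", "rna_source", "platform", "group"]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation is missing columns: {sorted(missing)}")
    return annot


def filter_undetected(
    matrix: ExpressionMatrix, threshold: float = DETECTION_THRESHOLD
) -> ExpressionMatrix:
    """Remove genes whose detection score is below ``threshold`` in every sample.

    A gene survives if it is detected (``D >= threshold``) in at least one
    sample; removal requires *consistent* background across the whole design.
    Row order is preserved.  Idempotent.
    """
    if matrix.detection is None:
        raise ValueError(
            "no detection scores on this matrix; skip the detection-filter stage"
        )
    keep = (matrix.detection.to_numpy() >= threshold).any(axis=1)
    return replace(
        matrix,
        intensities=matrix.intensities.loc[keep],
        detection=matrix.detection.loc[keep],
    )


def ztransform_array(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Standardize ``log10`` intensities within each array independently.

    Each column (array) is transformed as ``z = (log10 x - mean) / sd`` using
    the sample SD (n-1 denominator), so every output column has mean 0 and
    sample SD 1 by construction.  Arrays are treated on a stand-alone basis:
    no information is shared between samples.
    """
    if matrix.intensities.shape[0] < 2:
        raise ValueError("need at least 2 genes per array to standardize")
    logx = np.log10(matrix.intensities.to_numpy(dtype=float))
    mean = logx.mean(axis=0)
    sd = logx.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        bad = matrix.samples[np.flatnonzero(sd < 1e-12)].tolist()
        raise ValueError(f"zero within-array variance (degenerate arrays): {bad}")
    z = (logx - mean) / sd
    return pd.DataFrame(z, index=matrix.genes, columns=matrix.samples)


def log_ratio(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    baseline_timepoint: float = 0.0,
) -> pd.DataFrame:
    """Per-gene log2 ratio of raw-mean intensity at each timepoint vs baseline.

    Returns a genes x timepoints DataFrame whose baseline column is exactly 0.
    Means are taken across replicate arrays on the raw intensity scale; the
    ratio of means (not the mean of ratios) matches how fold changes are
    reported downstream.
    """
    annot = annotation[annotation["sample_id"].isin(matrix.samples)]
    timepoints = sorted(annot["timepoint_hr"].unique())
    if baseline_timepoint not in timepoints:
        raise ValueError(f"baseline timepoint {baseline_timepoint} absent from annotation")
    means = {}
    for t in timepoints:
        cols = annot.loc[annot["timepoint_hr"] == t, "sample_id"]
        means[t] = matrix.intensities[cols].mean(axis=1)
    base = means[baseline_timepoint]
    out = pd.DataFrame(
        {t: np.log2(means[t] / base) for t in timepoints}, index=matrix.genes
    )
    out.columns.name = "timepoint_hr"
    return out
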