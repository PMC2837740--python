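"""Z-ratio differential expression, significance filtering, and qPCR folds.

The Z-ratio statistic compares two groups of arrays that were each
standardized on a stand-alone basis (see :mod:`anro.preprocess`): for every
gene, take the difference of replicate-averaged z-scores,

    d_g = mean(z_A,g) - mean(z_B,g),

then divide each difference by the sample SD of *all* per-gene differences
in the comparison.  The denominator is shared across genes, so the vector of
Z-ratios has sample SD exactly 1 by construction — the statistic is
self-normalized against the comparison-wide noise floor.  This presumes that
most genes are unchanged; when a large fraction of the genome shifts
coordinately, the denominator inflates and power drops (a documented
property, not a bug).

Two-sided p-values come from the standard normal applied to the Z-ratio,
and q-values from Benjamini-Hochberg.  A gene is called significant by the
compound filter

    p <= 0.001  AND  q <= 0.1  AND  (|fold| >= 1.5  OR  |Z-ratio| >= 3.0),

with the fold clause evaluated on the raw intensity-ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr
from .preprocess import ExpressionMatrix

__all__ = [
    "SignificanceThresholds",
    "z_ratio",
    "z_test_pvalues",
    "fdr",
    "de_table",
    "timepoint_de_tables",
    "passes_filter",
    "significant_genes",
    "signed_fold",
    "delta_delta_ct",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class SignificanceThresholds:
    """Compound significance cutoffs (defaults as used throughout)."""

    p_max: float = 0.001
    fdr_max: float = 0.1
    fold_min: float = 1.5
    zratio_min: float = 3.0

    def __post_init__(self) -> None:
        for name in ("p_max", "fdr_max", "fold_min", "zratio_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def z_ratio(zA: pd.DataFrame, zB: pd.DataFrame) -> pd.Series:
    """Per-gene Z-ratio between two groups of z-scored arrays.

    ``zA`` and ``zB`` are genes x replicate-arrays over the same gene list.
    """
    if not zA.index.equals(zB.index):
        raise ValueError("both groups must cover the same gene list, in order")
    d = zA.mean(axis=1) - zB.mean(axis=1)
    sd = float(d.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero SD of per-gene differences (degenerate comparison)")
    out = d / sd
    out.name = "z_ratio"
    return out


def z_test_pvalues(z_ratios: pd.Series | np.ndarray) -> np.ndarray:
    """Two-sided standard-normal p-values for Z-ratio values."""
    z = np.asarray(z_ratios, dtype=float)
    if np.any(~np.isfinite(z)):
        raise ValueError("z_ratio values must be finite")
    return 2.0 * stats.norm.sf(np.abs(z))


def fdr(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p, capped at 1)."""
    return bh_fdr(np.asarray(pvalues, dtype=float))


def signed_fold(ratio: np.ndarray | pd.Series) -> np.ndarray:
    """Signed fold convention: ratios < 1 reported as negative reciprocals."""
    r = np.asarray(ratio, dtype=float)
    return np.where(r >= 1.0, r, -1.0 / r)


def de_table(
    z_matrix: pd.DataFrame,
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    timepoint: float,
    baseline_timepoint: float = 0.0,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> pd.DataFrame:
    """Full per-gene DE statistics for one timepoint-vs-baseline contrast.

    Returns a DataFrame indexed by gene with columns ``mean_logratio`` (log2
    of the ratio of raw replicate means), ``fold_change`` (that raw ratio),
    ``signed_fold``, ``z_ratio``, ``p``, ``q``, ``direction`` and
    ``passes_filter``.
    """
    annot = annotation[annotation["sample_id"].isin(matrix.samples)]
    for t in (timepoint, baseline_timepoint):
        if t not in set(annot["timepoint_hr"]):
            raise ValueError(f"timepoint {t} absent from annotation")
    cols_t = annot.loc[annot["timepoint_hr"] == timepoint, "sample_id"]
    cols_0 = annot.loc[annot["timepoint_hr"] == baseline_timepoint, "sample_id"]
    ratio = matrix.intensities[cols_t].mean(axis=1) / matrix.intensities[cols_0].mean(axis=1)
    zr = z_ratio(z_matrix[cols_t], z_matrix[cols_0])
    p = z_test_pvalues(zr)
    out = pd.DataFrame(
        {
            "mean_logratio": np.log2(ratio),
            "fold_change": ratio,
            "signed_fold": signed_fold(ratio),
            "z_ratio": zr,
            "p": p,
            "q": fdr(p),
        },
        index=matrix.genes,
    )
    out["direction"] = np.where(out["mean_logratio"] >= 0, "up", "down")
    out["passes_filter"] = passes_filter(out, thresholds)
    return out


def timepoint_de_tables(
    z_matrix: pd.DataFrame,
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    baseline_timepoint: float = 0.0,
    thresholds: SignificanceThresholds = SignificanceThresholds(),
) -> dict[float, pd.DataFrame]:
    """DE tables for every non-baseline timepoint of one channel."""
    annot = annotation[annotation["sample_id"].isin(matrix.samples)]
    tps = sorted(t for t in annot["timepoint_hr"].unique() if t != baseline_timepoint)
    return {
        t: de_table(z_matrix, matrix, annotation, t, baseline_timepoint, thresholds)
        for t in tps
    }


def passes_filter(
    table: pd.DataFrame, thresholds: SignificanceThresholds = SignificanceThresholds()
) -> pd.Series:
    """Evaluate the compound significance filter per gene.

    ``p <= p_max AND q <= fdr_max AND (fold effect >= fold_min OR
    |z_ratio| >= zratio_min)``, where the fold effect is
    ``max(ratio, 1/ratio)`` on the raw ratio scale.
    """
    required = {"fold_change", "z_ratio", "p", "q"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"DE table is missing columns: {sorted(missing)}")
    ratio = table["fold_change"].to_numpy(dtype=float)
    fold_effect = np.maximum(ratio, 1.0 / ratio)
    effect_ok = (fold_effect >= thresholds.fold_min) | (
        np.abs(table["z_ratio"].to_numpy()) >= thresholds.zratio_min
    )
    mask = (
        (table["p"].to_numpy() <= thresholds.p_max)
        & (table["q"].to_numpy() <= thresholds.fdr_max)
        & effect_ok
    )
    return pd.Series(mask, index=table.index, name="passes_filter")


def significant_genes(
    table: pd.DataFrame, thresholds: SignificanceThresholds = SignificanceThresholds()
) -> pd.DataFrame:
    """Genes passing the compound filter, with their direction of change."""
    mask = passes_filter(table, thresholds)
    out = table.loc[mask, ["direction"]].copy() if "direction" in table.columns else (
        pd.DataFrame(
            {"direction": np.where(table.loc[mask, "mean_logratio"] >= 0, "up", "down")},
            index=table.index[mask],
        )
    )
    return out


def delta_delta_ct(
    ct_target_treated: float,
    ct_reference_treated: float,
    ct_target_control: float,
    ct_reference_control: float,
) -> float:
    """One replicate's ddCt: (target - reference) in treated minus control."""
    vals = (ct_target_treated, ct_reference_treated, ct_target_control, ct_reference_control)
    if not all(np.isfinite(v) for v in vals):
        raise ValueError("Ct values must be finite")
    return (ct_target_treated - ct_reference_treated) - (
        ct_target_control - ct_reference_control
    )


def ddct_fold_change(ddct_replicates: Iterable[float]) -> float:
    """Average qPCR fold change: 2 ** (-mean(ddCt))."""
    vals = np.asarray(list(ddct_replicates), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one ddCt replicate")
    if np.any(~np.isfinite(vals)):
        raise ValueError("ddCt values must be finite")
    return float(2.0 ** (-vals.mean()))
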