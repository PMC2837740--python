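"""Cross-platform concordance and ChIP-binding integration.

Contrast-level log-ratio tables from different platforms (or channels) are
joined on uppercase HUGO symbols after averaging duplicate entries within
each table, and compared by a Pearson correlation matrix.  Separately,
binding lists from ChIP experiments are intersected with up/down significant
gene lists to call *direct* transcription-factor targets: genes both bound
and transcriptionally responsive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "join_platforms",
    "correlation_matrix",
    "DirectTargetSet",
    "direct_targets",
    "read_gene_list",
    "write_gene_list",
]


def _normalize_symbols(idx: pd.Index) -> pd.Index:
    return idx.astype(str).str.strip().str.upper()


def _average_duplicates(table: pd.DataFrame) -> pd.DataFrame:
    table = table.copy()
    table.index = _normalize_symbols(table.index)
    if table.index.has_duplicates:
        table = table.groupby(level=0).mean()
    return table


def join_platforms(tables: Mapping[str, pd.DataFrame | pd.Series]) -> pd.DataFrame:
    """Inner-join log-ratio tables on gene symbol, averaging duplicates first.

    ``tables`` maps a label (e.g. platform name) to a one-or-more-column
    log-ratio table indexed by gene symbol.  Output columns are prefixed
    with the label; rows are the symbols present in every input.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 tables to join")
    cleaned = []
    for label, tbl in tables.items():
        if isinstance(tbl, pd.Series):
            tbl = tbl.to_frame(name="logratio")
        tbl = _average_duplicates(tbl)
        tbl.columns = [f"{label}:{c}" for c in tbl.columns]
        cleaned.append(tbl)
    joined = pd.concat(cleaned, axis=1, join="inner")
    if joined.empty:
        raise ValueError("no gene symbols shared by all tables")
    joined.index.name = "gene"
    return joined


def correlation_matrix(joined: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between every pair of log-ratio columns."""
    if joined.shape[0] < 3:
        raise ValueError("need at least 3 genes for a correlation matrix")
    if joined.shape[1] < 2:
        raise ValueError("need at least 2 columns to correlate")
    sds = joined.std(ddof=1)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns: {zero}")
    return joined.corr(method="pearson")


@dataclass
class DirectTargetSet:
    """Genes both TF-bound (ChIP) and transcriptionally responsive.

    ``conflicts`` lists genes appearing in both the up and down input lists;
    they are excluded from both target sets.
    """

    up_targets: list[str]
    down_targets: list[str]
    conflicts: list[str] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)


def direct_targets(
    bound: Iterable[str], up: Iterable[str], down: Iterable[str]
) -> DirectTargetSet:
    """Intersect a ChIP-bound gene list with up/down significant calls."""
    norm = lambda xs: {str(g).strip().upper() for g in xs}
    bound_s, up_s, down_s = norm(bound), norm(up), norm(down)
    conflicts = up_s & down_s
    if conflicts:
        warnings.warn(
            f"{len(conflicts)} genes called both up and down were excluded from targets"
        )
    return DirectTargetSet(
        up_targets=sorted(bound_s & (up_s - conflicts)),
        down_targets=sorted(bound_s & (down_s - conflicts)),
        conflicts=sorted(conflicts),
        provenance={"bound": len(bound_s), "up": len(up_s), "down": len(down_s)},
    )


def read_gene_list(path: str | Path) -> list[str]:
    """One uppercase symbol per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip().upper() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
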