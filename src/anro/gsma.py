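"""Gene Set Matrix Analysis: the PAGE enrichment statistic across contrasts.

For one contrast (a vector of per-gene log2 ratios) and one gene set, the
parametric enrichment statistic is

    Z = (Sm - mu) * sqrt(m) / sigma

where ``Sm`` is the median log-ratio of the set members present among the
measured genes, ``mu`` the median and ``sigma`` the sample SD of *all*
log-ratios in the contrast, and ``m`` the number of set members measured.
Applying this per set and per contrast (NRO and total RNA at every
timepoint) yields the enrichment matrix; rows can then be ordered by the
first NRO contrast at which a set scores as up-regulated, which displays the
waves of coordinate transcription.

Because ``Sm`` is a median while ``sigma`` is an SD, the statistic is only
approximately unit-variance under the null; it is a ranking score, and the
attached normal p-values are a convenience, not an exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_fdr

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "PageComponents",
    "EnrichmentResult",
    "page_z",
    "gsma_matrix",
    "enrichment_significance",
    "sort_by_first_appearance",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSet:
    """A named set of uppercase gene symbols (order-free, deduplicated)."""

    name: str
    description: str
    genes: list[str]

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(str(g).strip().upper(), None)
        self.genes = list(seen)
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.name in self._sets:
                raise ValueError(f"duplicate gene set name: {s.name!r}")
            self._sets[s.name] = s

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.names == other.names and all(
            sorted(self[n].genes) == sorted(other[n].genes)
            and self[n].description == other[n].description
            for n in self.names
        )


@dataclass
class PageComponents:
    """The pieces of one enrichment cell: z = (sm - mu) * sqrt(m) / sigma."""

    sm: float
    mu: float
    sigma: float
    m: int
    z: float


def page_z(set_genes: Sequence[str], logratios: pd.Series) -> PageComponents:
    """PAGE statistic for one gene set in one contrast.

    ``logratios`` is indexed by gene symbol over the measured universe.
    Set members absent from the universe are silently dropped; ``m`` counts
    the intersection.
    """
    values = logratios.dropna()
    if len(values) < 2:
        raise ValueError("need at least 2 measured genes in the contrast")
    members = [str(g).strip().upper() for g in set_genes]
    in_set = values.loc[values.index.intersection(members)]
    m = len(in_set)
    if m == 0:
        raise ValueError("gene set has no members among the measured genes")
    sigma = float(values.std(ddof=1))
    if sigma == 0:
        raise ValueError("degenerate contrast: zero SD of log-ratios")
    mu = float(values.median())
    sm = float(in_set.median())
    z = (sm - mu) * np.sqrt(m) / sigma
    return PageComponents(sm=sm, mu=mu, sigma=sigma, m=m, z=float(z))


@dataclass
class EnrichmentResult:
    """Gene sets x contrasts enrichment matrix with per-cell components.

    ``z`` holds NaN for missing cells (set not measurable in that contrast);
    ``missing`` marks them explicitly so downstream ordering never mistakes
    an unmeasurable set for a null one.  ``p``/``q`` are filled by
    :func:`enrichment_significance`.
    """

    z: pd.DataFrame
    sm: pd.DataFrame
    m: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    missing: pd.DataFrame
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None

    @property
    def set_names(self) -> list[str]:
        return self.z.index.tolist()

    @property
    def contrasts(self) -> list:
        return self.z.columns.tolist()

    def to_tsv(self, path: str | Path) -> None:
        blocks = {"z": self.z, "Sm": self.sm, "m": self.m}
        if self.p is not None:
            blocks["p"] = self.p
        if self.q is not None:
            blocks["q"] = self.q
        wide = pd.concat(blocks, axis=1)
        wide.columns = [f"{c}:{stat}" for stat, c in wide.columns]
        wide.index.name = "gene_set"
        wide.to_csv(path, sep="\t")


def gsma_matrix(
    collection: GeneSetCollection, logratio_table: pd.DataFrame
) -> EnrichmentResult:
    """Apply :func:`page_z` to every set x contrast cell.

    ``logratio_table`` is genes x contrasts.  Cells whose preconditions fail
    (empty intersection, degenerate contrast) are flagged missing rather than
    silently zeroed.
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    names = collection.names
    contrasts = logratio_table.columns
    shape = (len(names), len(contrasts))
    z = np.full(shape, np.nan)
    sm = np.full(shape, np.nan)
    m = np.zeros(shape, dtype=int)
    missing = np.ones(shape, dtype=bool)
    mu = pd.Series(np.nan, index=contrasts, name="mu")
    sigma = pd.Series(np.nan, index=contrasts, name="sigma")
    for j, c in enumerate(contrasts):
        col = logratio_table[c]
        for i, name in enumerate(names):
            try:
                comp = page_z(collection[name].genes, col)
            except ValueError:
                continue
            z[i, j], sm[i, j], m[i, j] = comp.z, comp.sm, comp.m
            mu[c], sigma[c] = comp.mu, comp.sigma
            missing[i, j] = False
    idx = pd.Index(names, name="gene_set")
    return EnrichmentResult(
        z=pd.DataFrame(z, index=idx, columns=contrasts),
        sm=pd.DataFrame(sm, index=idx, columns=contrasts),
        m=pd.DataFrame(m, index=idx, columns=contrasts),
        mu=mu,
        sigma=sigma,
        missing=pd.DataFrame(missing, index=idx, columns=contrasts),
    )


def enrichment_significance(result: EnrichmentResult) -> EnrichmentResult:
    """Attach two-sided normal p per cell and BH q across sets per contrast."""
    z = result.z
    p = pd.DataFrame(2.0 * stats.norm.sf(np.abs(z.to_numpy())), index=z.index, columns=z.columns)
    p = p.where(~result.missing)
    q = p.copy()
    for c in z.columns:
        col = p[c].dropna()
        if len(col):
            q.loc[col.index, c] = bh_fdr(col.to_numpy())
    result.p, result.q = p, q
    return result


def sort_by_first_appearance(
    result: EnrichmentResult,
    contrast_meta: pd.DataFrame,
    z_threshold: float = 2.0,
) -> list[str]:
    """Order sets by the earliest NRO contrast where z exceeds the threshold.

    ``contrast_meta`` maps the result's contrast columns to channel and time:
    columns ``contrast``, ``rna_source``, ``timepoint_hr``.  Sets never
    reaching the threshold sort last, by descending |z| at the final NRO
    contrast.  Upregulation only: the test is ``z >= z_threshold``, signed.
    """
    nro = contrast_meta[contrast_meta["rna_source"] == "NRO"].sort_values("timepoint_hr")
    if nro.empty:
        raise ValueError("no NRO contrasts in the enrichment matrix")
    nro_cols = nro["contrast"].tolist()
    times = nro["timepoint_hr"].to_numpy(dtype=float)
    zmat = result.z[nro_cols].to_numpy()
    final_abs = np.abs(np.nan_to_num(zmat[:, -1], nan=-np.inf))
    keys = []
    for i, name in enumerate(result.set_names):
        hit = np.flatnonzero(np.nan_to_num(zmat[i], nan=-np.inf) >= z_threshold)
        first = times[hit[0]] if len(hit) else np.inf
        keys.append((first, -final_abs[i], name))
    return [name for _, _, name in sorted(keys)]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a tab-delimited GMT file: name, description, member genes."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            sets.append(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")
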