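"""First-appearance wave analysis and profile clustering.

A gene's *first appearance* is the earliest timepoint at which it is called
significantly up-regulated versus baseline.  Comparing first appearances in
the nascent (NRO) and total-RNA channels quantifies how far transcription
leads steady-state mRNA; classifying the NRO first appearance against the
timepoint grid assigns each gene a transcriptional wave:

    early          first up at <= 1 hr
    delayed_early  first up in (1, 6] hr
    late           first up after 6 hr (in the default design, only at 48 hr)
    unregulated    never significantly up

A gene is additionally flagged *transient* when it appears at some
timepoint but is no longer significant at the final one; only the final
timepoint matters (intermediate dropouts do not toggle the flag).

For heatmap-style ordering the module also provides agglomerative
complete-linkage clustering under the uncentered-Pearson similarity
(cosine of the raw profiles, no mean-centering), with a deterministic
lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "first_appearance",
    "classify_wave",
    "wave_table",
    "lead_lag",
    "uncentered_pearson",
    "Dendrogram",
    "hierarchical_cluster",
]


def first_appearance(flags: pd.DataFrame) -> pd.Series:
    """Earliest timepoint (column) at which each gene's flag is True.

    ``flags`` is a genes x timepoints boolean DataFrame whose columns are
    hours (floats).  Returns hours per gene, NaN when never significant.
    """
    tps = np.asarray(flags.columns, dtype=float)
    if np.any(np.diff(tps) <= 0):
        raise ValueError("timepoint columns must be strictly increasing hours")
    arr = flags.to_numpy(dtype=bool)
    any_hit = arr.any(axis=1)
    first_idx = arr.argmax(axis=1)
    out = np.where(any_hit, tps[first_idx], np.nan)
    return pd.Series(out, index=flags.index, name="first_up_hr")


def classify_wave(first_up: pd.Series, final_flag: pd.Series) -> pd.DataFrame:
    """Wave class and transience from the first appearance.

    ``final_flag`` is the per-gene significance flag at the final timepoint.
    """
    f = first_up.to_numpy(dtype=float)
    wave = np.full(len(f), "unregulated", dtype=object)
    wave[f <= 1.0] = "early"
    wave[(f > 1.0) & (f <= 6.0)] = "delayed_early"
    wave[f > 6.0] = "late"
    transient = ~np.isnan(f) & ~final_flag.to_numpy(dtype=bool)
    return pd.DataFrame({"wave_class": wave, "transient": transient}, index=first_up.index)


def _up_flags(de_tables: Mapping[float, pd.DataFrame]) -> pd.DataFrame:
    tps = sorted(de_tables)
    flags = {
        t: de_tables[t]["passes_filter"] & (de_tables[t]["direction"] == "up")
        for t in tps
    }
    return pd.DataFrame(flags)


def wave_table(
    nro_de: Mapping[float, pd.DataFrame],
    total_de: Mapping[float, pd.DataFrame],
) -> pd.DataFrame:
    """Combine per-timepoint DE tables of both channels into a wave table.

    Input maps timepoint_hr -> DE table (see
    :func:`anro.differential.timepoint_de_tables`); up-regulation flags are
    ``passes_filter AND direction == up``.  Output columns:
    ``first_up_nro``, ``first_up_total``, ``lead_hr`` (total minus NRO, for
    genes regulated in both), ``wave_class`` (from the NRO channel) and
    ``transient``.
    """
    flags_nro = _up_flags(nro_de)
    flags_total = _up_flags(total_de)
    genes = flags_nro.index
    if not genes.equals(flags_total.index):
        common = genes.intersection(flags_total.index)
        flags_nro, flags_total = flags_nro.loc[common], flags_total.loc[common]
    first_nro = first_appearance(flags_nro)
    first_total = first_appearance(flags_total)
    classes = classify_wave(first_nro, flags_nro.iloc[:, -1])
    out = pd.DataFrame(
        {
            "first_up_nro": first_nro,
            "first_up_total": first_total,
            "lead_hr": first_total - first_nro,
            "wave_class": classes["wave_class"],
            "transient": classes["transient"],
        },
        index=flags_nro.index,
    )
    out.index.name = "gene"
    return out


def lead_lag(waves: pd.DataFrame) -> dict[str, float]:
    """Summary of the NRO lead over total RNA.

    Restricted to genes with a first appearance in both channels.  Returns
    the median lead in hours, the fraction of genes whose NRO appearance is
    no later than their total-RNA appearance, and the subset size.
    """
    both = waves.dropna(subset=["first_up_nro", "first_up_total"])
    if both.empty:
        return {"median_lead_hr": float("nan"), "fraction_lead_nonneg": float("nan"), "n": 0}
    lead = both["first_up_total"] - both["first_up_nro"]
    return {
        "median_lead_hr": float(lead.median()),
        "fraction_lead_nonneg": float((lead >= 0).mean()),
        "n": int(len(both)),
    }


def uncentered_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of the raw profiles: sum(xy)/sqrt(sum(x^2)sum(y^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    nx, ny = np.sqrt((x * x).sum()), np.sqrt((y * y).sum())
    if nx == 0 or ny == 0:
        raise ValueError("all-zero profile has undefined uncentered correlation")
    return float((x * y).sum() / (nx * ny))


@dataclass
class Dendrogram:
    """Agglomerative merge history in scipy linkage-matrix layout.

    ``linkage`` rows are (cluster_i, cluster_j, height, size); leaves are
    numbered 0..n-1 in input order, merged clusters n, n+1, ...  ``labels``
    are the input row labels, ``leaf_order`` the left-to-right display order
    for heatmap export.
    """

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    def cut(self, height: float) -> pd.Series:
        """Flat cluster membership at the given distance cut height."""
        from scipy.cluster.hierarchy import fcluster

        member = fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(member, index=self.labels, name="cluster")


def _uncentered_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    norms = np.sqrt((profiles * profiles).sum(axis=1))
    if np.any(norms == 0):
        raise ValueError("all-zero profile has undefined uncentered correlation")
    sim = (profiles @ profiles.T) / np.outer(norms, norms)
    np.clip(sim, -1.0, 1.0, out=sim)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return d


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Complete-linkage clustering under 1 - uncentered-Pearson distance.

    Ties on the merge distance are broken by merging the pair whose two
    clusters have the lexicographically smallest minimum leaf labels, so the
    result is deterministic and independent of input row order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to cluster")
    labels = [str(x) for x in profiles.index]
    n = len(labels)
    leaf_d = _uncentered_distance_matrix(profiles.to_numpy(dtype=float))

    # active cluster id -> (member leaf indices, smallest leaf label)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    min_label: dict[int, str] = {i: labels[i] for i in range(n)}
    dist: dict[int, dict[int, float]] = {
        i: {j: leaf_d[i, j] for j in range(n) if j != i} for i in range(n)
    }
    children: dict[int, tuple[int, int]] = {}
    linkage = np.zeros((n - 1, 4))

    for step in range(n - 1):
        best = None
        for a in sorted(dist, key=lambda c: min_label[c]):
            for b in sorted(dist[a], key=lambda c: min_label[c]):
                if min_label[b] < min_label[a]:
                    continue  # each unordered pair visited once, labels sorted
                d = dist[a][b]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        new = n + step
        linkage[step] = [a, b, d, len(members[a]) + len(members[b])]
        children[new] = (a, b)
        members[new] = members[a] + members[b]
        min_label[new] = min(min_label[a], min_label[b])
        # complete linkage: distance to the merged cluster is the max
        dist[new] = {}
        for other in dist:
            if other in (a, b, new):
                continue
            d_new = max(dist[a][other], dist[b][other])
            dist[new][other] = d_new
            dist[other][new] = d_new
        for gone in (a, b):
            del dist[gone]
            for other in dist:
                dist[other].pop(gone, None)

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        first, second = (a, b) if min_label[a] <= min_label[b] else (b, a)
        return leaves(first) + leaves(second)

    order = leaves(n + n - 2) if n > 1 else [0]
    return Dendrogram(
        linkage=linkage,
        labels=labels,
        leaf_order=[labels[i] for i in order],
    )
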