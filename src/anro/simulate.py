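"""Synthetic paired NRO/total-RNA time courses with known ground truth.

The generator emulates an inducible-transcription-factor time course in a
B-cell model: nuclei and whole cells are sampled at 0, 0.25, 0.5, 1, 3, 6 and
48 hr after induction (6 replicate arrays per timepoint, 10 at 48 hr), and a
planted minority of genes steps up in four transcriptional waves:

``early``
    nascent (NRO) onset within the first hour (0.25-1 hr grid points);
``delayed_early``
    onset at 3-6 hr;
``late``
    onset only at the final, steady-state timepoint;
``transient_early``
    early onset that has returned to baseline by the final timepoint.

Total-RNA onsets trail NRO onsets by ``lag_steps`` positions on the timepoint
grid (clamped at the final point), so nascent transcription anticipates
steady-state mRNA changes — the property the downstream wave analysis is
meant to recover.

Signal and noise share the log2 scale: a regulated gene's expected log2 ratio
vs baseline is ``effect_log2`` from its onset onward, and replicate noise is
additive Gaussian with SD ``noise_sd_log`` in log2 units (homoscedastic).
Baseline abundances are drawn once per gene on the log10 scale,
``N(2.5, 0.5)`` truncated below at 0.5, spanning the dynamic range of
bead-array data; background (undetected) genes sit lower, ``N(1.8, 0.3)``,
and receive detection scores below any sensible threshold in every sample.
All draws flow from one ``numpy.random.default_rng(seed)`` stream, so a fixed
config is bit-reproducible.

The distributional choices above are stand-ins: no noise or abundance model
is measured from real arrays, and none is claimed to be.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gsma import GeneSet, GeneSetCollection
from .preprocess import ExpressionMatrix

__all__ = [
    "SimConfig",
    "WAVE_CLASSES",
    "generate_experiment",
    "expected_logratio",
    "steady_state_logratio",
    "generate_genesets",
    "generate_two_platforms",
    "generate_chip_list",
]

WAVE_CLASSES = ("early", "delayed_early", "late", "transient_early")

LOG10_2 = math.log10(2.0)

_DEFAULT_TIMEPOINTS = (0.0, 0.25, 0.5, 1.0, 3.0, 6.0, 48.0)
_DEFAULT_WAVE_MIX = {
    "early": 0.35,
    "delayed_early": 0.35,
    "late": 0.15,
    "transient_early": 0.15,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic paired NRO/total time-course experiment.

    Defaults describe the emulated induction design: seven timepoints from 0
    to 48 hr, 6 replicates each (10 at 48 hr), 5% of genes regulated across
    four waves with a one-grid-step NRO-to-total lag, effect of 1 log2 unit
    (2-fold), replicate noise SD 0.2 log2 units, and 10% background genes.
    """

    n_genes: int = 4000
    timepoints_hr: Sequence[float] = _DEFAULT_TIMEPOINTS
    replicates_per_timepoint: int = 6
    replicate_overrides: Mapping[float, int] = field(default_factory=lambda: {48.0: 10})
    fraction_regulated: float = 0.05
    wave_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_WAVE_MIX))
    effect_log2: float = 1.0
    lag_steps: int = 1
    noise_sd_log: float = 0.2
    fraction_background: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        tps = list(self.timepoints_hr)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ValueError("timepoints_hr must be strictly increasing with >= 2 points")
        if tps[0] != 0.0:
            raise ValueError("first timepoint must be the 0-hr baseline")
        if any(t < 0 for t in tps):
            raise ValueError("timepoints must be non-negative hours")
        if not 0.0 <= self.fraction_regulated <= 1.0:
            raise ValueError("fraction_regulated must lie in [0, 1]")
        if not 0.0 <= self.fraction_background <= 1.0:
            raise ValueError("fraction_background must lie in [0, 1]")
        if self.fraction_regulated + self.fraction_background > 1.0:
            raise ValueError("fraction_regulated + fraction_background must not exceed 1")
        if abs(sum(self.wave_mix.values()) - 1.0) > 1e-9:
            raise ValueError("wave_mix proportions must sum to 1")
        if set(self.wave_mix) - set(WAVE_CLASSES):
            raise ValueError(f"unknown wave classes: {set(self.wave_mix) - set(WAVE_CLASSES)}")
        if self.effect_log2 <= 0:
            raise ValueError("effect_log2 must be strictly positive")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be strictly positive")
        if self.lag_steps < 0:
            raise ValueError("lag_steps must be a non-negative integer")
        if self.replicates_per_timepoint < 1:
            raise ValueError("replicates_per_timepoint must be >= 1")

    def replicates_at(self, timepoint: float) -> int:
        return int(self.replicate_overrides.get(timepoint, self.replicates_per_timepoint))


def _largest_remainder_counts(total: int, proportions: Mapping[str, float]) -> dict[str, int]:
    """Integer counts summing to ``total`` that best match the proportions."""
    keys = list(proportions)
    exact = {k: total * proportions[k] for k in keys}
    counts = {k: int(math.floor(exact[k])) for k in keys}
    short = total - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def _onset_pool(wave: str, timepoints: Sequence[float]) -> list[float]:
    if wave in ("early", "transient_early"):
        pool = [t for t in timepoints if 0 < t <= 1.0]
    elif wave == "delayed_early":
        pool = [t for t in timepoints if 1.0 < t <= 6.0]
    else:  # late
        pool = [timepoints[-1]]
    if not pool:
        raise ValueError(f"timepoint grid has no admissible onset for wave {wave!r}")
    return pool


def _make_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]
    tps = list(config.timepoints_hr)

    n_bg = int(round(config.fraction_background * n))
    n_reg = int(round(config.fraction_regulated * n))
    order = rng.permutation(n)
    bg_idx = set(order[:n_bg].tolist())
    reg_idx = order[n_bg : n_bg + n_reg].tolist()

    wave_counts = _largest_remainder_counts(n_reg, config.wave_mix)
    waves: list[str] = []
    for w in WAVE_CLASSES:
        waves.extend([w] * wave_counts.get(w, 0))

    truth = pd.DataFrame(
        {
            "regulated": False,
            "background": False,
            "wave": "",
            "nro_onset_hr": np.nan,
            "total_onset_hr": np.nan,
            "effect_log2": 0.0,
            "persists_at_48h": False,
        },
        index=pd.Index(genes, name="gene"),
    )
    truth.iloc[sorted(bg_idx), truth.columns.get_loc("background")] = True

    last = len(tps) - 1
    for gi, wave in zip(reg_idx, waves):
        pool = _onset_pool(wave, tps)
        onset = float(pool[rng.integers(len(pool))])
        onset_idx = tps.index(onset)
        total_idx = min(onset_idx + config.lag_steps, last)
        g = genes[gi]
        truth.loc[g, "regulated"] = True
        truth.loc[g, "wave"] = wave
        truth.loc[g, "nro_onset_hr"] = onset
        truth.loc[g, "total_onset_hr"] = tps[total_idx]
        truth.loc[g, "effect_log2"] = config.effect_log2
        truth.loc[g, "persists_at_48h"] = wave != "transient_early"
    return truth


def expected_logratio(
    truth: pd.DataFrame, timepoints: Sequence[float], channel: str
) -> pd.DataFrame:
    """Noise-free expected log2 ratio vs baseline, per gene and timepoint.

    ``channel`` is ``"NRO"`` or ``"TOTAL"`` and selects which onset column
    applies.  Transient genes revert to 0 at the final timepoint; everything
    else holds ``effect_log2`` from onset onward.
    """
    if channel not in ("NRO", "TOTAL"):
        raise ValueError("channel must be 'NRO' or 'TOTAL'")
    onset = truth["nro_onset_hr" if channel == "NRO" else "total_onset_hr"].to_numpy()
    effect = truth["effect_log2"].to_numpy()
    persists = truth["persists_at_48h"].to_numpy()
    tps = list(timepoints)
    lr = np.zeros((len(truth), len(tps)))
    for j, t in enumerate(tps):
        on = ~np.isnan(onset) & (t >= onset)
        if t == tps[-1]:
            on &= persists
        lr[on, j] = effect[on]
    return pd.DataFrame(lr, index=truth.index, columns=tps)


def steady_state_logratio(truth: pd.DataFrame) -> pd.Series:
    """Expected log2 ratio at the final (steady-state) timepoint per gene."""
    lr = np.where(
        truth["regulated"].to_numpy() & truth["persists_at_48h"].to_numpy(),
        truth["effect_log2"].to_numpy(),
        0.0,
    )
    return pd.Series(lr, index=truth.index, name="logratio")


def _sample_ids(config: SimConfig, channel: str) -> tuple[list[str], pd.DataFrame]:
    ids, rows = [], []
    for t in config.timepoints_hr:
        for r in range(1, config.replicates_at(t) + 1):
            sid = f"{channel}_T{t:g}H_R{r}"
            ids.append(sid)
            rows.append(
                {
                    "sample_id": sid,
                    "timepoint_hr": t,
                    "replicate": r,
                    "rna_source": channel,
                    "platform": "synthetic",
                    "group": f"{channel}_{t:g}h",
                }
            )
    return ids, pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size)
    while True:
        bad = out <= lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_experiment(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate one paired experiment.

    Returns ``(nro_matrix, total_matrix, annotation, truth)``.  Deterministic
    for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    genes = truth.index
    bg = truth["background"].to_numpy()

    base_log10 = np.where(
        bg,
        _truncated_normal(rng, 1.8, 0.3, 0.5, len(genes)),
        _truncated_normal(rng, 2.5, 0.5, 0.5, len(genes)),
    )

    matrices: dict[str, ExpressionMatrix] = {}
    annots = []
    for channel in ("NRO", "TOTAL"):
        ids, annot = _sample_ids(config, channel)
        annots.append(annot)
        lr = expected_logratio(truth, config.timepoints_hr, channel)
        cols = np.empty((len(genes), len(ids)))
        detection = np.ones((len(genes), len(ids)))
        j = 0
        for t in config.timepoints_hr:
            n_rep = config.replicates_at(t)
            shift = lr[t].to_numpy()[:, None] * LOG10_2
            noise = rng.normal(0.0, config.noise_sd_log * LOG10_2, (len(genes), n_rep))
            cols[:, j : j + n_rep] = base_log10[:, None] + shift + noise
            detection[bg, j : j + n_rep] = rng.uniform(0.0, 0.9, (int(bg.sum()), n_rep))
            j += n_rep
        matrices[channel] = ExpressionMatrix(
            intensities=pd.DataFrame(10.0 ** cols, index=genes, columns=ids),
            detection=pd.DataFrame(detection, index=genes, columns=ids),
            rna_source=channel,
            platform="synthetic",
        )
    annotation = pd.concat(annots, ignore_index=True)
    return matrices["NRO"], matrices["TOTAL"], annotation, truth


def generate_genesets(
    truth: pd.DataFrame,
    n_planted: int,
    n_null: int,
    set_size: int,
    seed: int,
) -> GeneSetCollection:
    """Gene sets with known enrichment status, for exercising PAGE/GSMA.

    Planted sets are sampled without replacement from regulated genes sharing
    one wave class (classes are cycled in a fixed order); null sets are drawn
    uniformly from all genes.  Names encode the truth, e.g.
    ``PLANTED_EARLY_01`` and ``NULL_03``.
    """
    rng = np.random.default_rng(seed)
    sets: list[GeneSet] = []
    if n_planted > 0:
        pools = {
            w: truth.index[(truth["wave"] == w)].to_numpy()
            for w in WAVE_CLASSES
            if (truth["wave"] == w).sum() >= set_size
        }
        if not pools:
            raise ValueError("no wave class has enough regulated genes for the set size")
        classes = [w for w in WAVE_CLASSES if w in pools]
        for i in range(n_planted):
            w = classes[i % len(classes)]
            members = rng.choice(pools[w], size=set_size, replace=False)
            sets.append(
                GeneSet(
                    name=f"PLANTED_{w.upper()}_{i + 1:02d}",
                    description=f"planted {w} wave set",
                    genes=sorted(members.tolist()),
                )
            )
    if set_size > len(truth):
        raise ValueError("set size exceeds the gene universe")
    for i in range(n_null):
        members = rng.choice(truth.index.to_numpy(), size=set_size, replace=False)
        sets.append(
            GeneSet(
                name=f"NULL_{i + 1:02d}",
                description="random null set",
                genes=sorted(members.tolist()),
            )
        )
    return GeneSetCollection(sets)


def generate_two_platforms(
    truth: pd.DataFrame,
    shared_genes: int,
    platform_noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two contrast-level log-ratio tables measuring the same truth.

    Both platforms see the same true steady-state log2 ratios plus
    independent Gaussian measurement noise of SD ``platform_noise_sd``.  The
    expected inter-platform Pearson correlation is the attenuation
    ``v / (v + s^2)`` with ``v`` the variance of the true log-ratios and
    ``s`` the platform noise SD.
    """
    if platform_noise_sd <= 0:
        raise ValueError("platform_noise_sd must be strictly positive")
    if shared_genes > len(truth):
        raise ValueError("shared_genes exceeds the number of genes in truth")
    rng = np.random.default_rng(seed)
    genes = truth.index.to_numpy()[
        np.sort(rng.choice(len(truth), size=shared_genes, replace=False))
    ]
    true_lr = steady_state_logratio(truth).loc[genes].to_numpy()
    tables = []
    for name in ("PLATFORM_A", "PLATFORM_B"):
        noisy = true_lr + rng.normal(0.0, platform_noise_sd, shared_genes)
        tables.append(
            pd.DataFrame({name: noisy}, index=pd.Index(genes, name="gene"))
        )
    return tables[0], tables[1]


def generate_chip_list(
    truth: pd.DataFrame,
    coverage: float,
    n_decoys: int,
    seed: int,
) -> list[str]:
    """A synthetic TF-binding (ChIP) gene list with known composition.

    Contains ``coverage`` of the regulated genes (sampled without
    replacement) plus ``n_decoys`` unregulated genes, emulating a binding
    survey that covers most but not all responsive genes and also binds
    transcriptionally silent loci.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    regulated = truth.index[truth["regulated"]].to_numpy()
    unregulated = truth.index[~truth["regulated"]].to_numpy()
    n_cov = int(round(coverage * len(regulated)))
    if n_decoys > len(unregulated):
        raise ValueError("not enough unregulated genes for the requested decoys")
    bound = list(rng.choice(regulated, size=n_cov, replace=False)) if n_cov else []
    bound += list(rng.choice(unregulated, size=n_decoys, replace=False)) if n_decoys else []
    return sorted(bound)
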