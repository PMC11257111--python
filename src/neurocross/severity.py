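"""Noise-injection severity simulation.

A healthy cohort's node time series are split into a sham group, a simulated
mild-injury group (Gaussian noise of sd 1 added to three targeted networks),
and a simulated severe-injury group re-noised at each of a ladder of noise
levels (sds 3, 5, 7, 10, 15 by default). Cross-group similarity of the sham
group to each injured group then charts how the statistic degrades with
severity: for unit-variance signals the expected full-correlation similarity
against a clean reference falls as 1 / sqrt(1 + sigma^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .crossnet import EstimatorConfig, _jackknife_mean_var, resample_cross_group
from .datatypes import NodeTimeSeries
from .errors import ConfigurationError, ResamplingError

__all__ = ["NoiseSpec", "inject_noise", "run_severity_experiment"]

DEFAULT_TARGETS = ("EXN", "SMN", "DMN")
DEFAULT_LEVELS = (1.0, 3.0, 5.0, 7.0, 10.0, 15.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Which networks receive noise, at which severity levels."""

    target_networks: tuple[str, ...] = DEFAULT_TARGETS
    sd_levels: tuple[float, ...] = DEFAULT_LEVELS  # severe-group noise ladder
    mild_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_networks:
            raise ConfigurationError("target_networks must be nonempty")
        levels = tuple(float(s) for s in self.sd_levels)
        if any(s <= 0 for s in levels):
            raise ConfigurationError(f"sd_levels must be strictly positive: {levels}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ConfigurationError(f"sd_levels must be strictly increasing: {levels}")
        object.__setattr__(self, "sd_levels", levels)
        if self.mild_sd <= 0:
            raise ConfigurationError("mild_sd must be positive")

    def validate_against(self, node_names: Sequence[str]) -> None:
        unknown = set(self.target_networks) - set(node_names)
        if unknown:
            raise ConfigurationError(
                f"target networks {sorted(unknown)} not among nodes {list(node_names)}"
            )


def inject_noise(
    ts: NodeTimeSeries,
    networks: Sequence[str],
    sd: float,
    seed: int = 0,
) -> NodeTimeSeries:
    """Add independent Gaussian noise of the given sd to the named columns.

    The input is expected standardized (the simulation normalises series to
    zero mean, unit sd first); untargeted columns pass through bit-for-bit.
    """
    if sd < 0:
        raise ConfigurationError(f"noise sd must be non-negative; got {sd}")
    unknown = set(networks) - set(ts.node_names)
    if unknown:
        raise ConfigurationError(
            f"networks {sorted(unknown)} not among nodes {list(ts.node_names)}"
        )
    data = ts.data.copy()
    if sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        for name in networks:
            j = ts.node_names.index(name)
            data[:, j] = data[:, j] + sd * rng.standard_normal(ts.n_volumes)
    return NodeTimeSeries(ts.subject_id, data, ts.node_names, standardized=False)


def _noised_group(
    group: list[NodeTimeSeries],
    networks: Sequence[str],
    sd: float,
    base_seed: np.random.SeedSequence,
) -> list[NodeTimeSeries]:
    seeds = base_seed.spawn(len(group))
    return [
        inject_noise(ts, networks, sd, seed=s.generate_state(1)[0] % (2**31))
        for ts, s in zip(group, seeds)
    ]


def run_severity_experiment(
    cohort: Sequence[NodeTimeSeries],
    split: tuple[int, int, int] = (14, 14, 16),
    noise: NoiseSpec | None = None,
    crossnet_cfg: EstimatorConfig | None = None,
    n_trials: int = 128,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Partition a healthy cohort and chart similarity against injury severity.

    Returns a table with one row per (network, comparison, sd_level): the
    sham-versus-mild similarity (computed once; the mild group never sees the
    severe noise ladder) and the sham-versus-severe similarity at each level.
    The per-level significance contrast against the mild group uses the
    jackknife subject-level test (resampling trials reuse subjects, so tests
    on raw trial values overstate their sample size).

    The severe group is re-noised independently at every level from the same
    clean series, so levels are comparable without compounding noise.
    """
    noise = noise or NoiseSpec()
    cfg = crossnet_cfg or EstimatorConfig(estimator="full", ridge_rho=0.0, fisher=True)
    n_sham, n_mild, n_severe = split
    if min(split) < 2:
        raise ResamplingError(f"each split part needs >= 2 subjects; got {split}")
    if len(cohort) < sum(split):
        raise ResamplingError(
            f"cohort of {len(cohort)} too small for split {split} "
            f"(needs {sum(split)})"
        )
    cohort = [ts if ts.standardized else ts.standardize() for ts in cohort]
    noise.validate_against(cohort[0].node_names)

    root = np.random.SeedSequence(noise.seed)
    part_seed, mild_seed, severe_seed, resample_seed = root.spawn(4)
    order = np.random.default_rng(part_seed).permutation(len(cohort))
    sham = [cohort[i] for i in order[:n_sham]]
    mild_clean = [cohort[i] for i in order[n_sham : n_sham + n_mild]]
    severe_clean = [cohort[i] for i in order[n_sham + n_mild : sum(split)]]

    mild = _noised_group(mild_clean, noise.target_networks, noise.mild_sd, mild_seed)
    rs_seeds = resample_seed.spawn(1 + len(noise.sd_levels))

    def run(treatment, seed_seq):
        return resample_cross_group(
            treatment,
            sham,
            n_trials=n_trials,
            seed=int(seed_seq.generate_state(1)[0] % (2**31)),
            estimator_cfg=cfg,
        )

    res_mild = run(mild, rs_seeds[0])
    node_idx = {n: i for i, n in enumerate(res_mild.node_names)}
    mild_se = res_mild.jackknife_se()

    # error bars are the jackknife (subject-level) standard error: trial
    # values reuse subjects, so their naive standard error is far too small
    rows = []
    for net in noise.target_networks:
        k = node_idx[net]
        rows.append(
            {
                "network": net,
                "comparison": "sham_vs_mild",
                "sd_level": noise.mild_sd,
                "mean_z": res_mild.mean[k],
                "stderr": mild_se[k],
                "p_vs_mild": np.nan,
                "significant": False,
            }
        )
    level_seeds = severe_seed.spawn(len(noise.sd_levels))
    for li, sd in enumerate(noise.sd_levels):
        severe = _noised_group(
            severe_clean, noise.target_networks, sd, level_seeds[li]
        )
        res = run(severe, rs_seeds[1 + li])
        severe_se = res.jackknife_se()
        for net in noise.target_networks:
            k = node_idx[net]
            m1, v1, n1 = _jackknife_mean_var(res_mild, k)
            m2, v2, n2 = _jackknife_mean_var(res, k)
            if np.isfinite(v1) and np.isfinite(v2) and v1 + v2 > 0:
                se = np.sqrt(v1 + v2)
                df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
                p = 2.0 * stats.t.sf(abs(m2 - m1) / se, df)
            else:
                p = np.nan
            rows.append(
                {
                    "network": net,
                    "comparison": "sham_vs_severe",
                    "sd_level": sd,
                    "mean_z": res.mean[k],
                    "stderr": severe_se[k],
                    "p_vs_mild": p,
                    "significant": bool(np.isfinite(p) and p < alpha),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["network", "comparison", "sd_level"], ignore_index=True
    )
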