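"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a resting-state fMRI study of piglets in a single
template space: seven network masks, per-subject node time courses of 305
volumes at TR = 3 s, optional 4D volumes built from spatial maps times time
courses, and smooth positive cerebral-blood-flow maps. Subjects within one
cohort share a set of ground-truth network time courses (and, for CBF, a
shared perfusion pattern); each subject observes those with independent
noise. That shared component is what makes cross-subject similarity a
meaningful statistic, and it is retained on every record for oracle tests.

Injury is modelled as partial replacement of the shared signal: a network
with attenuation ``a`` in a TBI-labelled group contributes
``sqrt(1-a) * shared + sqrt(a) * subject-specific`` so the course stays
unit-variance while its cross-group similarity scales as ``sqrt(1-a)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .datatypes import DEFAULT_NETWORKS, NodeTimeSeries, RSNAtlas, SubjectRecord
from .errors import AtlasPlacementError, ConfigurationError

__all__ = [
    "CohortSpec",
    "generate_atlas",
    "generate_cohort",
    "generate_cbf_maps",
]


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_per_group
        Group label -> subject count, e.g. ``{"sham": 6, "SLN": 6, "FMT": 6}``.
    n_volumes, tr_seconds
        Length of each node time course; defaults mirror a 15-minute EPI run
        (305 volumes at TR = 3 s).
    ar_coeff
        Lag-1 autocorrelation of the shared network courses. Order-1
        autocorrelated Gaussians mimic slow BOLD fluctuations without
        committing to a haemodynamic response model.
    observation_noise_sd
        Per-subject white noise added on top of the (unit-variance) node
        courses; this is what separates subjects within a group.
    injury_effect
        Network label -> attenuation in [0, 1], applied to every group other
        than ``sham_group``. 0 leaves the network intact; 1 replaces the
        shared signal entirely with subject-specific activity.
    make_fmri, voxel_noise_sd
        When ``make_fmri`` is set, each subject also gets a 4D volume: the
        outer product of smoothed mask maps with the subject's node courses
        plus white voxel noise.
    seed
        Fully determines the cohort.
    """

    n_per_group: dict[str, int]
    n_volumes: int = 305
    tr_seconds: float = 3.0
    ar_coeff: float = 0.3
    observation_noise_sd: float = 0.3
    injury_effect: dict[str, float] = field(default_factory=dict)
    sham_group: str = "sham"
    timepoint: str = "D1"
    make_fmri: bool = False
    voxel_noise_sd: float = 0.2
    seed: int = 0

    def validate(self, n_networks: int) -> None:
        if not self.n_per_group:
            raise ConfigurationError("n_per_group is empty")
        for g, n in self.n_per_group.items():
            if n <= 0:
                raise ConfigurationError(f"group {g!r} has non-positive count {n}")
        # pseudo-subjects double the node count; netmats need T >= 2 * 2N
        if self.n_volumes < 4 * n_networks:
            raise ConfigurationError(
                f"n_volumes={self.n_volumes} too short for {2 * n_networks}-node "
                f"pseudo-subjects (need >= {4 * n_networks})"
            )
        if not 0 <= self.ar_coeff < 1:
            raise ConfigurationError(f"ar_coeff must be in [0, 1); got {self.ar_coeff}")
        if self.observation_noise_sd < 0:
            raise ConfigurationError("observation_noise_sd must be non-negative")
        for net, a in self.injury_effect.items():
            if not 0.0 <= a <= 1.0:
                raise ConfigurationError(
                    f"injury_effect[{net!r}]={a} outside [0, 1]"
                )


def generate_atlas(
    grid_shape: tuple[int, int, int],
    n_networks: int = 7,
    seed: int = 0,
    *,
    names: tuple[str, ...] | None = None,
    overlap_cap: float = 0.2,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RSNAtlas:
    """Place ``n_networks`` ellipsoidal masks on a grid, mostly disjoint.

    Centres are drawn at random and accepted only while every pairwise
    overlap fraction stays below ``overlap_cap``; after a bounded number of
    attempts the placement is declared infeasible.
    """
    if names is None:
        names = DEFAULT_NETWORKS[:n_networks] if n_networks <= len(
            DEFAULT_NETWORKS
        ) else tuple(f"NET{i:02d}" for i in range(n_networks))
    if len(names) != n_networks:
        raise ConfigurationError("names length must equal n_networks")
    grid_shape = tuple(int(s) for s in grid_shape)
    rng = np.random.default_rng(seed)
    coords = np.indices(grid_shape, dtype=float)

    # semi-axes ~1/8 of each dimension, at least 1 voxel
    semi = np.maximum(np.array(grid_shape) / 8.0, 1.0)
    masks: list[np.ndarray] = []
    max_attempts = 200 * n_networks
    attempts = 0
    while len(masks) < n_networks:
        if attempts >= max_attempts:
            raise AtlasPlacementError(
                f"could not place {n_networks} masks on grid {grid_shape} with "
                f"pairwise overlap fraction below the cap {overlap_cap} "
                f"({attempts} attempts); use a larger grid or a looser cap"
            )
        attempts += 1
        centre = np.array(
            [rng.uniform(semi[d], grid_shape[d] - semi[d]) if grid_shape[d] > 2 * semi[d]
             else grid_shape[d] / 2.0 for d in range(3)]
        )
        d2 = sum(((coords[d] - centre[d]) / semi[d]) ** 2 for d in range(3))
        cand = d2 <= 1.0
        n_cand = np.count_nonzero(cand)
        if n_cand == 0:
            continue
        ok = True
        for m in masks:
            inter = np.count_nonzero(cand & m)
            if inter / min(n_cand, np.count_nonzero(m)) >= overlap_cap:
                ok = False
                break
        if ok:
            masks.append(cand)
    return RSNAtlas(
        names=names,
        masks=np.stack(masks),
        voxel_size_mm=voxel_size_mm,
        overlap_cap=overlap_cap,
    )


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) series of length n."""
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    c = np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + c * eps[t]
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    return x / x.std(axis=0, ddof=0)


def network_spatial_maps(atlas: RSNAtlas, fwhm_vox: float = 2.0) -> np.ndarray:
    """Smoothed indicator maps of the atlas masks, peak-normalised to 1.

    These are the planted ground-truth spatial maps used to synthesise 4D
    volumes, so atlas matching of a perfect decomposition is exact by
    construction.
    """
    sigma = fwhm_vox / 2.3548
    maps = np.empty((atlas.n_networks, *atlas.grid_shape))
    for k in range(atlas.n_networks):
        m = ndimage.gaussian_filter(atlas.masks[k].astype(float), sigma)
        maps[k] = m / m.max()
    return maps


def generate_cohort(
    spec: CohortSpec, atlas: RSNAtlas
) -> list[SubjectRecord]:
    """Generate one cohort of subjects sharing ground-truth network courses.

    Every subject record carries ``truth_ts`` — its pre-noise node courses
    (equal to the shared courses for unperturbed networks) — so recovery can
    be checked against planted truth. ``node_ts`` is standardized.
    """
    spec.validate(atlas.n_networks)
    unknown = set(spec.injury_effect) - set(atlas.names)
    if unknown:
        raise ConfigurationError(
            f"injury_effect names unknown networks {sorted(unknown)}; "
            f"atlas has {list(atlas.names)}"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    T, N = spec.n_volumes, atlas.n_networks
    shared = _standardize(
        np.column_stack([_ar1(rng, T, spec.ar_coeff) for _ in range(N)])
    )
    atten = np.array([spec.injury_effect.get(name, 0.0) for name in atlas.names])
    spatial = network_spatial_maps(atlas) if spec.make_fmri else None

    subjects: list[SubjectRecord] = []
    for group, count in spec.n_per_group.items():
        injured = group != spec.sham_group
        for i in range(count):
            sid = f"{group}{i + 1:02d}"
            truth = shared.copy()
            if injured and np.any(atten > 0):
                own = _standardize(
                    np.column_stack([_ar1(rng, T, spec.ar_coeff) for _ in range(N)])
                )
                w = np.sqrt(1.0 - atten)
                truth = shared * w + own * np.sqrt(atten)
            observed = truth + spec.observation_noise_sd * rng.standard_normal((T, N))
            ts = NodeTimeSeries(sid, observed, atlas.names).standardize()
            fmri = None
            if spec.make_fmri:
                # volumes = sum_k map_k * course_k(t) + voxel noise, (x,y,z,T)
                fmri = np.tensordot(spatial, ts.data.T, axes=(0, 0)).astype(np.float32)
                fmri += spec.voxel_noise_sd * rng.standard_normal(fmri.shape).astype(
                    np.float32
                )
            subjects.append(
                SubjectRecord(
                    subject_id=sid,
                    group=group,
                    timepoint=spec.timepoint,
                    fmri=fmri,
                    node_ts=ts,
                    truth_ts=truth,
                )
            )
    return subjects


def generate_cbf_maps(
    cohort: list[SubjectRecord],
    atlas: RSNAtlas,
    group_effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    *,
    pattern_seed: int | None = None,
    baseline: float = 50.0,
    pattern_amplitude: float = 0.3,
    subject_noise: float = 0.1,
    disruption_gain: float = 2.0,
    smooth_fwhm_vox: float = 2.0,
) -> list[SubjectRecord]:
    """Fill each record's ``cbf`` with a smooth positive perfusion map.

    All subjects share one smooth baseline pattern (around ``baseline``
    ml/100g/min with relative spatial variation ``pattern_amplitude``); each
    subject perturbs it multiplicatively with its own smooth field of
    relative amplitude ``subject_noise``. ``group_effects`` maps
    group -> {network -> factor}: inside the named mask the subject's values
    are scaled by the factor and, to model that hypoperfusion comes with
    disorganised flow rather than a uniform dimming (a uniform scaling would
    be invisible to the Pearson spatial statistic), mixed with
    subject-specific smooth heterogeneity of relative amplitude
    ``disruption_gain * |1 - factor|``.

    The baseline pattern is an anatomical property and is stable across
    scanning sessions: pass the same ``pattern_seed`` when generating two
    timepoints of one study so only session noise and group effects differ.
    It defaults to ``seed`` (fully independent cohorts).

    Returns the same records, mutated in place, for convenience.
    """
    if baseline <= 0:
        raise ConfigurationError(f"baseline CBF must be positive; got {baseline}")
    group_effects = group_effects or {}
    for g, effects in group_effects.items():
        unknown = set(effects) - set(atlas.names)
        if unknown:
            raise ConfigurationError(
                f"group_effects[{g!r}] names unknown networks {sorted(unknown)}"
            )
    sigma = smooth_fwhm_vox / 2.3548
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pattern_rng = np.random.default_rng(
        np.random.SeedSequence(seed if pattern_seed is None else pattern_seed)
    )

    def smooth_unit_field(generator: np.random.Generator | None = None) -> np.ndarray:
        g = generator if generator is not None else rng
        f = ndimage.gaussian_filter(g.standard_normal(atlas.grid_shape), sigma)
        sd = f.std()
        return f / sd if sd > 0 else f

    pattern = baseline * (1.0 + pattern_amplitude * smooth_unit_field(pattern_rng))
    floor = 0.05 * baseline
    for rec in cohort:
        cbf = pattern * (1.0 + subject_noise * smooth_unit_field())
        effects = group_effects.get(rec.group, {})
        for net, factor in effects.items():
            if factor < 0:
                raise ConfigurationError(
                    f"negative CBF factor {factor} for {rec.group}/{net}"
                )
            mask = atlas.mask_for(net)
            disruption = disruption_gain * abs(1.0 - factor)
            local = 1.0 + disruption * smooth_unit_field()[mask]
            cbf[mask] = cbf[mask] * factor * local
        rec.cbf = np.maximum(cbf, floor)
    return cohort


def split_timepoints(spec: CohortSpec, d7_injury_scale: float = 0.5) -> tuple[CohortSpec, CohortSpec]:
    """Derive D1/D7 cohort specs from one base spec.

    The day-7 cohort halves (by default) every network's injury attenuation,
    emulating partial recovery; seeds are offset so the two timepoints are
    independent draws.
    """
    d1 = replace(spec, timepoint="D1")
    d7 = replace(
        spec,
        timepoint="D7",
        injury_effect={k: v * d7_injury_scale for k, v in spec.injury_effect.items()},
        seed=spec.seed + 1_000_003,
    )
    return d1, d7
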