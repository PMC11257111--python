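"""Group decomposition, atlas-matched node selection, and dual regression.

The concatenated cohort is decomposed into K spatial maps either by spatial
ICA (statistically independent maps, K = 100 by default) or by online sparse
dictionary learning (sparsely activated atoms, K = 300 by default). Each
resting-state network is then represented by the component whose thresholded,
smoothed map best matches the network's atlas mask (highest Pearson
correlation), and per-subject node time courses are read out by the first
stage of dual regression: an ordinary least-squares fit of every volume onto
the selected spatial maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.decomposition import FastICA, MiniBatchDictionaryLearning

from .datatypes import NodeTimeSeries, RSNAtlas, SubjectRecord
from .errors import (
    ConfigurationError,
    DimensionalityError,
    EstimationError,
    SelectionError,
)

__all__ = [
    "ComponentSet",
    "NodeSet",
    "fit_group_decomposition",
    "select_nodes",
    "dual_regression",
    "extract_cohort_timeseries",
]

DEFAULT_K = {"ICA": 100, "sDL": 300}


@dataclass
class ComponentSet:
    """K group-level spatial maps (z-scored per map) plus temporal weights."""

    method: str
    maps: np.ndarray  # (K, x, y, z), each map zero-mean unit-variance
    mixing: np.ndarray  # (T_total, K) group-level temporal weights
    grid_shape: tuple[int, int, int]

    @property
    def K(self) -> int:
        return self.maps.shape[0]


@dataclass
class NodeSet:
    """One selected component per network, with the audit trail."""

    names: tuple[str, ...]
    component_index: dict[str, int]
    match_r: dict[str, float]
    maps: np.ndarray  # (N, x, y, z) post-threshold, post-smoothing maps

    def map_matrix(self) -> np.ndarray:
        """Node maps flattened to (N, n_voxels) for regression."""
        return self.maps.reshape(self.maps.shape[0], -1)


def _as_4d_list(cohort) -> list[np.ndarray]:
    vols = []
    for item in cohort:
        arr = item.fmri if isinstance(item, SubjectRecord) else np.asarray(item)
        if arr is None:
            raise ConfigurationError(
                f"subject {getattr(item, 'subject_id', '?')!r} has no 4D data"
            )
        if arr.ndim != 4:
            raise ConfigurationError(f"expected 4D volumes; got shape {arr.shape}")
        vols.append(np.asarray(arr, dtype=float))
    return vols


def fit_group_decomposition(
    cohort_4d,
    method: str = "ICA",
    K: int | None = None,
    seed: int = 0,
    *,
    sdl_alpha: float = 1.0,
    max_iter: int = 500,
) -> ComponentSet:
    """Decompose temporally concatenated 4D data into K spatial maps.

    ``cohort_4d`` is a sequence of 4D arrays or of records carrying ``fmri``.
    Voxel time series are demeaned per subject before concatenation. For ICA
    the maps are independent-source estimates (FastICA on the voxel
    dimension); for sDL they are dictionary atoms of a sparse code fitted by
    online minibatch updates. Both are deterministic given ``seed``.
    """
    if method not in DEFAULT_K:
        raise ConfigurationError(f"method must be one of {list(DEFAULT_K)}; got {method!r}")
    vols = _as_4d_list(cohort_4d)
    if len(vols) < 2:
        raise ConfigurationError("group decomposition needs at least 2 subjects")
    grid = vols[0].shape[:3]
    for v in vols:
        if v.shape[:3] != grid:
            raise ConfigurationError(
                f"all volumes must share one grid; got {v.shape[:3]} vs {grid}"
            )
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("non-finite voxels in input volume")
    if K is None:
        K = DEFAULT_K[method]
    n_vox = int(np.prod(grid))
    # stack as (T_total, V), demeaning each voxel per subject
    X = np.vstack(
        [v.reshape(n_vox, -1).T - v.reshape(n_vox, -1).T.mean(axis=0) for v in vols]
    )
    t_total = X.shape[0]
    if K >= t_total:
        raise DimensionalityError(
            f"K={K} must be below the concatenated time dimension {t_total}"
        )
    if K > n_vox:
        raise DimensionalityError(f"K={K} exceeds the voxel count {n_vox}")

    if method == "ICA":
        ica = FastICA(
            n_components=K,
            random_state=seed,
            whiten="unit-variance",
            max_iter=max_iter,
            tol=1e-4,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings on toy grids
            sources = ica.fit_transform(X.T)  # voxels as samples -> spatial sources
        maps = sources.T.reshape(K, *grid)
        mixing = ica.mixing_  # (T_total, K)
    else:
        dl = MiniBatchDictionaryLearning(
            n_components=K,
            alpha=sdl_alpha,
            random_state=seed,
            max_iter=max_iter,
            transform_algorithm="lasso_lars",
            transform_alpha=sdl_alpha,
        )
        code = dl.fit_transform(X)  # (T_total, K)
        maps = dl.components_.reshape(K, *grid)
        mixing = code

    # z-score each map so thresholding is comparable across components
    flat = maps.reshape(K, -1)
    mu = flat.mean(axis=1, keepdims=True)
    sd = flat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    maps = ((flat - mu) / sd).reshape(K, *grid)
    return ComponentSet(method=method, maps=maps, mixing=mixing, grid_shape=grid)


def _threshold_smooth(zmap: np.ndarray, z_thresh: float, fwhm: float) -> np.ndarray:
    """Positive-side threshold then Gaussian smooth one z-scored map.

    The sign of a component map is arbitrary (for ICA exactly so); each map
    is flipped to positive skewness first so 'activation' is the heavy tail.
    """
    m = zmap.copy()
    skew = stats.skew(m.ravel())
    if skew < 0:
        m = -m
    m = np.where(m >= z_thresh, m, 0.0)
    if fwhm > 0:
        m = ndimage.gaussian_filter(m, fwhm / 2.3548)
    return m


def select_nodes(
    components: ComponentSet,
    atlas: RSNAtlas,
    z_thresh: float = 1.0,
    smoothing_fwhm: float = 2.0,
    one_to_one: bool = False,
) -> NodeSet:
    """Match each network to the best-correlated component map.

    Each component map is thresholded at ``z >= z_thresh``, smoothed, and
    Pearson-correlated against the binary atlas mask over all voxels; the
    highest-correlation component represents the network (ties and exact
    duplicates resolve to the lower component index). By default one
    component may represent several networks (a warning is emitted);
    ``one_to_one`` switches to a greedy unique assignment by descending
    match correlation.
    """
    if components.grid_shape != atlas.grid_shape:
        raise ConfigurationError(
            f"component grid {components.grid_shape} != atlas grid {atlas.grid_shape}"
        )
    K = components.K
    processed = np.stack(
        [
            _threshold_smooth(components.maps[k], z_thresh, smoothing_fwhm)
            for k in range(K)
        ]
    )
    flat = processed.reshape(K, -1)
    # correlate against each binary mask over all voxels
    corr = np.full((K, atlas.n_networks), -np.inf)
    fc = flat - flat.mean(axis=1, keepdims=True)
    fn = np.linalg.norm(fc, axis=1)
    for j in range(atlas.n_networks):
        m = atlas.masks[j].reshape(-1).astype(float)
        mc = m - m.mean()
        mn = np.linalg.norm(mc)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr[:, j] = (fc @ mc) / (fn * mn)
    corr = np.where(np.isfinite(corr), corr, -np.inf)

    index: dict[str, int] = {}
    match_r: dict[str, float] = {}
    if one_to_one:
        remaining = set(range(K))
        # assign networks in order of their best achievable correlation
        order = sorted(
            range(atlas.n_networks), key=lambda j: -np.max(corr[:, j])
        )
        for j in order:
            cands = sorted(remaining)
            if not cands:
                raise SelectionError("more networks than available components")
            best = max(cands, key=lambda k: (corr[k, j], -k))
            if not np.isfinite(corr[best, j]):
                raise SelectionError(
                    f"no finite atlas correlation for network {atlas.names[j]!r} "
                    f"(all candidate maps empty after thresholding?)"
                )
            index[atlas.names[j]] = best
            match_r[atlas.names[j]] = float(corr[best, j])
            remaining.discard(best)
    else:
        for j, name in enumerate(atlas.names):
            best = int(np.argmax(corr[:, j]))  # argmax ties -> lowest index
            if not np.isfinite(corr[best, j]):
                raise SelectionError(
                    f"no finite atlas correlation for network {name!r} "
                    f"(all candidate maps empty after thresholding?)"
                )
            index[name] = best
            match_r[name] = float(corr[best, j])
        used = list(index.values())
        if len(set(used)) < len(used):
            warnings.warn(
                "one component represents multiple networks; "
                "pass one_to_one=True for a unique assignment",
                stacklevel=2,
            )
    node_maps = np.stack([processed[index[name]] for name in atlas.names])
    return NodeSet(
        names=atlas.names,
        component_index=index,
        match_r=match_r,
        maps=node_maps,
    )


def dual_regression(
    subject_4d: np.ndarray,
    node_maps: NodeSet | np.ndarray,
    node_names: tuple[str, ...] | None = None,
    subject_id: str = "",
    standardize: bool = True,
) -> NodeTimeSeries:
    """Stage-1 dual regression: OLS of each volume onto the node spatial maps.

    Solves, per timepoint t, ``y_t = M^T b_t`` in the least-squares sense,
    where M is the (N, n_voxels) map matrix; the b's stacked over time are the
    subject's node time courses.
    """
    if isinstance(node_maps, NodeSet):
        names = node_maps.names
        M = node_maps.map_matrix()
    else:
        M = np.asarray(node_maps, dtype=float)
        if M.ndim == 4:
            M = M.reshape(M.shape[0], -1)
        names = node_names or tuple(f"node{i}" for i in range(M.shape[0]))
    vol = np.asarray(subject_4d, dtype=float)
    if vol.ndim != 4:
        raise ConfigurationError(f"expected a 4D volume; got shape {vol.shape}")
    n_vox = int(np.prod(vol.shape[:3]))
    if M.shape[1] != n_vox:
        raise ConfigurationError(
            f"maps cover {M.shape[1]} voxels but the volume has {n_vox}"
        )
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[0]:
        raise EstimationError(
            f"node map matrix is rank deficient (rank {rank} < {M.shape[0]} nodes "
            f"{list(names)}); nodes are collinear"
        )
    Y = vol.reshape(n_vox, -1)  # (V, T)
    ts, *_ = np.linalg.lstsq(M.T, Y, rcond=None)  # (N, T)
    out = NodeTimeSeries(subject_id, ts.T, names)
    return out.standardize() if standardize else out


def extract_cohort_timeseries(
    cohort: list[SubjectRecord],
    node_maps: NodeSet,
    standardize: bool = True,
) -> list[SubjectRecord]:
    """Run stage-1 dual regression for every subject, filling ``node_ts``."""
    for rec in cohort:
        if rec.fmri is None:
            raise ConfigurationError(f"subject {rec.subject_id!r} has no 4D data")
        rec.node_ts = dual_regression(
            rec.fmri, node_maps, subject_id=rec.subject_id, standardize=standardize
        )
    return cohort
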