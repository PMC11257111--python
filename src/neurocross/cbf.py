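"""Spatial analogue of the temporal statistic on cerebral-blood-flow maps.

Each subject's CBF map is masked with the seven network masks; cross-group
similarity of a network is the Pearson correlation between paired subjects'
in-mask voxel vectors, Fisher-transformed and aggregated with exactly the
same shuffled drop-one-out machinery as the temporal pipeline (the two share
the trial-pairing generator, so their resampling traces coincide under one
seed). No partial-correlation analogue exists spatially — there is no
conditioning set for voxel vectors — so the estimator is full correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .crossnet import (
    CrossGroupResult,
    aggregate_trials,
    compare_timepoints,  # noqa: F401  (re-exported: timepoint comparison is shared)
    fisher_z,
    iter_trial_pairings,
)
from .datatypes import RSNAtlas, SubjectRecord
from .errors import ConfigurationError

__all__ = ["MaskedCBFVector", "mask_cbf", "cross_group_spatial", "compare_timepoints"]


@dataclass(frozen=True)
class MaskedCBFVector:
    """In-mask CBF intensities of one subject for one network.

    ``voxel_index`` holds the mask's linear voxel indices; it is a function
    of the atlas alone, so all subjects on one atlas share the ordering.
    """

    subject_id: str
    rsn_name: str
    values: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_index", np.asarray(self.voxel_index))
        if values.shape != self.voxel_index.shape:
            raise ConfigurationError("values and voxel_index lengths differ")
        if not np.all(np.isfinite(values)) or np.any(values < 0):
            raise ConfigurationError(
                f"CBF values for {self.subject_id}/{self.rsn_name} must be "
                "finite and non-negative"
            )


def mask_cbf(cbf_map: np.ndarray, atlas: RSNAtlas, subject_id: str = "") -> list[MaskedCBFVector]:
    """Extract one in-mask voxel vector per network from a CBF map."""
    cbf_map = np.asarray(cbf_map, dtype=float)
    if cbf_map.shape != atlas.grid_shape:
        raise ConfigurationError(
            f"CBF map grid {cbf_map.shape} does not match atlas grid "
            f"{atlas.grid_shape}; inputs must arrive co-registered"
        )
    flat = cbf_map.reshape(-1)
    out = []
    for j, name in enumerate(atlas.names):
        idx = np.flatnonzero(atlas.masks[j].reshape(-1))
        out.append(
            MaskedCBFVector(
                subject_id=subject_id, rsn_name=name, values=flat[idx], voxel_index=idx
            )
        )
    return out


def _pair_similarity(vecs_a: list[MaskedCBFVector], vecs_b: list[MaskedCBFVector]) -> np.ndarray:
    """Fisher-z Pearson correlation per network between two subjects."""
    vals = np.empty(len(vecs_a))
    for j, (va, vb) in enumerate(zip(vecs_a, vecs_b)):
        a = va.values - va.values.mean()
        b = vb.values - vb.values.mean()
        denom = np.linalg.norm(a) * np.linalg.norm(b)
        r = float(a @ b / denom) if denom > 0 else 0.0
        vals[j] = fisher_z(r)
    return vals


def cross_group_spatial(
    treatment_cbf: Sequence[np.ndarray | SubjectRecord],
    sham_cbf: Sequence[np.ndarray | SubjectRecord],
    atlas: RSNAtlas,
    n_trials: int = 128,
    seed: int = 0,
) -> CrossGroupResult:
    """Cross-group spatial similarity with drop-one-out shuffled resampling.

    Accepts raw 3D maps or subject records carrying ``cbf``. Per trial, one
    pooled subject is dropped, both groups are shuffled and paired
    positionally, and the per-pair per-network Fisher-z spatial correlations
    are averaged over pairs; negatives are rejected at aggregation exactly as
    in the temporal pipeline.
    """

    def vectors(group, label):
        out = []
        for i, item in enumerate(group):
            if isinstance(item, SubjectRecord):
                if item.cbf is None:
                    raise ConfigurationError(
                        f"subject {item.subject_id!r} has no CBF map"
                    )
                out.append(mask_cbf(item.cbf, atlas, item.subject_id))
            else:
                out.append(mask_cbf(item, atlas, f"{label}{i:02d}"))
        return out

    tr = vectors(treatment_cbf, "treat")
    sh = vectors(sham_cbf, "sham")
    n_nodes = atlas.n_networks
    trials = np.empty((n_trials, n_nodes))
    drops = np.empty(n_trials, dtype=int)
    for t, (drop_a, drop_b, pairs) in enumerate(
        iter_trial_pairings(len(tr), len(sh), n_trials, seed)
    ):
        drops[t] = drop_a if drop_a is not None else len(tr) + drop_b
        vals = np.empty((len(pairs), n_nodes))
        for p, (ia, ib) in enumerate(pairs):
            vals[p] = _pair_similarity(tr[ia], sh[ib])
        trials[t] = vals.mean(axis=0)
    meta = {
        "n_trials": n_trials,
        "seed": seed,
        "estimator": "full",
        "fisher": True,
        "rejection": "trial",
        "modality": "cbf-spatial",
        "n_treatment": len(tr),
        "n_sham": len(sh),
        "pairing": "positional-after-shuffle",
        "drop_from": "pooled",
    }
    return aggregate_trials(trials, atlas.names, meta, drop_index=drops)
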