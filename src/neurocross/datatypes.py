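"""Core containers shared by the generator and the analysis stages.

Everything lives in a single common voxel grid: co-registration is an input
contract, not something this package performs. Coordinates are 0-based voxel
indices; NIfTI affines are carried through I/O untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: The seven resting-state networks used throughout: executive control,
#: sensorimotor, default mode, visual, auditory, basal ganglia, salience.
DEFAULT_NETWORKS: tuple[str, ...] = ("EXN", "SMN", "DMN", "VIS", "AUD", "BAS", "SAL")


@dataclass(frozen=True)
class RSNAtlas:
    """A named set of binary resting-state-network masks on one voxel grid.

    Parameters
    ----------
    names
        Ordered network labels; the order fixes node order everywhere downstream.
    masks
        Boolean array of shape ``(n_networks, *grid_shape)``.
    voxel_size_mm
        Physical voxel spacing, carried through to NIfTI output.
    overlap_cap
        Maximum allowed pairwise overlap fraction (intersection over the
        smaller mask); atlas matching is only identifiable when masks are
        mostly distinct.
    """

    names: tuple[str, ...]
    masks: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    overlap_cap: float = 0.2

    def __post_init__(self) -> None:
        masks = np.asarray(self.masks, dtype=bool)
        object.__setattr__(self, "masks", masks)
        object.__setattr__(self, "names", tuple(self.names))
        if masks.ndim != 4 or masks.shape[0] != len(self.names):
            raise ConfigurationError(
                f"masks must be (n_networks, x, y, z); got shape {masks.shape} "
                f"for {len(self.names)} names"
            )
        sizes = masks.reshape(masks.shape[0], -1).sum(axis=1)
        if np.any(sizes == 0):
            empty = [n for n, s in zip(self.names, sizes) if s == 0]
            raise ConfigurationError(f"empty atlas masks: {empty}")
        for i in range(len(self.names)):
            for j in range(i + 1, len(self.names)):
                frac = self.overlap_fraction(i, j)
                if frac >= self.overlap_cap:
                    raise ConfigurationError(
                        f"masks {self.names[i]}/{self.names[j]} overlap fraction "
                        f"{frac:.3f} >= cap {self.overlap_cap}"
                    )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(self.masks.shape[1:])

    @property
    def n_networks(self) -> int:
        return len(self.names)

    def overlap_fraction(self, i: int, j: int) -> float:
        """Intersection size over the smaller mask's size."""
        a, b = self.masks[i], self.masks[j]
        inter = np.count_nonzero(a & b)
        return inter / min(np.count_nonzero(a), np.count_nonzero(b))

    def mask_for(self, name: str) -> np.ndarray:
        return self.masks[self.names.index(name)]


@dataclass
class NodeTimeSeries:
    """Per-subject node activity: a T-by-N matrix plus node labels.

    Column order must be identical across all subjects in a study; the
    pairing machinery refuses to combine series whose labels differ.
    """

    subject_id: str
    data: np.ndarray
    node_names: tuple[str, ...]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.node_names = tuple(self.node_names)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.node_names):
            raise ConfigurationError(
                f"time-series matrix {self.data.shape} does not match "
                f"{len(self.node_names)} node names"
            )
        if not np.all(np.isfinite(self.data)):
            raise ConfigurationError(
                f"non-finite values in time series of {self.subject_id!r}"
            )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    def standardize(self) -> "NodeTimeSeries":
        """Return a copy with zero-mean, unit-variance columns."""
        x = self.data - self.data.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ConfigurationError(
                f"constant column(s) in {self.subject_id!r}; cannot standardize"
            )
        return NodeTimeSeries(self.subject_id, x / sd, self.node_names, standardized=True)


@dataclass
class SubjectRecord:
    """One subject at one timepoint, with whichever data modalities exist."""

    subject_id: str
    group: str
    timepoint: str = "D1"
    fmri: np.ndarray | None = None  # (x, y, z, T)
    node_ts: NodeTimeSeries | None = None
    cbf: np.ndarray | None = None  # (x, y, z)
    truth_ts: np.ndarray | None = field(default=None, repr=False)  # pre-noise node courses

    def __post_init__(self) -> None:
        if self.fmri is None and self.node_ts is None:
            raise ConfigurationError(
                f"subject {self.subject_id!r} has neither fmri nor node_ts"
            )
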