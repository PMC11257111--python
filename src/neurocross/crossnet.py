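"""Cross-group temporal correlation: the package's core statistic.

One treatment subject and one baseline (sham) subject are concatenated along
the node axis into a 2N-node *pseudo-subject*; the (partial) correlation
matrix of that pseudo-subject then contains, on the diagonal of its
off-diagonal N-by-N block, the same-node treatment-versus-baseline
similarities. Because any single pairing is arbitrary, the statistic is
aggregated over shuffled drop-one-out trials: each trial excludes one subject
drawn from the pooled roster, shuffles both groups, pairs them positionally,
and averages the Fisher-transformed cross-diagonals over the pairs. Negative
similarities are ambiguous as a measure of shared function and are rejected
before aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import NodeTimeSeries
from .errors import (
    ComparisonError,
    ConfigurationError,
    EstimationError,
    PairingError,
    ResamplingError,
)

__all__ = [
    "PseudoSubject",
    "NetMat",
    "CrossGroupResult",
    "EstimatorConfig",
    "build_pseudo_subject",
    "compute_netmat",
    "cross_diagonal",
    "fisher_z",
    "resample_cross_group",
    "compare_timepoints",
    "iter_trial_pairings",
    "aggregate_trials",
]

#: correlations are clipped to +/-(1 - FISHER_CLIP) before atanh, so identity
#: pairings give a finite ceiling z_max = atanh(1 - 1e-7) ~ 8.1 instead of inf
FISHER_CLIP = 1e-7
Z_MAX = float(np.arctanh(1.0 - FISHER_CLIP))


@dataclass(frozen=True)
class PseudoSubject:
    """T-by-2N matrix: treatment nodes first, baseline nodes second."""

    data: np.ndarray
    node_names: tuple[str, ...]
    source_pair: tuple[str, str]

    @property
    def n_nodes(self) -> int:
        """Number of nodes per half (N)."""
        return self.data.shape[1] // 2


@dataclass(frozen=True)
class NetMat:
    """A 2N-by-2N network matrix with its estimator settings."""

    matrix: np.ndarray
    estimator: str
    ridge_rho: float = 0.0
    fisher: bool = False


@dataclass(frozen=True)
class EstimatorConfig:
    """Netmat estimator settings used by the resampling loop.

    ``partial`` with a small ridge is the default: partial correlation
    isolates direct node-to-node coupling by conditioning on the remaining
    nodes, and the ridge keeps the precision matrix estimable when T is not
    much larger than 2N.
    """

    estimator: str = "partial"
    ridge_rho: float = 0.1
    fisher: bool = True

    def __post_init__(self) -> None:
        if self.estimator not in ("full", "partial"):
            raise ConfigurationError(f"unknown estimator {self.estimator!r}")
        if self.ridge_rho < 0:
            raise ConfigurationError("ridge_rho must be non-negative")


@dataclass
class CrossGroupResult:
    """Per-node similarity distribution over resampling trials.

    ``trials`` keeps every raw trial value (negatives included) so users can
    re-aggregate or run subject-level inference; ``mean``/``stderr`` are
    computed over the retained (non-negative) values only.
    """

    node_names: tuple[str, ...]
    trials: np.ndarray  # (n_trials, N)
    mean: np.ndarray
    stderr: np.ndarray
    n_rejected_negative: np.ndarray
    meta: dict = field(default_factory=dict)
    #: pooled index of the subject each trial dropped (enables jackknife
    #: subject-level inference); None when the provenance is unknown
    drop_index: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    def retained(self, node: int) -> np.ndarray:
        """Non-negative trial values for one node."""
        col = self.trials[:, node]
        return col[col >= 0]

    def jackknife_se(self) -> np.ndarray:
        """Subject-level standard error of each node's mean similarity.

        Derived from the drop-one-out structure (see
        :func:`_jackknife_mean_var`); unlike ``stderr`` — the standard error
        of the trial values, which treats dependent trials as independent —
        this reflects the run-to-run uncertainty due to subject sampling.
        """
        if self.drop_index is None:
            return np.full(len(self.node_names), np.nan)
        return np.array(
            [
                np.sqrt(_jackknife_mean_var(self, k)[1])
                for k in range(len(self.node_names))
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": list(self.node_names),
                "mean_z": self.mean,
                "stderr": self.stderr,
                "jack_se": self.jackknife_se(),
                "n_retained": self.trials.shape[0] - self.n_rejected_negative,
                "n_rejected": self.n_rejected_negative,
            }
        )


def build_pseudo_subject(ts_a: NodeTimeSeries, ts_b: NodeTimeSeries) -> PseudoSubject:
    """Concatenate two subjects' node series along the node axis.

    Columns are standardized so every downstream covariance is a correlation.
    Node order must match exactly; a silent reorder would scramble the
    cross-diagonal.
    """
    if ts_a.n_volumes != ts_b.n_volumes:
        raise PairingError(
            f"volume counts differ: {ts_a.subject_id}={ts_a.n_volumes}, "
            f"{ts_b.subject_id}={ts_b.n_volumes}"
        )
    if ts_a.node_names != ts_b.node_names:
        raise PairingError(
            f"node order differs between {ts_a.subject_id} and {ts_b.subject_id}: "
            f"{ts_a.node_names} vs {ts_b.node_names}"
        )
    a = ts_a if ts_a.standardized else ts_a.standardize()
    b = ts_b if ts_b.standardized else ts_b.standardize()
    names = tuple(f"{n}|a" for n in a.node_names) + tuple(
        f"{n}|b" for n in b.node_names
    )
    return PseudoSubject(
        data=np.hstack([a.data, b.data]),
        node_names=names,
        source_pair=(ts_a.subject_id, ts_b.subject_id),
    )


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Variance-stabilising atanh with clipping to keep the ceiling finite."""
    return np.arctanh(np.clip(r, -1.0 + FISHER_CLIP, 1.0 - FISHER_CLIP))


def _partial_from_cov(cov: np.ndarray, rho: float) -> np.ndarray:
    p = cov.shape[0]
    try:
        prec = np.linalg.inv(cov + rho * np.eye(p))
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "covariance is singular; pass ridge_rho > 0 to regularise"
        ) from exc
    d = np.sqrt(np.diag(prec))
    if rho == 0.0 and np.linalg.cond(cov) > 1e12:
        raise EstimationError(
            "covariance is numerically singular; pass ridge_rho > 0 to regularise"
        )
    pc = -prec / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def compute_netmat(
    ps: PseudoSubject,
    estimator: str = "partial",
    ridge_rho: float = 0.1,
    fisher: bool = True,
) -> NetMat:
    """Estimate the 2N-by-2N network matrix of a pseudo-subject.

    ``full`` is the Pearson correlation matrix. ``partial`` is the negated,
    normalised off-diagonal of the (optionally ridge-regularised) inverse of
    the correlation matrix: ``rho_ij = -P_ij / sqrt(P_ii P_jj)`` with
    ``P = (Sigma + rho I)^-1``. With ``fisher`` the off-diagonals are
    atanh-transformed (clipped; the diagonal maps to the finite ceiling).
    """
    cfg = EstimatorConfig(estimator, ridge_rho, fisher)
    x = ps.data
    cov = np.cov(x, rowvar=False, ddof=1)
    # standardized columns: rescale to an exact correlation matrix
    d = np.sqrt(np.diag(cov))
    cov = cov / np.outer(d, d)
    if cfg.estimator == "full":
        mat = cov.copy()
    else:
        mat = _partial_from_cov(cov, cfg.ridge_rho)
    mat = (mat + mat.T) / 2.0
    if cfg.fisher:
        mat = fisher_z(mat)
    return NetMat(matrix=mat, estimator=cfg.estimator, ridge_rho=cfg.ridge_rho, fisher=cfg.fisher)


def cross_diagonal(nm: NetMat | np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Same-node cross-group similarities: entries ``M[i, i + N]``.

    These are the diagonal of the treatment-versus-baseline off-diagonal
    block of the pseudo-subject netmat.
    """
    mat = nm.matrix if isinstance(nm, NetMat) else np.asarray(nm)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ConfigurationError(f"netmat must be square; got {mat.shape}")
    if mat.shape[0] % 2 != 0:
        raise ConfigurationError(
            f"netmat dimension {mat.shape[0]} is odd; pseudo-subjects have 2N nodes"
        )
    n = mat.shape[0] // 2
    if n_nodes is not None and n_nodes != n:
        raise ConfigurationError(
            f"n_nodes={n_nodes} inconsistent with matrix dimension {mat.shape[0]}"
        )
    return mat[np.arange(n), np.arange(n) + n].copy()


def iter_trial_pairings(
    n_a: int, n_b: int, n_trials: int, seed: int
) -> Iterator[tuple[int | None, int | None, list[tuple[int, int]]]]:
    """Yield per-trial (dropped_a, dropped_b, pair list) for drop-one-out trials.

    Each trial excludes one subject drawn uniformly from the pooled roster of
    both groups, shuffles the survivors of each group independently, and
    pairs them positionally up to the smaller group size. The master seed
    spawns one substream per trial, so increasing ``n_trials`` never
    reshuffles earlier trials. Both the temporal and the spatial pipelines
    use this generator, so their resampling traces coincide under one seed.
    """
    if n_a < 2 or n_b < 2:
        raise ResamplingError(
            f"drop-one-out needs at least 2 subjects per group; got {n_a} and {n_b}"
        )
    children = np.random.SeedSequence(seed).spawn(n_trials)
    for child in children:
        rng = np.random.default_rng(child)
        drop = int(rng.integers(n_a + n_b))
        drop_a = drop if drop < n_a else None
        drop_b = drop - n_a if drop >= n_a else None
        idx_a = [i for i in range(n_a) if i != drop_a]
        idx_b = [i for i in range(n_b) if i != drop_b]
        rng.shuffle(idx_a)
        rng.shuffle(idx_b)
        yield drop_a, drop_b, list(zip(idx_a, idx_b))


def aggregate_trials(
    trials: np.ndarray,
    node_names: Sequence[str],
    meta: dict | None = None,
    drop_index: np.ndarray | None = None,
) -> CrossGroupResult:
    """Negative rejection + mean/standard error over retained trial values."""
    trials = np.asarray(trials, dtype=float)
    n_trials, n_nodes = trials.shape
    mean = np.full(n_nodes, np.nan)
    stderr = np.full(n_nodes, np.nan)
    n_rej = np.zeros(n_nodes, dtype=int)
    for k in range(n_nodes):
        col = trials[:, k]
        keep = col[col >= 0]
        n_rej[k] = n_trials - keep.size
        if keep.size:
            mean[k] = keep.mean()
            stderr[k] = (
                keep.std(ddof=1) / np.sqrt(keep.size) if keep.size > 1 else 0.0
            )
    return CrossGroupResult(
        node_names=tuple(node_names),
        trials=trials,
        mean=mean,
        stderr=stderr,
        n_rejected_negative=n_rej,
        meta=dict(meta or {}),
        drop_index=None if drop_index is None else np.asarray(drop_index, dtype=int),
    )


def resample_cross_group(
    treatment: Sequence[NodeTimeSeries],
    sham: Sequence[NodeTimeSeries],
    n_trials: int = 128,
    seed: int = 0,
    estimator_cfg: EstimatorConfig | None = None,
    rejection: str = "trial",
) -> CrossGroupResult:
    """Shuffled drop-one-out resampling of the cross-group similarity.

    Per trial: drop one pooled subject, shuffle both groups, pair
    positionally, compute each pair's netmat cross-diagonal, and average over
    pairs. ``rejection`` controls where negative similarities are discarded:
    ``"trial"`` (default) rejects a node's negative *trial averages* during
    aggregation, keeping the trial count interpretable; ``"pair"`` rejects
    negative *per-pair* values before the trial average.
    """
    cfg = estimator_cfg or EstimatorConfig()
    if rejection not in ("trial", "pair"):
        raise ConfigurationError(f"unknown rejection stage {rejection!r}")
    treatment = [t if t.standardized else t.standardize() for t in treatment]
    sham = [s if s.standardized else s.standardize() for s in sham]
    names = treatment[0].node_names
    for ts in (*treatment, *sham):
        if ts.node_names != names:
            raise PairingError(f"node order differs for subject {ts.subject_id!r}")
    n_nodes = len(names)
    trials = np.empty((n_trials, n_nodes))
    drops = np.empty(n_trials, dtype=int)
    for t, (drop_a, drop_b, pairs) in enumerate(
        iter_trial_pairings(len(treatment), len(sham), n_trials, seed)
    ):
        drops[t] = drop_a if drop_a is not None else len(treatment) + drop_b
        vals = np.empty((len(pairs), n_nodes))
        for p, (ia, ib) in enumerate(pairs):
            ps = build_pseudo_subject(treatment[ia], sham[ib])
            nm = compute_netmat(ps, cfg.estimator, cfg.ridge_rho, cfg.fisher)
            vals[p] = cross_diagonal(nm)
        if rejection == "pair":
            masked = np.where(vals >= 0, vals, np.nan)
            with np.errstate(invalid="ignore"):
                trial_val = np.nanmean(masked, axis=0)
            # a node with no surviving pair keeps a negative marker so the
            # trial is counted as rejected for that node
            trial_val = np.where(np.isnan(trial_val), -np.inf, trial_val)
        else:
            trial_val = vals.mean(axis=0)
        trials[t] = trial_val
    meta = {
        "n_trials": n_trials,
        "seed": seed,
        "estimator": cfg.estimator,
        "ridge_rho": cfg.ridge_rho,
        "fisher": cfg.fisher,
        "rejection": rejection,
        "n_treatment": len(treatment),
        "n_sham": len(sham),
        "treatment_ids": [t.subject_id for t in treatment],
        "sham_ids": [s.subject_id for s in sham],
        "pairing": "positional-after-shuffle",
        "drop_from": "pooled",
    }
    return aggregate_trials(trials, names, meta, drop_index=drops)


def _jackknife_mean_var(
    res: CrossGroupResult, node: int
) -> tuple[float, float, int]:
    """Delete-one-subject mean and jackknife variance for one node.

    Trials are grouped by which pooled subject they dropped; the per-group
    means are delete-one replicates of the similarity statistic, and the
    standard jackknife formula ``(n-1)/n * sum((theta_i - theta_bar)^2)``
    estimates its subject-sampling variance. Pairing-shuffle noise inside
    each group inflates the estimate slightly, which errs conservative.
    """
    if res.drop_index is None:
        raise ComparisonError(
            "jackknife test needs per-trial drop provenance; this result was "
            "aggregated without drop_index (use test='welch' instead)"
        )
    vals = res.trials[:, node]
    keep = vals >= 0
    if not np.any(keep):
        return np.nan, np.nan, 0
    m = float(vals[keep].mean())
    thetas = []
    for s in np.unique(res.drop_index):
        v = vals[(res.drop_index == s) & keep]
        if v.size:
            thetas.append(v.mean())
    th = np.asarray(thetas)
    n = th.size
    if n < 2:
        return m, np.nan, n
    var = (n - 1) / n * float(np.sum((th - th.mean()) ** 2))
    return m, var, n


def compare_timepoints(
    d1: CrossGroupResult,
    d7: CrossGroupResult,
    alpha: float = 0.05,
    test: str = "jackknife",
) -> pd.DataFrame:
    """Per-node D7-versus-D1 comparison of cross-group similarity.

    The default ``jackknife`` test compares the two run means with a
    subject-level variance estimate built from the drop-one-out structure
    itself (see :func:`_jackknife_mean_var`), combined Welch-Satterthwaite
    style. Resampling trials reuse subjects, so tests that treat the trial
    values as independent samples (``welch``: Welch's t; ``anova``: one-way
    F) grossly overstate their effective sample size; they are provided for
    comparability with error-bar conventions but are strongly anticonservative.
    No multiple-comparison correction is applied.
    """
    if d1.node_names != d7.node_names:
        raise ComparisonError(
            f"node sets differ: {d1.node_names} vs {d7.node_names}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0, 1]; got {alpha}")
    if test not in ("jackknife", "welch", "anova"):
        raise ConfigurationError(f"unknown test {test!r}")
    rows = []
    for k, node in enumerate(d1.node_names):
        a, b = d1.retained(k), d7.retained(k)
        diff = b.mean() - a.mean() if a.size and b.size else np.nan
        if test == "jackknife":
            m1, v1, n1 = _jackknife_mean_var(d1, k)
            m2, v2, n2 = _jackknife_mean_var(d7, k)
            if np.isfinite(v1) and np.isfinite(v2):
                se = np.sqrt(v1 + v2)
                if se == 0.0:
                    stat, p = (0.0, 1.0) if m1 == m2 else (np.inf, 0.0)
                else:
                    stat = (m2 - m1) / se
                    df = (v1 + v2) ** 2 / (
                        v1**2 / (n1 - 1) + v2**2 / (n2 - 1)
                    ) if v1 + v2 > 0 else 1.0
                    p = 2.0 * stats.t.sf(abs(stat), df)
            else:
                stat, p = np.nan, np.nan
        elif a.size > 1 and b.size > 1 and (a.std() > 0 or b.std() > 0):
            if test == "welch":
                stat, p = stats.ttest_ind(b, a, equal_var=False)
            else:
                stat, p = stats.f_oneway(b, a)
        elif a.size and b.size and np.array_equal(np.sort(a), np.sort(b)):
            stat, p = 0.0, 1.0
        else:
            stat, p = np.nan, np.nan
        significant = bool(np.isfinite(p) and p < alpha)
        rows.append(
            {
                "node": node,
                "d1_mean": a.mean() if a.size else np.nan,
                "d7_mean": b.mean() if b.size else np.nan,
                "diff": diff,
                "stat": stat,
                "p": p,
                "significant": significant,
                "direction": "increase" if diff > 0 else ("decrease" if diff < 0 else "none"),
            }
        )
    return pd.DataFrame(rows)
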