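"""Highly variable feature (HVF) selection.

Cross-sample variability per feature is summarised by a "quantile" standard
deviation that drops one minimum and one maximum observation, making it robust
to single-sample outliers.  The distribution of these SDs over features is
modelled as a two-component Gaussian mixture (unmodulated vs. highly
variable), fitted by EM.  A variability threshold is chosen to maximise the
expected number of highly variable minus unmodulated features above it, the
fit is repeated over several independently initialised runs, and the mean
threshold is floored to the nearest 0.5 below for a reproducible final cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass
class MixtureFit:
    """Two-component 1-D Gaussian mixture; component 2 is the high-mean one."""

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    converged: bool
    ll_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture SDs must be positive")
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("mixture weights must sum to 1")
        if self.means[0] > self.means[1]:
            raise ValueError("components must be ordered by mean")

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior P(component | x); rows sum to 1. Column 1 = highly variable."""
        x = np.asarray(x, dtype=float)
        dens = np.column_stack([
            self.weights[k] * _normal_pdf(x, self.means[k], self.sds[k])
            for k in (0, 1)
        ])
        total = dens.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        return dens / total

    @property
    def separation(self) -> float:
        """|mu2 - mu1| / pooled SD; a diagnostic for degenerate 2-component fits."""
        pooled = float(np.sqrt(np.mean(np.square(self.sds))))
        return abs(self.means[1] - self.means[0]) / pooled


@dataclass
class HVFResult:
    quantile_sds: "np.ndarray"        # per-feature, NaN when insufficient data
    feature_ids: list[str]
    run_thresholds: list[float]
    final_threshold: float
    hv_features: list[str]
    fits: list[MixtureFit] = field(default_factory=list)


def _normal_pdf(x, mu, sd):
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * np.sqrt(2.0 * np.pi))


def quantile_sd(values: np.ndarray) -> float:
    """Sample SD after dropping one minimum and one maximum observation.

    Missing values are removed first; exactly one occurrence of the minimum
    and one of the maximum are trimmed.  Returns NaN when fewer than two
    values remain.
    """
    v = np.asarray(values, dtype=float)
    v = np.sort(v[np.isfinite(v)])
    if v.size < 4:
        # after trimming 2 values fewer than 2 remain
        return np.nan
    trimmed = v[1:-1]
    return float(np.std(trimmed, ddof=1))


def quantile_sds(matrix: OmicsMatrix) -> np.ndarray:
    vals = matrix.values.to_numpy(dtype=float)
    return np.array([quantile_sd(row) for row in vals])


def _kmeans2_1d(x: np.ndarray, rng: np.random.Generator,
                jitter: float) -> tuple[np.ndarray, np.ndarray]:
    """Tiny 1-D 2-means with jittered quantile initialisation."""
    c = np.quantile(x, [0.25, 0.75]) + rng.normal(0, jitter, 2)
    c = np.sort(c)
    for _ in range(50):
        assign = np.abs(x[:, None] - c[None, :]).argmin(axis=1)
        new = np.array([x[assign == k].mean() if (assign == k).any() else c[k]
                        for k in (0, 1)])
        if np.allclose(new, c):
            break
        c = new
    return assign, c


def fit_two_component_mixture(sds: np.ndarray, seed: int | None = None,
                              n_restarts: int = 5, max_iter: int = 1000,
                              tol: float = 1e-8) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to the SD distribution.

    Best of ``n_restarts`` runs initialised from 2-means clustering with
    jitter; converges on the log-likelihood change.  Components are ordered
    by mean.  Raises on near-degenerate component SDs (< 1e-6).
    """
    x = np.asarray(sds, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise ValueError(f"need >= 20 finite values to fit a mixture, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: mixture fit is degenerate")
    rng = np.random.default_rng(seed)
    spread = np.std(x)

    best: MixtureFit | None = None
    for _ in range(n_restarts):
        assign, centers = _kmeans2_1d(x, rng, jitter=0.1 * spread)
        mu = centers.astype(float)
        sd = np.array([max(x[assign == k].std(), 1e-3 * spread) if (assign == k).sum() > 1
                       else 0.5 * spread for k in (0, 1)])
        w = np.array([(assign == k).mean() for k in (0, 1)])
        w = np.clip(w, 1e-3, 1 - 1e-3)
        w /= w.sum()

        ll_prev, trace, converged, it = -np.inf, [], False, 0
        for it in range(1, max_iter + 1):
            dens = np.column_stack([w[k] * _normal_pdf(x, mu[k], sd[k]) for k in (0, 1)])
            total = dens.sum(axis=1)
            total[total <= 0] = np.finfo(float).tiny
            ll = float(np.log(total).sum())
            trace.append(ll)
            resp = dens / total[:, None]
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-12)
            w = nk / x.size
            mu = (resp * x[:, None]).sum(axis=0) / nk
            var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
            sd = np.sqrt(np.maximum(var, 0.0))
            if np.any(sd < 1e-6):
                raise ValueError("near-degenerate mixture component (sd < 1e-6)")
            if np.isfinite(ll_prev) and abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        order = np.argsort(mu)
        fit = MixtureFit(means=tuple(float(m) for m in mu[order]),
                         sds=tuple(float(s) for s in sd[order]),
                         weights=tuple(float(v) for v in w[order]),
                         log_likelihood=trace[-1], n_iterations=it,
                         converged=converged, ll_trace=trace)
        if best is None or fit.log_likelihood > best.log_likelihood:
            best = fit
    if not best.converged:
        logger.warning("mixture EM did not converge within %d iterations", max_iter)
    return best


def optimal_threshold(fit: MixtureFit, sds: np.ndarray) -> float:
    """Threshold maximising sum over x > t of [P(HV|x) - P(unmodulated|x)].

    The candidate grid is every observed SD plus the midpoints between
    consecutive observed SDs; ties are broken towards the smallest t.  With
    no high-variance mass above any candidate, the maximum of 0 is attained
    at the largest observed value (empty HV set).
    """
    x = np.asarray(sds, dtype=float)
    x = np.sort(x[np.isfinite(x)])
    if x.size == 0:
        raise ValueError("no finite SD values: empty threshold grid")
    mids = (x[:-1] + x[1:]) / 2.0
    grid = np.unique(np.concatenate([x, mids]))
    resp = fit.responsibilities(x)
    margin = resp[:, 1] - resp[:, 0]  # P(HV|x) - P(unmodulated|x)
    # objective(t) = sum of margin over x > t, computed via suffix sums
    suffix = np.concatenate([np.cumsum(margin[::-1])[::-1], [0.0]])
    idx = np.searchsorted(x, grid, side="right")
    objective = suffix[idx]
    best = np.flatnonzero(objective >= objective.max() - 1e-12)[0]
    return float(grid[best])


def floor_to_half(value: float) -> float:
    """Round down to the nearest multiple of 0.5."""
    return float(np.floor(value * 2.0) / 2.0)


def select_hvf(matrix: OmicsMatrix, n_runs: int = 10, seed: int | None = None,
               n_restarts: int = 5) -> HVFResult:
    """Run the full HVF procedure on a features x samples matrix.

    ``n_runs`` independent EM fits (distinct sub-seeds) each yield a
    threshold; the final threshold is the run mean floored to 0.5, and the HV
    set is every feature whose quantile SD exceeds it.
    """
    sds = quantile_sds(matrix)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2 ** 31 - 1, size=n_runs)
    thresholds, fits = [], []
    for s in sub_seeds:
        fit = fit_two_component_mixture(sds, seed=int(s), n_restarts=n_restarts)
        fits.append(fit)
        thresholds.append(optimal_threshold(fit, sds))
    final = floor_to_half(float(np.mean(thresholds)))
    hv = [f for f, s in zip(matrix.feature_ids, sds)
          if np.isfinite(s) and s > final]
    logger.info("HVF: run thresholds %s -> final %.1f, %d features selected",
                np.round(thresholds, 3), final, len(hv))
    return HVFResult(quantile_sds=sds, feature_ids=matrix.feature_ids,
                     run_thresholds=[float(t) for t in thresholds],
                     final_threshold=final, hv_features=hv, fits=fits)
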