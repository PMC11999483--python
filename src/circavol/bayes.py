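"""Sequential Bayesian decomposition of a bounded daily series into mean,
volatility, and noise.

Generative model (per time step, in the transformed space):

    log vmu_t = log vmu_{t-1} + Normal(0, kmu)
    log SD_t  = log SD_{t-1}  + Normal(0, vSD)
    mu_t      = mu_{t-1}      + Normal(0, exp(log vmu_t))
    y_t       ~ Normal(mu_t, exp(log SD_t))

The filter inverts this model on a discrete grid: the joint posterior over
(mu, log vmu, log SD) is carried as a probability mass array, one slice per
(kmu, vSD) candidate pair, mixed by Bayesian model averaging.  Each step
alternates a *predict* (diffusion through the discretized transition
kernels) with an *update* (Gaussian likelihood reweighting) when the day
was observed; missing days get predict only, so posterior uncertainty
grows through gaps.  Point estimates are the expectations of the
marginalized posterior: mu in its natural (transformed) space, volatility
and noise in log space.

Raw bounded scores enter through the bounded logit transform
``logit((raw - min)/(max - min) * 0.8 + 0.1)``, which maps the observed
range onto an unbounded scale while keeping the endpoints finite.

Transition kernels are built from Gaussian CDF differences over cell
edges, with the two outermost cells extended to +-infinity: probability
mass that would diffuse beyond the grid is collected in the boundary
cells, so total mass is conserved exactly; a leakage diagnostic records
steps where that out-of-bounds share exceeds 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logit, expit, ndtr

__all__ = [
    "TransformSpec",
    "FilterConfig",
    "FilterModel",
    "PosteriorState",
    "FilterEstimates",
    "bounded_logit_transform",
    "inverse_bounded_logit",
    "predict_step",
    "update_step",
    "run_filter",
    "fit_series_bundle",
]

_MU_BOUND = 1.2 * logit(0.95)  # transformed-space mu range, widened 20%


class LikelihoodUnderflowError(RuntimeError):
    """Total likelihood underflow during an update (offending index attached)."""

    def __init__(self, index: int):
        super().__init__(f"likelihood underflow at time index {index}")
        self.index = index


# ---------------------------------------------------------------------------
# bounded logit transform
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformSpec:
    """Observed-range bounds used by the bounded logit transform."""

    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.max > self.min):
            raise ValueError("max must exceed min")


def bounded_logit_transform(raw, spec: TransformSpec):
    """Map raw scores in [min, max] to the unbounded filter space.

    min maps to logit(0.1) = ln(1/9), max to logit(0.9); NaN (missing)
    entries pass through untouched.
    """
    x = np.asarray(raw, dtype=float)
    obs = ~np.isnan(x)
    if np.any((x[obs] < spec.min) | (x[obs] > spec.max)):
        raise ValueError("raw values outside [min, max]")
    out = np.full(x.shape, np.nan)
    out[obs] = logit((x[obs] - spec.min) / (spec.max - spec.min) * 0.8 + 0.1)
    return out if x.ndim else float(out)


def inverse_bounded_logit(transformed, spec: TransformSpec):
    """Inverse of :func:`bounded_logit_transform` (NaN passes through)."""
    z = np.asarray(transformed, dtype=float)
    out = (expit(z) - 0.1) / 0.8 * (spec.max - spec.min) + spec.min
    return out if z.ndim else float(out)


# ---------------------------------------------------------------------------
# configuration and precomputed model
# ---------------------------------------------------------------------------

def _default_candidates() -> np.ndarray:
    return np.logspace(-3, 0, 5)


@dataclass(frozen=True)
class FilterConfig:
    """Grid sizes/bounds and (kmu, vSD) candidate sets for the filter.

    Defaults: 40 points per dynamic dimension; mu spans the transformed
    space [logit(0.05), logit(0.95)] widened by 20%; log-volatility and
    log-noise span [-6, 1]; 5x5 log-spaced candidates in [1e-3, 1].
    """

    n_mu: int = 40
    n_logvmu: int = 40
    n_logsd: int = 40
    mu_bounds: tuple[float, float] = (-_MU_BOUND, _MU_BOUND)
    logvmu_bounds: tuple[float, float] = (-6.0, 1.0)
    logsd_bounds: tuple[float, float] = (-6.0, 1.0)
    kmu_candidates: tuple[float, ...] = field(
        default_factory=lambda: tuple(_default_candidates())
    )
    vsd_candidates: tuple[float, ...] = field(
        default_factory=lambda: tuple(_default_candidates())
    )

    def __post_init__(self) -> None:
        for n in (self.n_mu, self.n_logvmu, self.n_logsd):
            if n < 8:
                raise ValueError("grid sizes must be >= 8")
        for lo, hi in (self.mu_bounds, self.logvmu_bounds, self.logsd_bounds):
            if not (math.isfinite(lo) and math.isfinite(hi) and hi > lo):
                raise ValueError("grid bounds must be finite and ordered")
        if len(self.kmu_candidates) == 0 or len(self.vsd_candidates) == 0:
            raise ValueError("candidate sets must be non-empty")
        if min(self.kmu_candidates) <= 0 or min(self.vsd_candidates) <= 0:
            raise ValueError("candidates must be positive")


def _grid(lo: float, hi: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    centers = np.linspace(lo, hi, n)
    inner = 0.5 * (centers[1:] + centers[:-1])
    edges = np.concatenate(([-np.inf], inner, [np.inf]))
    return centers, edges


def _transition(centers: np.ndarray, edges: np.ndarray, sigma: float) -> np.ndarray:
    """Column-stochastic kernel T[new, old] of a Normal(0, sigma) step,
    integrated over destination cells (outer cells stretch to infinity)."""
    n = len(centers)
    if sigma < 1e-12:
        return np.eye(n)
    z = (edges[:, None] - centers[None, :]) / sigma
    cdf = np.where(np.isneginf(z), 0.0, np.where(np.isposinf(z), 1.0, ndtr(z)))
    return cdf[1:, :] - cdf[:-1, :]


def _escape(centers: np.ndarray, sigma: float) -> np.ndarray:
    """Per-source-cell probability of stepping beyond the nominal bounds."""
    if sigma < 1e-12:
        return np.zeros(len(centers))
    half = 0.5 * (centers[1] - centers[0])
    lo, hi = centers[0] - half, centers[-1] + half
    return ndtr((lo - centers) / sigma) + 1.0 - ndtr((hi - centers) / sigma)


class FilterModel:
    """Precomputed grids and transition kernels for a :class:`FilterConfig`."""

    def __init__(self, config: FilterConfig):
        self.config = config
        self.mu, mu_edges = _grid(*config.mu_bounds, config.n_mu)
        half = 0.5 * (self.mu[1] - self.mu[0])
        # finite-width cell edges for the likelihood integral (the infinite
        # outer edges are only for mass-conserving transition kernels)
        self.mu_like_edges = np.concatenate(
            ([self.mu[0] - half], mu_edges[1:-1], [self.mu[-1] + half])
        )
        self.logvmu, j_edges = _grid(*config.logvmu_bounds, config.n_logvmu)
        self.logsd, s_edges = _grid(*config.logsd_bounds, config.n_logsd)
        self.kmu = np.asarray(config.kmu_candidates, dtype=float)
        self.vsd = np.asarray(config.vsd_candidates, dtype=float)
        # log-volatility kernel per kmu candidate; log-noise per vSD candidate
        self.t_logvmu = np.stack(
            [_transition(self.logvmu, j_edges, k) for k in self.kmu]
        )
        self.t_logsd = np.stack(
            [_transition(self.logsd, s_edges, v) for v in self.vsd]
        )
        # mu kernel conditional on the (new) log-volatility cell
        self.t_mu = np.stack(
            [_transition(self.mu, mu_edges, math.exp(j)) for j in self.logvmu]
        )
        self.esc_mu = np.stack([_escape(self.mu, math.exp(j)) for j in self.logvmu])
        self.esc_logvmu = np.stack([_escape(self.logvmu, k) for k in self.kmu])
        self.esc_logsd = np.stack([_escape(self.logsd, v) for v in self.vsd])


@dataclass
class PosteriorState:
    """Joint posterior mass over (kmu cand, vSD cand, mu, logvmu, logSD)."""

    mass: np.ndarray  # shape (Ck, Cv, M, J, S)
    model: FilterModel
    diagnostics: list = field(default_factory=list)

    @classmethod
    def uniform(cls, model: FilterModel) -> "PosteriorState":
        shape = (
            len(model.kmu),
            len(model.vsd),
            len(model.mu),
            len(model.logvmu),
            len(model.logsd),
        )
        return cls(mass=np.full(shape, 1.0 / np.prod(shape)), model=model)

    @property
    def total(self) -> float:
        return float(self.mass.sum())

    def marginal(self, axis_name: str) -> np.ndarray:
        ax = {"mu": 2, "logvmu": 3, "logsd": 4}[axis_name]
        keep = [a for a in range(5) if a != ax]
        return self.mass.sum(axis=tuple(keep))

    def _moments(self, axis_name: str, grid: np.ndarray) -> tuple[float, float]:
        p = self.marginal(axis_name)
        m1 = float(p @ grid)
        var = float(p @ (grid - m1) ** 2)
        return m1, math.sqrt(max(var, 0.0))

    def expectations(self) -> dict[str, float]:
        m = self.model
        e_mu, s_mu = self._moments("mu", m.mu)
        e_j, s_j = self._moments("logvmu", m.logvmu)
        e_s, s_s = self._moments("logsd", m.logsd)
        return {
            "mu": e_mu,
            "logvmu": e_j,
            "logsd": e_s,
            "spread_mu": s_mu,
            "spread_logvmu": s_j,
            "spread_logsd": s_s,
        }


# ---------------------------------------------------------------------------
# filter steps
# ---------------------------------------------------------------------------

def predict_step(state: PosteriorState, t: int | None = None) -> PosteriorState:
    """Diffuse the posterior one step through the transition kernels.

    Log-volatility diffuses with its kmu candidate, log-noise with its
    vSD candidate, then mu diffuses with step SD ``exp(logvmu)`` of the
    *new* log-volatility cell, matching the generative ordering.  Mass is
    conserved exactly; an out-of-bounds share above 1% is recorded as a
    leakage diagnostic.
    """
    m = state.model
    p = state.mass  # (k, v, M, J, S)
    Ck, Cv, M, J, S = p.shape

    # leakage diagnostic: mass that would step past the nominal grid bounds
    pj = p.sum(axis=(1, 2, 4))  # (k, J)
    ps = p.sum(axis=(0, 2, 3))  # (v, S)
    leak = float((pj * m.esc_logvmu).sum() + (ps * m.esc_logsd).sum())

    # log-noise diffusion: batched over vSD candidates
    q = np.ascontiguousarray(p.transpose(1, 0, 2, 3, 4).reshape(Cv, Ck * M * J, S))
    q = np.matmul(q, m.t_logsd.transpose(0, 2, 1))  # sum over old S
    p = q.reshape(Cv, Ck, M, J, S).transpose(1, 0, 2, 3, 4)

    # log-volatility diffusion: batched over kmu candidates
    q = np.ascontiguousarray(p.transpose(0, 1, 2, 4, 3).reshape(Ck, Cv * M * S, J))
    q = np.matmul(q.reshape(Ck, -1, J), m.t_logvmu.transpose(0, 2, 1))
    p = q.reshape(Ck, Cv, M, S, J).transpose(0, 1, 2, 4, 3)

    # mu diffusion conditional on the new log-volatility cell
    leak += float((p.sum(axis=(0, 1, 4)) * m.esc_mu.T).sum())
    q = np.ascontiguousarray(p.transpose(3, 0, 1, 4, 2).reshape(J, Ck * Cv * S, M))
    q = np.matmul(q, m.t_mu.transpose(0, 2, 1))
    p = q.reshape(J, Ck, Cv, S, M).transpose(1, 2, 4, 0, 3)

    p = p / p.sum()
    diags = list(state.diagnostics)
    if leak > 0.01:
        diags.append({"time": t, "kind": "leakage", "fraction": leak})
    return PosteriorState(mass=np.ascontiguousarray(p), model=m, diagnostics=diags)


def update_step(state: PosteriorState, y: float, t: int | None = None) -> PosteriorState:
    """Reweight the posterior by the Gaussian likelihood of observation y.

    The likelihood is integrated over each mu cell (CDF difference across
    the cell edges) rather than point-evaluated at the center: with
    point evaluation, small-noise cells produce grid-alignment aliasing
    (a sharp density spike hits or misses a cell center by luck), which
    the cell integral removes.
    """
    if not math.isfinite(y):
        raise ValueError("observation must be finite")
    m = state.model
    sd = np.exp(m.logsd)  # (S,)
    z = (m.mu_like_edges[:, None] - y) / sd[None, :]  # (M+1, S)
    lik = ndtr(z[1:, :]) - ndtr(z[:-1, :])  # (M, S): mass of N(y, sd) per mu cell
    p = state.mass * lik[None, None, :, None, :]
    tot = p.sum()
    if not np.isfinite(tot) or tot <= 1e-300:
        raise LikelihoodUnderflowError(-1 if t is None else t)
    return PosteriorState(mass=p / tot, model=m, diagnostics=list(state.diagnostics))


# ---------------------------------------------------------------------------
# whole-series filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterEstimates:
    """Per-time-point marginalized-posterior expectations and spreads.

    ``mu`` is in the transformed (estimation) space; ``log_vmu`` and
    ``log_sd`` in log space.  Use :meth:`mu_raw` for a convenience
    back-transform to the original units.
    """

    mu: np.ndarray
    log_vmu: np.ndarray
    log_sd: np.ndarray
    spread_mu: np.ndarray
    spread_logvmu: np.ndarray
    spread_logsd: np.ndarray
    missing: np.ndarray
    spec: TransformSpec
    diagnostics: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.mu)

    def mu_raw(self) -> np.ndarray:
        return inverse_bounded_logit(self.mu, self.spec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mu_hat": self.mu,
                "logvmu_hat": self.log_vmu,
                "logsd_hat": self.log_sd,
                "spread_mu": self.spread_mu,
                "spread_logvmu": self.spread_logvmu,
                "spread_logsd": self.spread_logsd,
                "missing": self.missing.astype(int),
            }
        )


def run_filter(
    series,
    spec: TransformSpec,
    config: FilterConfig | None = None,
    model: FilterModel | None = None,
) -> FilterEstimates:
    """Filter one raw bounded series (NaN marks missing days).

    Time point 0 applies the uniform prior (plus an update when observed);
    every later point applies predict, then update if observed.  Estimates
    are recorded at every point, observed or not, so gaps carry estimates
    with systematically increased spread.
    """
    raw = np.asarray(series, dtype=float)
    if raw.ndim != 1 or len(raw) < 2:
        raise ValueError("series must be 1-D with length >= 2")
    obs_mask = ~np.isnan(raw)
    if obs_mask.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    z = bounded_logit_transform(raw, spec)
    if model is None:
        model = FilterModel(config or FilterConfig())
    state = PosteriorState.uniform(model)

    n = len(raw)
    out = {k: np.empty(n) for k in ("mu", "logvmu", "logsd", "spread_mu", "spread_logvmu", "spread_logsd")}
    for t in range(n):
        if t > 0:
            state = predict_step(state, t=t)
        if obs_mask[t]:
            state = update_step(state, float(z[t]), t=t)
        e = state.expectations()
        for k in out:
            out[k][t] = e[k]
    return FilterEstimates(
        mu=out["mu"],
        log_vmu=out["logvmu"],
        log_sd=out["logsd"],
        spread_mu=out["spread_mu"],
        spread_logvmu=out["spread_logvmu"],
        spread_logsd=out["spread_logsd"],
        missing=~obs_mask,
        spec=spec,
        diagnostics=state.diagnostics,
    )


def fit_series_bundle(
    dataset,
    config: FilterConfig | None = None,
    day_range: tuple[int, int] = (-14, 28),
    fixed_bounds: dict[str, tuple[float, float]] | None = None,
    measures: tuple[str, ...] | None = None,
) -> dict[tuple[int, str], FilterEstimates | None]:
    """Filter all six daily tracks of every participant in a trial.

    Tracks: pa, na, m10, l5, m10_onset, l5_onset, each filtered on the
    grid of days ``day_range[0]..day_range[1]`` with its own per-series
    transform bounds (observed min/max, or ``fixed_bounds[measure]`` when
    given).  A track with fewer than 2 observations, or a degenerate
    constant range, is recorded as ``None`` (unavailable).
    """
    from .synthetic import MEASURES

    if measures is None:
        measures = MEASURES
    model = FilterModel(config or FilterConfig())
    first, last = day_range
    days_idx = np.arange(first, last + 1)
    results: dict[tuple[int, str], FilterEstimates | None] = {}
    days = dataset.days
    for pid, sub in days.groupby("id", sort=True):
        sub = sub.set_index("day")
        for meas in measures:
            vals = np.full(len(days_idx), np.nan)
            for i, d in enumerate(days_idx):
                if d in sub.index and bool(sub.loc[d, "valid"]):
                    vals[i] = float(sub.loc[d, meas])
            obs = vals[~np.isnan(vals)]
            if len(obs) < 2:
                results[(int(pid), meas)] = None
                continue
            if fixed_bounds and meas in fixed_bounds:
                lo, hi = fixed_bounds[meas]
            else:
                lo, hi = float(obs.min()), float(obs.max())
            if not hi > lo:
                results[(int(pid), meas)] = None
                continue
            spec = TransformSpec(min=lo, max=hi)
            results[(int(pid), meas)] = run_filter(vals, spec, model=model)
    return results
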