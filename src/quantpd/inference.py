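"""Bayesian model selection and parameter estimation for PKPD time courses.

Three nested models compete for each curve:

``nosignal``   constant mean,
``baseline``   quadratic drift  a0 + a1*t + a2*t**2,
``full``       drift plus the sigmoid drug effect  e_max * E_unit(t; q, ts),

where ``E_unit(t) = C(t)**n / (ec50**n + C(t)**n)`` is the unit-amplitude
effect shape, so the model is linear in (a0, a1, a2, e_max) for fixed
nonlinear parameters (q = log10 EC50, ts, and optionally t_half).

The linear coefficients and the noise SD are integrated out analytically:
the intercept carries a flat (improper) prior — it appears in every model
and cancels from all model comparisons — the remaining (centered) linear
coefficients carry a Zellner g-prior N(0, g*sigma^2*(Xc'Xc)^-1), and sigma
a Jeffreys prior.  The resulting marginal likelihood, for a model with k
non-intercept columns,

    log m(y | q, ts) = const - (1/2) log N - (k/2) log(1+g)
                       - ((N-1)/2) log( RSS + ESS/(1+g) )

depends on the design only through its column span (basis invariant) and
is invariant under rescaling of the data, so model probabilities are too.
g sets the Occam factor sqrt(1+g) per extra linear dimension; the default
g = 1e8 admits signal components up to ~1e4 times the noise SD.

Two engines integrate the remaining 2-3 nonlinear dimensions over their
uniform prior box: a deterministic trapezoid quadrature (exact, fast, used
for simulation studies) and an annealed ensemble MCMC sampler with stepping-stone
evidence estimates (useful when extra nonlinear parameters make
quadrature awkward, and as a cross-check on the quadrature engine).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .model import DoseSchedule, KineticParams, TimeCourse, plasma_concentration

__all__ = [
    "MODELS",
    "PriorSpec",
    "McmcSettings",
    "ModelSelectionResult",
    "design_matrix",
    "log_marginal_given_nonlinear",
    "quadrature_evidence",
    "QuadratureFitter",
    "anneal_mcmc",
    "model_probabilities",
]

MODELS: tuple[str, ...] = ("full", "baseline", "nosignal")

MIN_POINTS = 8  # fewer points cannot support the 4-column full model robustly


@dataclass(frozen=True)
class PriorSpec:
    """Prior specification for the nonlinear and nuisance parameters.

    ``t_half`` may be a fixed value (simulation default 41 min) or a
    ``(lo, hi)`` uniform range (in-vivo default (2, 60) min).  ``g`` is the
    Zellner g-prior scale on the non-intercept linear coefficients.
    """

    q_range: tuple[float, float] = (-3.0, 1.3)
    ts_range: tuple[float, float] = (0.0, 1.0)
    t_half: float | tuple[float, float] = 41.0
    hill: float = 1.0
    g: float = 1e8

    def __post_init__(self) -> None:
        if not self.q_range[1] > self.q_range[0]:
            raise ValueError("q_range must be non-degenerate")
        if not all(map(math.isfinite, self.q_range)):
            raise ValueError("q_range must be finite")
        if not self.ts_range[1] >= self.ts_range[0]:
            raise ValueError("ts_range must be ordered")
        if self.t_half_free:
            lo, hi = self.t_half  # type: ignore[misc]
            if not (0 < lo < hi):
                raise ValueError("t_half range must be positive and increasing")
        elif not (float(self.t_half) > 0):  # type: ignore[arg-type]
            raise ValueError("t_half must be positive")
        if not self.g > 0:
            raise ValueError("g must be positive")

    @property
    def t_half_free(self) -> bool:
        return isinstance(self.t_half, (tuple, list))

    @property
    def ndim(self) -> int:
        """Number of nonlinear dimensions of the full model."""
        return 3 if self.t_half_free else 2


@dataclass(frozen=True)
class McmcSettings:
    """Annealed-MCMC settings.

    Defaults: a 50-walker ensemble run for 100 sweeps at each of 30
    geometrically spaced inverse temperatures, discarding the first half of
    each rung as equilibration, so 50 x 50 = 2500 retained samples per
    annealing step.
    """

    walkers: int = 50
    repeats: int = 100
    ladder: tuple[float, ...] | None = None  # inverse temperatures, ending at 1
    burn_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.walkers < 4 or self.repeats < 2:
            raise ValueError("need at least 4 walkers and 2 repeats")
        lad = self.resolve_ladder()
        if lad[-1] != 1.0 or np.any(np.diff(lad) <= 0) or lad[0] <= 0:
            raise ValueError("ladder must be increasing in (0, 1] and end at 1")

    def resolve_ladder(self) -> NDArray[np.float64]:
        if self.ladder is None:
            return np.geomspace(1e-4, 1.0, 30)
        return np.asarray(self.ladder, dtype=float)

    @property
    def retained_samples(self) -> int:
        """Post-burn samples per annealing rung."""
        return self.walkers * (self.repeats - int(self.burn_frac * self.repeats))


@dataclass
class ModelSelectionResult:
    """Posterior model probabilities plus parameter estimates for one curve."""

    log_evidence: dict[str, float]
    probabilities: dict[str, float]
    preferred: str
    residual_sd: float
    estimates: dict[str, dict[str, float]] | None
    engine: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def prob_full(self) -> float:
        return self.probabilities["full"]

    @property
    def prob_baseline(self) -> float:
        return self.probabilities["baseline"]

    @property
    def prob_nosignal(self) -> float:
        return self.probabilities["nosignal"]


# ---------------------------------------------------------------------------
# design matrices and the analytic linear/sigma marginal
# ---------------------------------------------------------------------------


def unit_effect(
    times: NDArray[np.float64],
    schedule: DoseSchedule,
    q: float,
    ts: float,
    t_half: float,
    hill: float = 1.0,
) -> NDArray[np.float64]:
    """Unit-amplitude effect shape C^n/(ec50^n + C^n) on a time grid."""
    kin = KineticParams(t_half=t_half, t_shift=ts, hill=hill)
    c = np.asarray(plasma_concentration(times, schedule, kin))
    cn = c**hill
    return cn / (10.0 ** (hill * q) + cn)


def design_matrix(
    curve: TimeCourse,
    nonlinear: dict[str, float],
    model: str,
    schedule: DoseSchedule | None = None,
    hill: float = 1.0,
) -> NDArray[np.float64]:
    """Basis columns of a model, linear in the marginalized coefficients.

    nosignal: [1]; baseline: [1, t, t^2]; full: [1, t, t^2, E_unit] where
    the last column is the unit-amplitude effect shape, so the e_max
    coefficient is unconstrained in sign.
    """
    t = curve.times
    if model == "nosignal":
        return np.ones((t.size, 1))
    if model == "baseline":
        return np.column_stack([np.ones_like(t), t, t**2])
    if model == "full":
        if schedule is None:
            raise ValueError("full model requires a dose schedule")
        u = unit_effect(
            t, schedule, nonlinear["q"], nonlinear["ts"], nonlinear["t_half"], hill
        )
        return np.column_stack([np.ones_like(t), t, t**2, u])
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


def _log_marginal_core(
    y: NDArray[np.float64], X: NDArray[np.float64], g: float
) -> float:
    """Closed-form log marginal for y = X @ beta + noise, first column = 1.

    Flat prior on the intercept, Zellner g-prior on the centered remaining
    columns, Jeffreys prior on the noise SD.
    """
    n, m = X.shape
    if n < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points to fit, got {n}")
    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss <= 0:
        raise ValueError("degenerate curve: zero variance")
    k = m - 1
    if k > 0:
        xc = X[:, 1:] - X[:, 1:].mean(axis=0)
        qmat, rmat = np.linalg.qr(xc)
        if np.any(np.abs(np.diag(rmat)) < 1e-10 * max(1.0, np.abs(rmat).max())):
            raise ValueError("rank-deficient design matrix (degenerate grid)")
        coef = qmat.T @ yc
        ess = float(coef @ coef)
    else:
        ess = 0.0
    rss = max(tss - ess, 0.0)
    s = rss + ess / (1.0 + g)
    half = (n - 1) / 2.0
    return float(
        gammaln(half)
        + half * (math.log(2.0) - math.log(2.0 * math.pi))
        - math.log(2.0)
        - 0.5 * math.log(n)
        - 0.5 * k * math.log1p(g)
        - half * math.log(s)
    )


def log_marginal_given_nonlinear(
    curve: TimeCourse,
    nonlinear: dict[str, float],
    model: str,
    schedule: DoseSchedule | None = None,
    prior: PriorSpec | None = None,
) -> float:
    """Log marginal likelihood with linear coefficients and sigma integrated out."""
    prior = prior or PriorSpec()
    X = design_matrix(curve, nonlinear, model, schedule, prior.hill)
    return _log_marginal_core(np.asarray(curve.values, float), X, prior.g)


# ---------------------------------------------------------------------------
# quadrature engine
# ---------------------------------------------------------------------------


def _trapezoid_logweights(grid: NDArray[np.float64]) -> NDArray[np.float64]:
    """Log of trapezoid weights normalized to average over the interval."""
    if grid.size == 1:
        return np.zeros(1)
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return np.log(w / (grid[-1] - grid[0]))


def _ts_quadrature(
    ts_range: tuple[float, float],
    boundaries: NDArray[np.float64],
    dts: float,
    max_cuts: int = 64,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Time-shift quadrature nodes and log weights, split at discontinuities.

    The unit effect column jumps whenever a dose onset (t_k + ts) crosses a
    sample time, so the marginal likelihood is only piecewise smooth in ts;
    composite trapezoid rules within each smooth bin (ts in (b_j, b_{j+1}])
    restore second-order accuracy.  Left bin edges are evaluated just
    inside the bin.
    """
    lo, hi = float(ts_range[0]), float(ts_range[1])
    if hi == lo:
        return np.array([lo]), np.zeros(1)
    inner = np.unique(boundaries[(boundaries > lo) & (boundaries < hi)])
    cuts = [lo, *inner.tolist(), hi] if inner.size <= max_cuts else [lo, hi]
    nodes, logw = [], []
    total = hi - lo
    for a, b in zip(cuts, cuts[1:]):
        n = max(int(math.ceil((b - a) / dts)) + 1, 2)
        g = np.linspace(a, b, n)
        h = g[1] - g[0]
        w = np.full(n, h)
        w[0] = w[-1] = h / 2
        g[0] = a + 1e-9  # the bin is open on the left
        nodes.append(g)
        logw.append(np.log(w / total))
    return np.concatenate(nodes), np.concatenate(logw)


class QuadratureFitter:
    """Batch model-selection engine for curves sharing one sampling grid.

    Precomputes, for every node of a tensor grid over the nonlinear prior
    box, an orthonormal basis extension of the drift columns by the unit
    effect shape; fitting a curve then costs a handful of matrix-vector
    products.  Deterministic by construction.
    """

    def __init__(
        self,
        times: NDArray[np.float64],
        schedule: DoseSchedule,
        prior: PriorSpec | None = None,
        dq: float = 0.025,
        dts: float = 0.05,
        n_thalf: int = 25,
        threshold: float = 0.5,
    ) -> None:
        self.prior = prior or PriorSpec()
        self.schedule = schedule
        self.threshold = float(threshold)
        self.times = t = np.asarray(times, dtype=float)
        n = t.size
        if n < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} time points, got {n}")
        p = self.prior
        self.q_grid = _span_grid(p.q_range, dq)
        # smoothness boundaries in ts: dose onsets crossing sample times
        bounds = np.unique((t[:, None] - np.asarray(schedule.dose_times)).ravel())
        self.ts_grid, ts_logw = _ts_quadrature(p.ts_range, bounds, dts)
        if p.t_half_free:
            self.th_grid = np.linspace(p.t_half[0], p.t_half[1], n_thalf)  # type: ignore[index]
        else:
            self.th_grid = np.array([float(p.t_half)])  # type: ignore[arg-type]

        # orthonormal basis of the centered drift columns, shared by all nodes
        xc = np.column_stack([t, t**2])
        xc -= xc.mean(axis=0)
        self.q_base, r_base = np.linalg.qr(xc)
        if np.any(np.abs(np.diag(r_base)) < 1e-12):
            raise ValueError("degenerate time grid: drift columns are rank-deficient")

        qq, tt, hh = np.meshgrid(self.q_grid, self.ts_grid, self.th_grid, indexing="ij")
        self.nodes = np.column_stack([qq.ravel(), tt.ravel(), hh.ravel()])
        lw_q = _trapezoid_logweights(self.q_grid)
        lw_ts = ts_logw
        lw_th = _trapezoid_logweights(self.th_grid)
        self.log_w = (
            lw_q[:, None, None] + lw_ts[None, :, None] + lw_th[None, None, :]
        ).ravel()

        # third orthonormal direction (the part of E_unit outside the drift
        # span) per node; nodes where E_unit is collinear get a zero vector
        u = _unit_effect_batch(t, schedule, self.nodes, p.hill)
        uc = u - u.mean(axis=1, keepdims=True)
        uc -= (uc @ self.q_base) @ self.q_base.T
        nrm = np.linalg.norm(uc, axis=1)
        ok = nrm > 1e-9
        uc[ok] /= nrm[ok, None]
        uc[~ok] = 0.0
        self.u_basis = uc  # (n_nodes, n_times)

        half = (n - 1) / 2.0
        self._const = (
            gammaln(half)
            + half * (math.log(2.0) - math.log(2.0 * math.pi))
            - math.log(2.0)
            - 0.5 * math.log(n)
        )
        self._half = half
        self._n = n

    # -- per-curve computations -------------------------------------------

    def _node_log_marginals(
        self, yc: NDArray[np.float64], tss: float, ess_drift: float
    ) -> NDArray[np.float64]:
        g = self.prior.g
        cu = self.u_basis @ yc
        ess = ess_drift + cu**2
        s = np.maximum(tss - ess, 0.0) + ess / (1.0 + g)
        return self._const - 1.5 * math.log1p(g) - self._half * np.log(s)

    def log_evidences(self, values: NDArray[np.float64]) -> dict[str, float]:
        """Log evidence of the three models for one curve's values."""
        y = np.asarray(values, dtype=float)
        if y.shape != self.times.shape:
            raise ValueError("curve length does not match the fitter's time grid")
        yc = y - y.mean()
        tss = float(yc @ yc)
        if tss <= 0:
            raise ValueError("degenerate curve: zero variance")
        g = self.prior.g
        cb = self.q_base.T @ yc
        ess_b = float(cb @ cb)
        s_base = max(tss - ess_b, 0.0) + ess_b / (1.0 + g)
        lz_nosig = self._const - self._half * math.log(tss)
        lz_base = self._const - math.log1p(g) - self._half * math.log(s_base)
        lm = self._node_log_marginals(yc, tss, ess_b)
        lz_full = float(logsumexp(lm + self.log_w))
        self._last_node_lm = lm  # cached for estimates/posterior means
        return {"full": lz_full, "baseline": lz_base, "nosignal": lz_nosig}

    def _ml_nonlinear(self, y: NDArray[np.float64]) -> tuple[NDArray[np.float64], float]:
        """Grid argmax of the full-model marginal, polished by Nelder-Mead."""
        lm = self._last_node_lm
        i0 = int(np.argmax(lm))
        x0 = self.nodes[i0]
        p = self.prior
        tc = TimeCourse(times=self.times, values=y)
        free_ts = p.ts_range[1] > p.ts_range[0]

        def neg(x: NDArray[np.float64]) -> float:
            nl = {"q": x[0], "ts": x[1] if free_ts else p.ts_range[0], "t_half": x[2]}
            return -log_marginal_given_nonlinear(tc, nl, "full", self.schedule, p)

        bounds = [p.q_range, p.ts_range if free_ts else (x0[1], x0[1])]
        bounds.append(tuple(p.t_half) if p.t_half_free else (x0[2], x0[2]))  # type: ignore[arg-type]
        res = minimize(neg, x0, method="Nelder-Mead", bounds=bounds,
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
        x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        return x, -float(res.fun)

    def fit(self, curve: TimeCourse | NDArray[np.float64]) -> ModelSelectionResult:
        """Full model selection + estimation for one curve."""
        values = curve.values if isinstance(curve, TimeCourse) else np.asarray(curve, float)
        lz = self.log_evidences(values)
        probs = _normalize_evidence(lz)
        preferred = max(probs, key=probs.get)  # type: ignore[arg-type]
        estimates = None
        diagnostics: dict = {"n_nodes": self.nodes.shape[0]}
        if probs["full"] > self.threshold:
            x_ml, lm_ml = self._ml_nonlinear(values)
            w = self._posterior_node_weights()
            nodes = self.nodes
            mean_q = float(w @ nodes[:, 0])
            mean_ts = float(w @ nodes[:, 1])
            mean_th = float(w @ nodes[:, 2])
            mean_ec50 = float(w @ 10.0 ** nodes[:, 0])
            beta, resid_sd = self._linear_fit(values, x_ml)
            estimates = {
                "q": {"ml": float(x_ml[0]), "mean": mean_q},
                "ec50": {"ml": 10.0 ** float(x_ml[0]), "mean": mean_ec50},
                "ts": {"ml": float(x_ml[1]), "mean": mean_ts},
                "t_half": {"ml": float(x_ml[2]), "mean": mean_th},
                "a0": {"ml": beta[0], "mean": beta[0]},
                "a1": {"ml": beta[1], "mean": beta[1]},
                "a2": {"ml": beta[2], "mean": beta[2]},
                "e_max": {"ml": beta[3], "mean": beta[3]},
            }
            diagnostics["log_marginal_ml"] = lm_ml
            residual_sd = resid_sd
        else:
            simple = preferred if preferred != "full" else "baseline"
            residual_sd = self._residual_sd_simple(values, simple)
        return ModelSelectionResult(
            log_evidence=lz,
            probabilities=probs,
            preferred=preferred,
            residual_sd=residual_sd,
            estimates=estimates,
            engine="quadrature",
            diagnostics=diagnostics,
        )

    def _posterior_node_weights(self) -> NDArray[np.float64]:
        lw = self._last_node_lm + self.log_w
        w = np.exp(lw - lw.max())
        return w / w.sum()

    def _linear_fit(
        self, y: NDArray[np.float64], x_nl: NDArray[np.float64]
    ) -> tuple[list[float], float]:
        """OLS coefficients (a0, a1, a2, e_max) at the ML nonlinear point."""
        tc = TimeCourse(times=self.times, values=y)
        nl = {"q": x_nl[0], "ts": x_nl[1], "t_half": x_nl[2]}
        X = design_matrix(tc, nl, "full", self.schedule, self.prior.hill)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = float(np.sqrt(resid @ resid / (y.size - X.shape[1])))
        return [float(b) for b in beta], sd

    def _residual_sd_simple(self, y: NDArray[np.float64], model: str) -> float:
        tc = TimeCourse(times=self.times, values=y)
        X = design_matrix(tc, {}, model)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(np.sqrt(resid @ resid / max(y.size - X.shape[1], 1)))


def _span_grid(rng: tuple[float, float], step: float) -> NDArray[np.float64]:
    lo, hi = float(rng[0]), float(rng[1])
    if hi == lo:
        return np.array([lo])
    n = max(int(round((hi - lo) / step)) + 1, 2)
    return np.linspace(lo, hi, n)


def _unit_effect_batch(
    times: NDArray[np.float64],
    schedule: DoseSchedule,
    nodes: NDArray[np.float64],
    hill: float,
) -> NDArray[np.float64]:
    """Unit effect shapes for an array of (q, ts, t_half) nodes; (n_nodes, n_t)."""
    out = np.empty((nodes.shape[0], times.size))
    # concentration depends only on (ts, t_half): compute once per unique pair
    key = nodes[:, 1:]
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    dt = np.asarray(schedule.dose_times)
    peaks = np.asarray(schedule.dose_peaks)
    conc_u = np.empty((uniq.shape[0], times.size))
    for i, (ts, th) in enumerate(uniq):
        lag = times[:, None] - ts - dt
        decay = np.where(lag >= 0, np.exp2(-np.abs(lag) / th), 0.0)
        conc_u[i] = decay @ peaks
    cn = conc_u[inv] ** hill
    out = cn / (10.0 ** (hill * nodes[:, [0]]) + cn)
    return out


def _normalize_evidence(lz: dict[str, float]) -> dict[str, float]:
    """Equal model priors: probabilities proportional to evidence."""
    names = list(lz)
    vals = np.array([lz[m] for m in names])
    p = np.exp(vals - logsumexp(vals))
    p /= p.sum()
    return {m: float(pi) for m, pi in zip(names, p)}


def quadrature_evidence(
    curve: TimeCourse,
    model: str,
    prior: PriorSpec | None = None,
    schedule: DoseSchedule | None = None,
    tol: float = 0.01,
    max_levels: int = 4,
) -> float:
    """Log evidence by trapezoid quadrature over the nonlinear prior box.

    Grid density is doubled until successive estimates differ by < ``tol``
    (models without nonlinear parameters are exact in closed form).  On
    non-convergence the best estimate is returned with a warning.
    """
    prior = prior or PriorSpec()
    if model in ("baseline", "nosignal"):
        return log_marginal_given_nonlinear(curve, {}, model, schedule, prior)
    if model != "full":
        raise ValueError(f"unknown model {model!r}")
    if schedule is None:
        raise ValueError("full model requires a dose schedule")
    dq, dts, nth = 0.1, 0.2, 7
    prev = None
    for _ in range(max_levels):
        fitter = QuadratureFitter(curve.times, schedule, prior, dq=dq, dts=dts, n_thalf=nth)
        lz = fitter.log_evidences(curve.values)["full"]
        if prev is not None and abs(lz - prev) < tol:
            return lz
        prev = lz
        dq /= 2
        dts /= 2
        nth = 2 * nth - 1
    import warnings

    warnings.warn("quadrature_evidence did not converge to tol; returning best estimate")
    return prev  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# annealed MCMC engine
# ---------------------------------------------------------------------------


class _MarginalField:
    """Vectorized full-model log marginal over (q, ts[, t_half]) for one curve."""

    def __init__(
        self,
        curve: TimeCourse,
        schedule: DoseSchedule,
        prior: PriorSpec,
    ) -> None:
        self.prior = prior
        self.schedule = schedule
        self.times = curve.times
        t = self.times
        n = t.size
        if n < MIN_POINTS:
            raise ValueError(f"need at least {MIN_POINTS} points, got {n}")
        xc = np.column_stack([t, t**2])
        xc -= xc.mean(axis=0)
        self.q_base, _ = np.linalg.qr(xc)
        y = np.asarray(curve.values, float)
        self.yc = y - y.mean()
        self.tss = float(self.yc @ self.yc)
        cb = self.q_base.T @ self.yc
        self.ess_drift = float(cb @ cb)
        half = (n - 1) / 2.0
        self._half = half
        self._const = (
            gammaln(half)
            + half * (math.log(2.0) - math.log(2.0 * math.pi))
            - math.log(2.0)
            - 0.5 * math.log(n)
            - 1.5 * math.log1p(prior.g)
        )
        lo = [prior.q_range[0], prior.ts_range[0]]
        hi = [prior.q_range[1], prior.ts_range[1]]
        if prior.t_half_free:
            lo.append(prior.t_half[0])  # type: ignore[index]
            hi.append(prior.t_half[1])  # type: ignore[index]
        self.lo = np.array(lo)
        self.hi = np.array(hi)

    def __call__(self, x: NDArray[np.float64]) -> NDArray[np.float64]:
        """Log marginal at points x of shape (batch, ndim); -inf outside the box."""
        x = np.atleast_2d(x)
        inside = np.all((x >= self.lo) & (x <= self.hi), axis=1)
        out = np.full(x.shape[0], -np.inf)
        if not inside.any():
            return out
        xi = x[inside]
        p = self.prior
        th = xi[:, 2] if p.t_half_free else np.full(xi.shape[0], float(p.t_half))  # type: ignore[arg-type]
        nodes = np.column_stack([xi[:, 0], xi[:, 1], th])
        u = _unit_effect_batch(self.times, self.schedule, nodes, p.hill)
        uc = u - u.mean(axis=1, keepdims=True)
        uc -= (uc @ self.q_base) @ self.q_base.T
        nrm = np.linalg.norm(uc, axis=1)
        ok = nrm > 1e-9
        cu = np.zeros(xi.shape[0])
        cu[ok] = (uc[ok] / nrm[ok, None]) @ self.yc
        ess = self.ess_drift + cu**2
        s = np.maximum(self.tss - ess, 0.0) + ess / (1.0 + p.g)
        out[inside] = self._const - self._half * np.log(s)
        return out


def anneal_mcmc(
    curve: TimeCourse,
    model: str,
    prior: PriorSpec | None = None,
    settings: McmcSettings | None = None,
    schedule: DoseSchedule | None = None,
) -> dict:
    """Annealed ensemble MCMC over the nonlinear parameters of one model.

    Runs an ensemble sampler (emcee stretch moves) up a ladder of inverse
    temperatures; the evidence is a stepping-stone estimate along the
    ladder.  Models without nonlinear parameters are
    returned exactly.  Deterministic given ``settings.seed``.

    Returns a dict with ``log_evidence``, posterior ``samples`` (final
    rung), ``log_marginals`` per sample, ``ml_sample`` (first occurrence of
    the maximum-likelihood sample over the whole run) and ``ml_log_marginal``.
    """
    import emcee

    prior = prior or PriorSpec()
    settings = settings or McmcSettings()
    if model in ("baseline", "nosignal"):
        lz = log_marginal_given_nonlinear(curve, {}, model, schedule, prior)
        return {"log_evidence": lz, "samples": None, "ml_sample": None,
                "ml_log_marginal": None, "log_marginals": None}
    if model != "full":
        raise ValueError(f"unknown model {model!r}")
    if schedule is None:
        raise ValueError("full model requires a dose schedule")

    field_fn = _MarginalField(curve, schedule, prior)
    ndim = prior.ndim
    ladder = settings.resolve_ladder()
    rs = np.random.RandomState(settings.seed % (2**32))
    lo, hi = field_fn.lo, field_fn.hi
    state = lo + (hi - lo) * rs.rand(settings.walkers, ndim)

    mean_lm = np.empty(ladder.size)
    rung_lm: list[NDArray[np.float64]] = []
    best_lm = -np.inf
    best_x: NDArray[np.float64] | None = None
    final_chain = None
    final_lm = None
    burn = int(settings.burn_frac * settings.repeats)
    for i, beta in enumerate(ladder):
        def log_prob(x: NDArray[np.float64], _b: float = float(beta)) -> NDArray[np.float64]:
            return _b * field_fn(x)

        sampler = emcee.EnsembleSampler(settings.walkers, ndim, log_prob, vectorize=True)
        sampler.random_state = rs.get_state()
        sampler.run_mcmc(state, settings.repeats, skip_initial_state_check=True)
        rs.set_state(sampler.random_state)
        chain = sampler.get_chain()  # (repeats, walkers, ndim)
        lm = sampler.get_log_prob() / beta
        state = chain[-1]
        mean_lm[i] = lm[burn:].mean()
        rung_lm.append(lm[burn:].reshape(-1))
        flat_lm = lm.reshape(-1)
        j = int(np.argmax(flat_lm))
        if flat_lm[j] > best_lm:
            best_lm = float(flat_lm[j])
            best_x = chain.reshape(-1, ndim)[j].copy()
        if i == ladder.size - 1:
            final_chain = chain[burn:].reshape(-1, ndim)
            final_lm = lm[burn:].reshape(-1)

    # stepping-stone evidence along the ladder: each segment's ratio
    # Z(b_{i+1})/Z(b_i) is estimated from the samples at inverse temperature
    # b_i; the [0, ladder[0]] stub uses the (near-prior) first-rung mean
    log_z = float(mean_lm[0] * ladder[0])
    for i in range(ladder.size - 1):
        d = ladder[i + 1] - ladder[i]
        log_z += float(logsumexp(d * rung_lm[i]) - math.log(rung_lm[i].size))
    return {
        "log_evidence": log_z,
        "samples": final_chain,
        "log_marginals": final_lm,
        "ml_sample": best_x,
        "ml_log_marginal": best_lm,
        "mean_log_marginal_per_rung": mean_lm,
        "ladder": ladder,
    }


# ---------------------------------------------------------------------------
# top-level model selection
# ---------------------------------------------------------------------------


def model_probabilities(
    curve: TimeCourse,
    schedule: DoseSchedule,
    prior: PriorSpec | None = None,
    engine: Literal["quadrature", "mcmc"] = "quadrature",
    settings: McmcSettings | None = None,
    threshold: float = 0.5,
    fitter: QuadratureFitter | None = None,
) -> ModelSelectionResult:
    """Posterior model probabilities (equal model priors) plus estimates.

    Parameter estimates are populated only when the full model's posterior
    probability exceeds ``threshold`` (default 0.5).  Both the
    maximum-likelihood-sample value and the posterior mean are reported for
    the nonlinear parameters; the linear coefficients (a0, a1, a2, e_max)
    are the least-squares solution at the maximum-likelihood nonlinear
    point.
    """
    prior = prior or PriorSpec()
    if engine == "quadrature":
        if fitter is None:
            fitter = QuadratureFitter(curve.times, schedule, prior, threshold=threshold)
        else:
            fitter.threshold = threshold
        return fitter.fit(curve)
    if engine != "mcmc":
        raise ValueError(f"unknown engine {engine!r}")

    settings = settings or McmcSettings()
    lz = {}
    full_run = anneal_mcmc(curve, "full", prior, settings, schedule)
    lz["full"] = full_run["log_evidence"]
    for m in ("baseline", "nosignal"):
        lz[m] = log_marginal_given_nonlinear(curve, {}, m, schedule, prior)
    probs = _normalize_evidence(lz)
    preferred = max(probs, key=probs.get)  # type: ignore[arg-type]
    estimates = None
    helper = QuadratureFitter(curve.times, schedule, prior, dq=1.0, dts=1.0, n_thalf=2)
    y = np.asarray(curve.values, float)
    if probs["full"] > threshold:
        x_ml = full_run["ml_sample"]
        samples = full_run["samples"]
        if prior.t_half_free:
            ml = np.array([x_ml[0], x_ml[1], x_ml[2]])
            mean_th = float(samples[:, 2].mean())
        else:
            ml = np.array([x_ml[0], x_ml[1], float(prior.t_half)])  # type: ignore[arg-type]
            mean_th = float(prior.t_half)  # type: ignore[arg-type]
        beta, resid_sd = helper._linear_fit(y, ml)
        estimates = {
            "q": {"ml": float(ml[0]), "mean": float(samples[:, 0].mean())},
            "ec50": {"ml": 10.0 ** float(ml[0]), "mean": float((10.0 ** samples[:, 0]).mean())},
            "ts": {"ml": float(ml[1]), "mean": float(samples[:, 1].mean())},
            "t_half": {"ml": float(ml[2]), "mean": mean_th},
            "a0": {"ml": beta[0], "mean": beta[0]},
            "a1": {"ml": beta[1], "mean": beta[1]},
            "a2": {"ml": beta[2], "mean": beta[2]},
            "e_max": {"ml": beta[3], "mean": beta[3]},
        }
        residual_sd = resid_sd
    else:
        simple = preferred if preferred != "full" else "baseline"
        residual_sd = helper._residual_sd_simple(y, simple)
    return ModelSelectionResult(
        log_evidence=lz,
        probabilities=probs,
        preferred=preferred,
        residual_sd=residual_sd,
        estimates=estimates,
        engine="mcmc",
        diagnostics={"ladder_size": settings.resolve_ladder().size},
    )
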