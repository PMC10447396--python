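"""Bayesian conditional Poisson inference for the case-crossover design.

The study model is a Poisson regression with one intercept per
case-crossover stratum (the event/non-event day grouping).  Conditioning on
each stratum's total count cancels the stratum intercepts and leaves the
multinomial likelihood

    sum over strata [ x_case' beta - log sum over stratum days exp(x_day' beta) ],

identical to the conditional-logistic likelihood when each stratum holds one
case.  This module fits that likelihood with weakly informative Normal
priors, by default via a deterministic Laplace (Gaussian) approximation at
the posterior mode; an MCMC backend (affine-invariant ensemble sampler) is
available as a cross-check.

A consequence of conditioning worth stating explicitly: any covariate that
is constant within every stratum — patient-level terms included — drops out
of the likelihood entirely.  The per-patient random effects used to absorb
recurrent admissions are constant within each admission's stratum, so they
decouple exactly: their posterior equals their prior and the exposure
coefficient is untouched.  ``fit_model`` detects stratum-constant columns
and reports them as decoupled rather than estimating them numerically.

The non-linear sensitivity analysis replaces the linear temperature term
with a discretized curve under a random-walk-of-order-2 (RW2) prior: a
Gaussian Markov random field penalizing second differences, whose null space
contains all linear curves, so it shrinks toward — and can reveal departures
from — linearity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from .design import DesignMatrix, build_design_matrix
from .exceptions import ConvergenceError, DataError, DesignError

Z975 = norm.ppf(0.975)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """What to fit and how.

    ``temperature`` selects a linear term or an RW2-discretized curve with
    ``n_bins`` equal-width bins.  ``prior_sd`` is the Normal prior SD on
    fixed effects (``None`` = flat, used for maximum-likelihood oracles).
    ``patient_effect`` adds per-patient terms (prior SD ~ half-Normal of
    scale ``patient_sd_scale``) for patients with at least
    ``patient_min_admissions`` admissions; see the module docstring for why
    these decouple.  ``rw2_sd_scale`` is the half-Normal scale of the RW2
    smoothness SD on the scaled structure matrix.
    """

    temperature: str = "linear"  # "linear" | "rw2"
    adjusted: bool = True
    n_bins: int = 20
    prior_sd: float | None = 10.0
    patient_effect: bool = False
    patient_min_admissions: int = 2
    patient_sd_scale: float = 1.0
    rw2_sd_scale: float = 1.0
    backend: str = "laplace"  # "laplace" | "mcmc"
    chains: int = 4
    draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.temperature not in ("linear", "rw2"):
            raise DesignError(f"unknown temperature term {self.temperature!r}")
        if self.backend not in ("laplace", "mcmc"):
            raise DesignError(f"unknown backend {self.backend!r}")
        if self.temperature == "rw2" and self.n_bins < 4:
            raise DesignError("rw2 needs n_bins >= 4")
        if self.prior_sd is not None and self.prior_sd <= 0:
            raise DesignError("prior_sd must be > 0 (or None for flat)")


# ---------------------------------------------------------------------------
# conditional likelihood
# ---------------------------------------------------------------------------

def _check_one_case(design: DesignMatrix) -> None:
    cases = np.add.reduceat(design.y, design.stratum_starts)
    if not np.all(cases == 1):
        bad = int(np.argmax(cases != 1))
        raise DataError(
            f"stratum #{bad} has {int(cases[bad])} case rows (expected exactly 1)"
        )


def _cll_parts(beta: np.ndarray, X: np.ndarray, y: np.ndarray,
               starts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Conditional log-likelihood with gradient and Hessian, one pass."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    sizes = np.diff(np.r_[starts, len(eta)])
    e = np.exp(eta - np.repeat(m, sizes))
    denom = np.add.reduceat(e, starts)
    ll = float(eta[y == 1].sum() - (np.log(denom) + m).sum())
    w = e / np.repeat(denom, sizes)
    Xw = X * w[:, None]
    S = np.add.reduceat(Xw, starts, axis=0)  # per-stratum E[x]
    grad = X[y == 1].sum(axis=0) - S.sum(axis=0)
    hess = -(Xw.T @ X - S.T @ S)
    return ll, grad, hess


def conditional_loglik(beta, design: DesignMatrix) -> float:
    """Conditional Poisson log-likelihood (stratum intercepts conditioned out).

    Invariant to adding any stratum-constant quantity to the linear
    predictor — the formal statement that the design controls for factors
    that do not vary within a stratum.
    """
    _check_one_case(design)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _cll_parts(beta, design.X, design.y, design.stratum_starts)
    return ll


def conditional_score_hessian(beta, design: DesignMatrix):
    """Gradient and Hessian of :func:`conditional_loglik` at ``beta``."""
    _check_one_case(design)
    beta = np.asarray(beta, dtype=float)
    _, g, h = _cll_parts(beta, design.X, design.y, design.stratum_starts)
    return g, h


def _within_stratum_variance(X: np.ndarray, starts: np.ndarray,
                             sizes: np.ndarray) -> np.ndarray:
    means = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    centered = X - np.repeat(means, sizes, axis=0)
    return (centered**2).sum(axis=0)


def _newton(X, y, starts, prior_prec, beta0=None, tol=1e-9, max_iter=60):
    """Posterior mode of cll(beta) - 0.5 beta' P beta, with backtracking."""
    p = X.shape[1]
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    P = prior_prec

    def objective(b):
        ll, g, h = _cll_parts(b, X, y, starts)
        return ll - 0.5 * b @ P @ b, g - P @ b, h - P

    f, g, h = objective(beta)
    for it in range(max_iter):
        gnorm = float(np.linalg.norm(g, ord=np.inf))
        if gnorm < tol * (1.0 + abs(f)):
            return beta, f, g, h, it, True
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-h, g, rcond=None)[0]
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            fc, gc, hc = objective(cand)
            if fc > f - 1e-12:
                beta, f, g, h = cand, fc, gc, hc
                break
            t *= 0.5
        else:  # no ascent found
            return beta, f, g, h, it, False
    gnorm = float(np.linalg.norm(g, ord=np.inf))
    return beta, f, g, h, max_iter, gnorm < 1e-6 * (1.0 + abs(f))


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

def percent_change(beta):
    """Map log relative rate per degC to % risk change: 100*(exp(beta)-1).

    Monotone, so it is applied to posterior draws or quantiles directly.
    """
    return 100.0 * np.expm1(np.asarray(beta, dtype=float))


@dataclass
class FitResult:
    """Posterior summaries of one model fit.

    ``coef`` has one row per design column (posterior median, SD, 2.5% and
    97.5% quantiles, on the log-rate scale).  ``percent_change`` summarises
    the temperature coefficient as % risk change per 1 degC (same draws or
    quantiles, transformed).  For RW2 fits, ``curve`` holds the fitted
    exposure-response (log relative rate vs temperature, sum-to-zero
    centred) with its credible band.
    """

    coef: pd.DataFrame
    percent_change: dict | None
    diagnostics: dict
    curve: pd.DataFrame | None = None
    _mean: np.ndarray | None = None
    _cov: np.ndarray | None = None
    _active: list = field(default_factory=list)
    _draws: np.ndarray | None = None  # mcmc draws over active columns
    _rw2: dict | None = None

    def sample_coef(self, term: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Posterior draws of one coefficient (Gaussian for laplace backend)."""
        if term not in self._active:
            raise DataError(f"{term!r} was not an active model term")
        j = self._active.index(term)
        if self._draws is not None:
            idx = rng.integers(0, len(self._draws), n)
            return self._draws[idx, j]
        return rng.normal(self._mean[j], math.sqrt(self._cov[j, j]), n)


def _coef_table(columns, active, mean, cov, draws=None,
                inactive_sd=None) -> pd.DataFrame:
    rows = []
    for c in columns:
        if c in active:
            j = active.index(c)
            if draws is not None:
                med, lo, hi = np.percentile(draws[:, j], [50, 2.5, 97.5])
                sd = float(draws[:, j].std())
            else:
                sd = math.sqrt(max(cov[j, j], 0.0))
                med, lo, hi = mean[j], mean[j] - Z975 * sd, mean[j] + Z975 * sd
            rows.append((c, med, sd, lo, hi, False))
        else:
            sd = np.inf if inactive_sd is None else inactive_sd
            rows.append((c, 0.0, sd, -Z975 * sd, Z975 * sd, True))
    return pd.DataFrame(
        rows, columns=["term", "median", "sd", "lo", "hi", "decoupled"]
    ).set_index("term")


def _pct_summary(med, lo, hi):
    return {
        "median": float(percent_change(med)),
        "lo": float(percent_change(lo)),
        "hi": float(percent_change(hi)),
    }


# ---------------------------------------------------------------------------
# linear-temperature fit
# ---------------------------------------------------------------------------

def fit_model(design: DesignMatrix, spec: ModelSpec | None = None) -> FitResult:
    """Fit the (linear-temperature) conditional Poisson model.

    Default backend is the Laplace approximation: Newton ascent to the
    posterior mode under the conditional likelihood plus Normal priors,
    with Gaussian quantiles from the negative inverse Hessian.  The mcmc
    backend samples the same posterior and reports sample quantiles plus
    split-Rhat / effective-sample-size diagnostics.

    Columns with zero within-stratum variance carry no likelihood
    information (see module docstring); they are reported with their prior
    and flagged ``decoupled`` in the coefficient table.
    """
    spec = spec or ModelSpec()
    if spec.temperature == "rw2":
        return fit_rw2(design, spec)
    _check_one_case(design)

    wvar = _within_stratum_variance(design.X, design.stratum_starts,
                                    design.stratum_sizes)
    active_mask = wvar > 1e-12
    active = [c for c, a in zip(design.columns, active_mask) if a]
    if not active:
        raise DataError("no covariate varies within any stratum")
    Xa = design.X[:, active_mask]
    p = Xa.shape[1]
    prior_prec = (
        np.zeros((p, p)) if spec.prior_sd is None
        else np.eye(p) / spec.prior_sd**2
    )

    mode, f, g, h, n_iter, ok = _newton(Xa, design.y, design.stratum_starts,
                                        prior_prec)
    if not ok:
        raise ConvergenceError(
            f"posterior mode finding stalled after {n_iter} iterations "
            f"(|grad| = {np.linalg.norm(g, ord=np.inf):.3e})"
        )
    cov = np.linalg.inv(-h)

    diagnostics = {
        "backend": spec.backend,
        "converged": True,
        "n_iter": n_iter,
        "grad_norm": float(np.linalg.norm(g, ord=np.inf)),
        "n_strata": design.n_strata,
        "decoupled_columns": [c for c in design.columns if c not in active],
    }
    diagnostics.update(_patient_effect_diagnostics(design, spec))

    draws = None
    if spec.backend == "mcmc":
        draws, mcmc_diag = _run_mcmc(Xa, design.y, design.stratum_starts,
                                     prior_prec, mode, cov, spec)
        diagnostics.update(mcmc_diag)

    coef = _coef_table(design.columns, active, mode, cov, draws,
                       inactive_sd=spec.prior_sd)
    pct = None
    if "x_lag" in design.columns:
        row = coef.loc["x_lag"]
        pct = _pct_summary(row["median"], row["lo"], row["hi"])

    return FitResult(
        coef=coef,
        percent_change=pct,
        diagnostics=diagnostics,
        _mean=mode,
        _cov=cov,
        _active=active,
        _draws=draws,
    )


def _patient_effect_diagnostics(design: DesignMatrix, spec: ModelSpec) -> dict:
    if not spec.patient_effect:
        return {"patient_effect": "off"}
    # one stratum per admission => admissions per patient = strata per patient
    pid = design.patient_ids[design.stratum_starts]
    counts = pd.Series(pid).value_counts()
    eligible = int((counts >= spec.patient_min_admissions).sum())
    return {
        "patient_effect": "decoupled",
        "patient_effect_note": (
            "per-patient terms are constant within each admission's stratum; "
            "the conditional likelihood is invariant to them, so their "
            "posterior equals the prior and the exposure coefficient is "
            "unchanged"
        ),
        "n_patients_with_effect": eligible,
        "patient_sd_scale": spec.patient_sd_scale,
    }


def _run_mcmc(X, y, starts, prior_prec, mode, cov, spec: ModelSpec):
    import emcee

    p = X.shape[1]
    nwalkers = max(2 * p + 2, 2 * spec.chains, 8)

    def log_prob(b):
        ll, _, _ = _cll_parts(b, X, y, starts)
        return ll - 0.5 * b @ prior_prec @ b

    rng = np.random.default_rng(spec.seed)
    scale = np.sqrt(np.diag(cov))
    p0 = mode + scale * rng.standard_normal((nwalkers, p))
    sampler = emcee.EnsembleSampler(nwalkers, p, log_prob)
    # the ensemble sampler keeps its own legacy RNG; seed it for determinism
    sampler.random_state = np.random.RandomState(spec.seed).get_state()
    burn = max(200, spec.draws // 2)
    state = sampler.run_mcmc(p0, burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, spec.draws, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, p)

    import arviz as az

    posterior = {
        f"b{j}": np.moveaxis(chain[:, :, j], 0, 1) for j in range(p)
    }
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata).to_array().values
    ess = az.ess(idata).to_array().values
    diag = {
        "rhat_max": float(np.max(rhat)),
        "ess_min": float(np.min(ess)),
    }
    if diag["rhat_max"] > 1.05:
        diag["warning"] = f"split-Rhat {diag['rhat_max']:.3f} > 1.05"
    return chain.reshape(-1, p), diag


# ---------------------------------------------------------------------------
# RW2 exposure-response
# ---------------------------------------------------------------------------

@dataclass
class Rw2Prior:
    """Second-difference (RW2) structure over temperature bins.

    ``structure`` is the scaled penalty matrix D'D: symmetric PSD with rank
    ``n_bins - 2`` and null space spanned by constant and linear vectors.
    Scaling follows the generalized-variance convention (geometric mean of
    the marginal variances of the intrinsic model equals one) so the
    smoothness hyperprior has a scale-free interpretation.
    """

    midpoints: np.ndarray
    edges: np.ndarray
    structure: np.ndarray
    rank: int
    scale: float
    sum_to_zero: bool = True

    @property
    def n_bins(self) -> int:
        return len(self.midpoints)


def make_rw2_prior(temps, n_bins: int = 20) -> Rw2Prior:
    """Equal-width bins over the observed exposure range + scaled RW2 penalty."""
    temps = np.asarray(temps, dtype=float)
    temps = temps[np.isfinite(temps)]
    if n_bins < 4:
        raise DesignError("rw2 needs n_bins >= 4")
    lo, hi = float(temps.min()), float(temps.max())
    if not hi > lo:
        raise DesignError("degenerate temperature range for rw2 binning")
    edges = np.linspace(lo, hi, n_bins + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    D = np.zeros((n_bins - 2, n_bins))
    for i in range(n_bins - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    K = D.T @ D
    gv = float(np.exp(np.mean(np.log(np.diag(np.linalg.pinv(K))))))
    return Rw2Prior(midpoints=mid, edges=edges, structure=K * gv,
                    rank=n_bins - 2, scale=gv)


def _bin_index(x, prior: Rw2Prior) -> np.ndarray:
    width = prior.edges[1] - prior.edges[0]
    ib = np.floor((np.asarray(x) - prior.edges[0]) / width).astype(int)
    return np.clip(ib, 0, prior.n_bins - 1)


def fit_rw2(design: DesignMatrix, spec: ModelSpec) -> FitResult:
    """Fit the RW2 exposure-response curve (INLA-style Laplace inference).

    The temperature column is replaced by one indicator per bin, the curve
    gets the RW2 prior with a sum-to-zero constraint (enforced by
    reparametrizing on an orthonormal basis of the zero-sum subspace) plus a
    weak Normal fixed-effect prior, and the smoothness precision tau is set
    by maximizing the Laplace-approximate marginal likelihood under a
    half-Normal hyperprior on the smoothness SD.  Quantiles condition on the
    optimized tau.
    """
    _check_one_case(design)
    if "x_lag" not in design.columns:
        raise DesignError("rw2 fit needs the x_lag column in the design")
    prior = make_rw2_prior(design.x_lag, spec.n_bins)
    nb = prior.n_bins
    ib = _bin_index(design.x_lag, prior)
    Z = np.zeros((len(ib), nb))
    Z[np.arange(len(ib)), ib] = 1.0

    other_cols = [c for c in design.columns if c != "x_lag"]
    W = design.X[:, [design.columns.index(c) for c in other_cols]]
    # keep only columns with within-stratum variation (as in fit_model)
    if W.shape[1]:
        wvar = _within_stratum_variance(W, design.stratum_starts,
                                        design.stratum_sizes)
        keep = wvar > 1e-12
        other_active = [c for c, k in zip(other_cols, keep) if k]
        W = W[:, keep]
    else:
        other_active = []

    A = sla.null_space(np.ones((1, nb)))  # (nb, nb-1), orthonormal
    Xe = np.hstack([Z @ A, W])
    nz, nw = nb - 1, W.shape[1]
    fixed_prec = 0.0 if spec.prior_sd is None else 1.0 / spec.prior_sd**2
    AKA = A.T @ prior.structure @ A

    def prior_prec(log_tau: float) -> np.ndarray:
        P = np.zeros((nz + nw, nz + nw))
        P[:nz, :nz] = math.exp(log_tau) * AKA + fixed_prec * np.eye(nz)
        P[nz:, nz:] = fixed_prec * np.eye(nw)
        return P

    s = spec.rw2_sd_scale

    def log_hyper(log_tau: float) -> float:
        # half-Normal(0, s) on sigma = tau^(-1/2), with the log-tau Jacobian
        sigma2 = math.exp(-log_tau)
        return -sigma2 / (2 * s**2) - 0.5 * log_tau

    warm = {"b": None}

    def neg_marginal(log_tau: float) -> float:
        P = prior_prec(log_tau)
        mode, fval, g, h, _, ok = _newton(Xe, design.y, design.stratum_starts,
                                          P, beta0=warm["b"])
        if not ok:
            return np.inf
        warm["b"] = mode
        _, ld_prior = np.linalg.slogdet(P)
        _, ld_post = np.linalg.slogdet(-h)
        return -(fval + 0.5 * ld_prior - 0.5 * ld_post + log_hyper(log_tau))

    opt = minimize_scalar(neg_marginal, bounds=(-6.0, 14.0), method="bounded",
                          options={"xatol": 0.02})
    log_tau = float(opt.x)
    P = prior_prec(log_tau)
    mode, fval, g, h, n_iter, ok = _newton(Xe, design.y, design.stratum_starts,
                                           P, beta0=warm["b"])
    if not ok:
        raise ConvergenceError(
            f"rw2 mode finding stalled (|grad| = "
            f"{np.linalg.norm(g, ord=np.inf):.3e})"
        )
    cov = np.linalg.inv(-h)

    theta_mean = A @ mode[:nz]
    theta_cov = A @ cov[:nz, :nz] @ A.T
    theta_sd = np.sqrt(np.maximum(np.diag(theta_cov), 0.0))
    curve = pd.DataFrame(
        {
            "temperature": prior.midpoints,
            "median": theta_mean,
            "lo": theta_mean - Z975 * theta_sd,
            "hi": theta_mean + Z975 * theta_sd,
            "n_rows": np.bincount(ib, minlength=nb),
        }
    )

    coef = _coef_table(other_active, other_active, mode[nz:], cov[nz:, nz:],
                       inactive_sd=spec.prior_sd)
    mass_lo, mass_hi = np.percentile(design.x_lag, [5, 95])
    diagnostics = {
        "backend": "laplace",
        "converged": True,
        "n_iter": n_iter,
        "grad_norm": float(np.linalg.norm(g, ord=np.inf)),
        "n_strata": design.n_strata,
        "tau": math.exp(log_tau),
        "sigma_rw2": math.exp(-log_tau / 2),
        "n_bins": nb,
    }
    return FitResult(
        coef=coef,
        percent_change=None,
        diagnostics=diagnostics,
        curve=curve,
        _mean=mode,
        _cov=cov,
        _active=list(other_active),
        _rw2={
            "theta_mean": theta_mean,
            "theta_cov": theta_cov,
            "midpoints": prior.midpoints,
            "mass_lo": float(mass_lo),
            "mass_hi": float(mass_hi),
        },
    )


def linearity_summary(fit: FitResult) -> dict:
    """Departure of the posterior-median RW2 curve from its own LS line.

    Computed over bins whose midpoints lie within the central 5-95% of
    exposure mass.  Returns the maximum absolute deviation, the curve's
    range over the same bins, and their ratio (small ratio = near-linear).
    """
    if fit._rw2 is None:
        raise DataError("linearity_summary needs an rw2 fit")
    r = fit._rw2
    sel = (r["midpoints"] >= r["mass_lo"]) & (r["midpoints"] <= r["mass_hi"])
    x, yv = r["midpoints"][sel], r["theta_mean"][sel]
    slope, intercept = np.polyfit(x, yv, 1)
    resid = yv - (slope * x + intercept)
    rng_ = float(yv.max() - yv.min())
    max_dev = float(np.abs(resid).max())
    return {
        "max_deviation": max_dev,
        "curve_range": rng_,
        "ratio": max_dev / rng_ if rng_ > 0 else 0.0,
        "ls_slope": float(slope),
    }


def threshold_slope_probability(
    fit: FitResult, threshold: float, n_draws: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Posterior probability that the curve slope above ``threshold`` exceeds
    the slope below it (both slopes by least squares over bin midpoints)."""
    if fit._rw2 is None:
        raise DataError("threshold_slope_probability needs an rw2 fit")
    rng = rng or np.random.default_rng(0)
    r = fit._rw2
    mid = r["midpoints"]
    cov = r["theta_cov"] + 1e-10 * np.eye(len(mid))
    L = np.linalg.cholesky(cov)
    draws = r["theta_mean"] + rng.standard_normal((n_draws, len(mid))) @ L.T

    def slope_weights(sel: np.ndarray) -> np.ndarray:
        w = np.zeros(len(mid))
        xc = mid[sel] - mid[sel].mean()
        w[sel] = xc / (xc @ xc)
        return w

    above, below = mid > threshold, mid <= threshold
    if above.sum() < 2 or below.sum() < 2:
        raise DesignError("threshold leaves fewer than 2 bins on one side")
    s_hi = draws @ slope_weights(above)
    s_lo = draws @ slope_weights(below)
    return float(np.mean(s_hi > s_lo))


# ---------------------------------------------------------------------------
# convenience
# ---------------------------------------------------------------------------

def fit(strata: pd.DataFrame, spec: ModelSpec | None = None,
        extra_columns: tuple[str, ...] = ()) -> FitResult:
    """Build the design matrix for ``spec`` and fit it."""
    spec = spec or ModelSpec()
    design = build_design_matrix(strata, adjusted=spec.adjusted,
                                 extra_columns=extra_columns)
    return fit_model(design, spec)
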