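"""Hierarchical Bayesian random-intercept regression with a Gibbs sampler.

The model regresses a synchrony measure on one or more drivers with
random intercepts for species and pixel:

    y_i ~ N(mu_i, sigma^2)
    mu_i = alpha + sum_k beta_k x_ik + u_species(i) + v_pixel(i)
    u_j ~ N(0, tau_sp^2),  v_k ~ N(0, tau_px^2)

Priors follow common noninformative practice for this model class:
N(0, 1000) on alpha and each beta, Uniform(0, 100) on the random-intercept
*variances* (not SDs), and a vague inverse-gamma(1e-3, 1e-3) on the
residual variance.  All conditionals except the uniform-prior variances
are conjugate and sampled in closed form; the variances are updated by
slice sampling on their bounded support.

Continuous variables are conventionally standardized by centering and
dividing by twice the sample SD, which puts binary and continuous
predictors on a comparable scale and makes effect sizes directly
comparable across drivers.

Convergence is assessed with the Gelman-Rubin potential scale reduction
factor across chains; runs exceeding 1.1 on any monitored parameter are
flagged with a :class:`~phenosync.exceptions.ConvergenceWarning`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    ConvergenceWarning,
    DegenerateInputError,
    InvalidParameterError,
)

PRIOR_BETA_VARIANCE = 1000.0
TAU2_UPPER = 100.0
RHAT_THRESHOLD = 1.1

#: Predictor sets of the two standard model variants: synchrony against
#: preseason temperature, or against day length and chilling jointly.
VARIANTS = {
    "temperature": ["preseason_temp"],
    "daylength_chilling": ["dl_at_forcing", "mean_chilling"],
}


def standardize_2sd(x: np.ndarray) -> np.ndarray:
    """Center and scale by twice the sample SD; result has mean 0, SD 0.5."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot standardize a constant vector")
    return (x - x.mean()) / (2.0 * sd)


@dataclass
class HBData:
    """Design data for the random-intercept model.

    ``X`` excludes the intercept column; ``species_idx`` / ``pixel_idx``
    are 0-based level codes or ``None`` when the corresponding random
    effect is absent.
    """

    y: np.ndarray
    X: np.ndarray
    predictor_names: list[str]
    species_idx: np.ndarray | None = None
    pixel_idx: np.ndarray | None = None
    species_levels: list = field(default_factory=list)
    pixel_levels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.y.size
        if self.X.shape[0] != n:
            raise InvalidParameterError("X and y lengths differ")
        for idx, name in ((self.species_idx, "species"), (self.pixel_idx, "pixel")):
            if idx is not None and idx.size != n:
                raise InvalidParameterError(f"{name} index length differs from y")

    @property
    def n_species(self) -> int:
        return len(self.species_levels)

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_levels)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        response: str,
        predictors: list[str],
        species_col: str | None = None,
        pixel_col: str | None = None,
        standardize: bool = True,
    ) -> "HBData":
        """Build model data from a tidy frame, optionally 2-SD standardized.

        Standardization is applied to the response and every predictor.
        Grouping factors with fewer than two levels are dropped with a
        warning (a one-level random intercept is not identifiable).
        """
        data = df[[response, *predictors]].copy()
        cols = [c for c in (species_col, pixel_col) if c is not None]
        data = pd.concat([data, df[cols]], axis=1).dropna()
        y = data[response].to_numpy(dtype=float)
        X = data[predictors].to_numpy(dtype=float)
        if standardize:
            y = standardize_2sd(y)
            X = np.column_stack([standardize_2sd(X[:, k]) for k in range(X.shape[1])]) if X.size else X

        def _codes(col):
            if col is None:
                return None, []
            codes, levels = pd.factorize(data[col], sort=True)
            if len(levels) < 2:
                warnings.warn(
                    f"random effect {col!r} has < 2 levels and is dropped"
                )
                return None, []
            return codes.astype(np.int64), list(levels)

        sp_idx, sp_levels = _codes(species_col)
        px_idx, px_levels = _codes(pixel_col)
        return cls(
            y=y,
            X=X,
            predictor_names=list(predictors),
            species_idx=sp_idx,
            pixel_idx=px_idx,
            species_levels=sp_levels,
            pixel_levels=px_levels,
        )


def _slice_bounded(logp, x0: float, lo: float, hi: float, rng) -> float:
    """One slice-sampling update on a bounded support (shrinkage variant)."""
    height = logp(x0) - rng.exponential()
    left, right = lo, hi
    for _ in range(1000):
        x = rng.uniform(left, right)
        if logp(x) >= height:
            return x
        if x < x0:
            left = x
        else:
            right = x
    return x0  # pathological shrinkage; keep the current state


def _sample_tau2(effects: np.ndarray, current: float, rng) -> float:
    """Slice-sample a random-intercept variance under Uniform(0, TAU2_UPPER)."""
    j = effects.size
    s = max(float(np.sum(effects**2)), 1e-12)

    def logp(t: float) -> float:
        return -0.5 * j * math.log(t) - s / (2.0 * t)

    return _slice_bounded(logp, current, 1e-10, TAU2_UPPER, rng)


@dataclass
class HBPosterior:
    """Post-burn-in MCMC draws with convergence bookkeeping.

    ``draws`` maps parameter name to an array of shape (chains, n_draws).
    Monitored parameters (intercept, slopes, variances) drive the
    convergence flag; random-intercept draws are kept for inspection.
    """

    draws: dict[str, np.ndarray]
    monitored: list[str]
    chains: int
    iterations: int
    burnin: int

    def rhat(self) -> dict[str, float]:
        return {name: gelman_rubin(self.draws[name]) for name in self.monitored}

    @property
    def converged(self) -> bool:
        values = [v for v in self.rhat().values() if np.isfinite(v)]
        return bool(values) and max(values) <= RHAT_THRESHOLD

    def summary(self) -> pd.DataFrame:
        rows = {}
        rhats = self.rhat()
        for name, arr in self.draws.items():
            flat = arr.ravel()
            rows[name] = {
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)),
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": rhats.get(name, np.nan),
            }
        return pd.DataFrame(rows).T

    def credible_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        flat = self.draws[name].ravel()
        lo = (1.0 - level) / 2.0
        return float(np.quantile(flat, lo)), float(np.quantile(flat, 1.0 - lo))


def fit_hb_model(
    data: HBData,
    chains: int = 3,
    iterations: int = 4000,
    burnin: int = 1000,
    seed: int = 0,
    prior_beta_var: float = PRIOR_BETA_VARIANCE,
) -> HBPosterior:
    """Fit the random-intercept regression by Gibbs sampling.

    Runs ``chains`` independent chains of ``iterations`` sweeps each and
    keeps the draws after ``burnin``.  Default lengths (4000/1000) are
    sized for desk-scale data; production-length chains are a matter of
    passing larger values.  Seeds are split deterministically across
    chains, so identical inputs give identical posteriors.

    Emits a :class:`ConvergenceWarning` when any monitored parameter has
    a Gelman-Rubin statistic above 1.1 (the posterior is still returned,
    never silently accepted).
    """
    if chains < 1 or iterations <= burnin:
        raise InvalidParameterError("need chains >= 1 and iterations > burnin")
    y, X = data.y, data.X
    n = y.size
    design = np.column_stack([np.ones(n), X])
    p = design.shape[1]
    names = ["alpha"] + [f"beta[{nm}]" for nm in data.predictor_names]

    xtx = design.T @ design
    prior_prec = np.eye(p) / prior_beta_var
    kept = iterations - burnin

    has_sp = data.species_idx is not None
    has_px = data.pixel_idx is not None
    n_sp, n_px = data.n_species, data.n_pixels
    if has_sp:
        counts_sp = np.bincount(data.species_idx, minlength=n_sp).astype(float)
    if has_px:
        counts_px = np.bincount(data.pixel_idx, minlength=n_px).astype(float)

    param_names = names + ["sigma2"]
    if has_sp:
        param_names += ["tau2_species"] + [f"u_species[{lv}]" for lv in data.species_levels]
    if has_px:
        param_names += ["tau2_pixel"] + [f"v_pixel[{lv}]" for lv in data.pixel_levels]
    store = {nm: np.empty((chains, kept)) for nm in param_names}

    seeds = np.random.SeedSequence(seed).spawn(chains)
    ols_beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        beta = ols_beta + rng.normal(0.0, 0.1, p)
        resid0 = y - design @ beta
        sigma2 = max(float(np.var(resid0)), 1e-6)
        u = rng.normal(0.0, 0.1, n_sp) if has_sp else np.zeros(0)
        v = rng.normal(0.0, 0.1, n_px) if has_px else np.zeros(0)
        tau2_sp = 1.0
        tau2_px = 1.0

        for it in range(iterations):
            re_part = np.zeros(n)
            if has_sp:
                re_part += u[data.species_idx]
            if has_px:
                re_part += v[data.pixel_idx]

            # beta | rest (conjugate multivariate normal)
            prec = xtx / sigma2 + prior_prec
            chol = np.linalg.cholesky(prec)
            rhs = design.T @ (y - re_part) / sigma2
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(p)
            beta = mean + np.linalg.solve(chol.T, z)
            fixed = design @ beta

            # species intercepts and variance
            if has_sp:
                r = y - fixed - (v[data.pixel_idx] if has_px else 0.0)
                s = np.bincount(data.species_idx, weights=r, minlength=n_sp)
                post_var = 1.0 / (counts_sp / sigma2 + 1.0 / tau2_sp)
                u = post_var * s / sigma2 + np.sqrt(post_var) * rng.standard_normal(n_sp)
                tau2_sp = _sample_tau2(u, tau2_sp, rng)

            # pixel intercepts and variance
            if has_px:
                r = y - fixed - (u[data.species_idx] if has_sp else 0.0)
                s = np.bincount(data.pixel_idx, weights=r, minlength=n_px)
                post_var = 1.0 / (counts_px / sigma2 + 1.0 / tau2_px)
                v = post_var * s / sigma2 + np.sqrt(post_var) * rng.standard_normal(n_px)
                tau2_px = _sample_tau2(v, tau2_px, rng)

            # residual variance (conjugate inverse-gamma)
            re_part = np.zeros(n)
            if has_sp:
                re_part += u[data.species_idx]
            if has_px:
                re_part += v[data.pixel_idx]
            sse = float(np.sum((y - fixed - re_part) ** 2))
            sigma2 = 1.0 / rng.gamma(1e-3 + 0.5 * n, 1.0 / (1e-3 + 0.5 * sse))

            if it >= burnin:
                k = it - burnin
                for d, nm in enumerate(names):
                    store[nm][c, k] = beta[d]
                store["sigma2"][c, k] = sigma2
                if has_sp:
                    store["tau2_species"][c, k] = tau2_sp
                    for j, lv in enumerate(data.species_levels):
                        store[f"u_species[{lv}]"][c, k] = u[j]
                if has_px:
                    store["tau2_pixel"][c, k] = tau2_px
                    for j, lv in enumerate(data.pixel_levels):
                        store[f"v_pixel[{lv}]"][c, k] = v[j]

    monitored = names + ["sigma2"]
    if has_sp:
        monitored.append("tau2_species")
    if has_px:
        monitored.append("tau2_pixel")
    posterior = HBPosterior(
        draws=store,
        monitored=monitored,
        chains=chains,
        iterations=iterations,
        burnin=burnin,
    )
    if chains >= 2 and not posterior.converged:
        warnings.warn(
            "Gelman-Rubin statistic above 1.1 on a monitored parameter",
            ConvergenceWarning,
        )
    return posterior


def gelman_rubin(draws_by_chain: np.ndarray) -> float:
    """Potential scale reduction factor from between/within-chain variance.

    ``draws_by_chain`` has shape (chains, draws).  Returns NaN (with a
    warning) in the degenerate case of zero within-chain variance, e.g.
    chains stuck at constants.
    """
    draws = np.asarray(draws_by_chain, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise InvalidParameterError("need draws from at least two chains")
    m, n = draws.shape
    if n < 2:
        raise InvalidParameterError("need at least two draws per chain")
    chain_means = draws.mean(axis=1)
    w = float(draws.var(axis=1, ddof=1).mean())
    b = float(n * chain_means.var(ddof=1))
    if w == 0:
        warnings.warn("zero within-chain variance: Gelman-Rubin undefined")
        return math.nan
    var_plus = (n - 1) / n * w + b / n
    return math.sqrt(var_plus / w)


def hb_data_for_variant(
    df: pd.DataFrame,
    response: str,
    variant: str,
    species_col: str | None = "species",
    pixel_col: str | None = "pixel",
    standardize: bool = True,
) -> HBData:
    """Build :class:`HBData` for a named model variant.

    ``"temperature"`` regresses the response on preseason temperature;
    ``"daylength_chilling"`` on day length at forcing fulfilment and
    accumulated chilling jointly.
    """
    if variant not in VARIANTS:
        raise InvalidParameterError(f"unknown variant {variant!r}")
    return HBData.from_frame(
        df,
        response=response,
        predictors=VARIANTS[variant],
        species_col=species_col,
        pixel_col=pixel_col,
        standardize=standardize,
    )
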