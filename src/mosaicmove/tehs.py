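"""Time-explicit habitat selection (TEHS): two Bayesian submodels per animal.

The TEHS analysis couples two views of each step:

*Time submodel* — how long the animal takes to cross the landscape::

    log t_i ~ Normal(b0 + g * log d_i + sum_k b_k p_ik, sigma^2)

where ``t_i`` is the step duration, ``d_i`` the (zero-floored) step length
and ``p_ik`` the buffered-path proportion of non-baseline class ``k``
(pasture is the baseline and enters as the implicit remainder).  Reported
as *time ratios* ``exp(b_a - b_b)``: a ratio above 1 means slower movement
(more time) in class ``a`` than in class ``b``.

*Habitat-selection submodel* — which step the animal chose, a conditional
logit over the observed step and four cardinal alternatives of identical
length::

    P(observed | choice set) = exp(a . p_obs) / sum_j exp(a . p_j)

Because all five candidates share the start point, length and duration,
those cancel and only the compositions drive the choice.  Reported as
*odds ratios* ``exp(a_k)``: above 1 = selection of class ``k`` over
pasture, below 1 = avoidance.

Both submodels use Normal(0, 10^2) priors on coefficients and a
Half-Normal(0, 5) prior on sigma, and are fitted independently per
individual; population results are post-hoc tallies of per-individual 95%
credible intervals, stratified by sex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

import arviz as az

from .landscape import ConfigurationError


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults suit the per-individual TEHS fits."""

    n_iter: int = 4000
    n_burn: int = 2000
    n_chains: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_burn < self.n_iter):
            raise ConfigurationError("need 0 <= n_burn < n_iter")
        if self.n_chains < 1:
            raise ConfigurationError("need at least one chain")

    def chain_rng(self, chain: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(chain,))
        )


@dataclass
class PosteriorFit:
    """MCMC draws plus per-parameter summaries for one submodel fit.

    ``draws`` maps parameter name -> array of shape (n_chains, n_kept).
    """

    draws: dict[str, np.ndarray]
    covariates: tuple[str, ...]
    summary: pd.DataFrame
    mcmc: MCMCConfig

    def stacked(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)


def summarize_draws(draws: Mapping[str, np.ndarray], mcmc: MCMCConfig) -> pd.DataFrame:
    """Posterior mean/sd/quantiles plus split-Rhat and ESS per parameter."""
    rows = []
    for name, arr in draws.items():
        flat = arr.reshape(-1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess = float(az.ess(arr))
            rhat = float(az.rhat(arr)) if arr.shape[1] >= 4 else np.nan
        rows.append(
            {
                "parameter": name,
                "mean": flat.mean(),
                "sd": flat.std(ddof=1),
                "q2.5": np.quantile(flat, 0.025),
                "q50": np.quantile(flat, 0.5),
                "q97.5": np.quantile(flat, 0.975),
                "ess": ess,
                "rhat": rhat,
            }
        )
    df = pd.DataFrame(rows).set_index("parameter")
    bad = df["rhat"].dropna() > 1.05
    if bad.any():
        warnings.warn(
            f"possible non-convergence (split-Rhat > 1.05): {list(df.index[df['rhat'] > 1.05])}"
        )
    return df


# ---------------------------------------------------------------------------
# Time submodel
# ---------------------------------------------------------------------------

def fit_time_submodel(
    d: np.ndarray,
    t_min: np.ndarray,
    p: np.ndarray,
    covariates: Sequence[str],
    mcmc: MCMCConfig = MCMCConfig(),
    prior_sd: float = 10.0,
    sigma_prior_scale: float = 5.0,
    sigma_fixed: float | None = None,
) -> PosteriorFit:
    """Gibbs sampler for the log-normal traversal-time regression.

    Coefficients are drawn from their exact conjugate multivariate-normal
    conditional given sigma; sigma is updated by an adaptive random-walk
    Metropolis step on log sigma under the Half-Normal prior.  Passing
    ``sigma_fixed`` holds sigma at a known value, making the whole fit
    conjugate (used by the closed-form oracle checks).

    ``p`` has one column per entry of ``covariates`` (the non-baseline
    class proportions).  Columns with zero variance are dropped for this
    fit with a warning.
    """
    d = np.asarray(d, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.ndim == 1:
        p = p[:, None]
    if np.any(d <= 0):
        raise ValueError("step lengths must be positive (floor zero steps first)")
    if np.any(t_min <= 0):
        raise ValueError("durations must be positive")

    covariates = list(covariates)
    keep = []
    for j, name in enumerate(covariates):
        if len(d) and np.ptp(p[:, j]) == 0.0:
            warnings.warn(f"covariate {name!r} has zero variance; dropped from this fit")
        else:
            keep.append(j)
    covariates = [covariates[j] for j in keep]
    p = p[:, keep]

    names = ["beta0", "gamma"] + [f"beta[{c}]" for c in covariates]
    x = np.column_stack([np.ones(len(d)), np.log(d), p]) if len(d) else np.empty((0, len(names)))
    y = np.log(t_min)
    n, q = x.shape
    xtx = x.T @ x
    xty = x.T @ y
    prior_prec = np.eye(q) / prior_sd**2

    n_kept = mcmc.n_iter - mcmc.n_burn
    coef_draws = np.empty((mcmc.n_chains, n_kept, q))
    sigma_draws = np.empty((mcmc.n_chains, n_kept))

    for chain in range(mcmc.n_chains):
        rng = mcmc.chain_rng(chain)
        sigma = sigma_fixed if sigma_fixed is not None else 1.0
        beta = np.zeros(q)
        log_step = -0.5  # RW scale on log sigma, adapted during burn-in
        accepted = 0
        window = 0
        for it in range(mcmc.n_iter):
            # beta | sigma : conjugate MVN
            prec = xtx / sigma**2 + prior_prec
            chol = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, xty / sigma**2) if n else np.zeros(q)
            z = rng.standard_normal(q)
            beta = mean + np.linalg.solve(chol.T, z)
            if sigma_fixed is None:
                # log sigma : adaptive random-walk Metropolis
                resid = y - x @ beta if n else y
                ssr = float(resid @ resid)

                def logpost(log_s: float) -> float:
                    s = np.exp(log_s)
                    return (
                        -n * log_s
                        - ssr / (2 * s**2)
                        - s**2 / (2 * sigma_prior_scale**2)
                        + log_s  # Jacobian of the log transform
                    )

                cur = np.log(sigma)
                prop = cur + np.exp(log_step) * rng.standard_normal()
                if np.log(rng.random()) < logpost(prop) - logpost(cur):
                    sigma = float(np.exp(prop))
                    accepted += 1
                window += 1
                if it < mcmc.n_burn and window == 50:
                    rate = accepted / window
                    log_step += 0.5 * (rate - 0.44)
                    accepted = window = 0
            if it >= mcmc.n_burn:
                coef_draws[chain, it - mcmc.n_burn] = beta
                sigma_draws[chain, it - mcmc.n_burn] = sigma

    draws = {name: coef_draws[:, :, j] for j, name in enumerate(names)}
    draws["sigma"] = sigma_draws
    return PosteriorFit(
        draws=draws,
        covariates=tuple(covariates),
        summary=summarize_draws(draws, mcmc),
        mcmc=mcmc,
    )


@dataclass(frozen=True)
class RatioResult:
    """Posterior of a ratio-scale contrast with its 95% CI verdict.

    ``direction`` is ``"above"`` when the equal-tailed 95% interval lies
    entirely above 1, ``"below"`` when entirely below, else ``None``.
    For time ratios "above" = slower (more time); for odds ratios
    "above" = selection, "below" = avoidance.
    """

    name: str
    draws: np.ndarray
    mean: float
    q2_5: float
    q97_5: float
    direction: str | None

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray) -> "RatioResult":
        lo, hi = np.quantile(draws, [0.025, 0.975])
        direction = "above" if lo > 1.0 else ("below" if hi < 1.0 else None)
        return cls(name, draws, float(draws.mean()), float(lo), float(hi), direction)


def _coef_draws(fit: PosteriorFit, prefix: str, cls: str, baseline: str) -> np.ndarray:
    if cls == baseline:
        return np.zeros_like(next(iter(fit.draws.values())).reshape(-1))
    key = f"{prefix}[{cls}]"
    if key not in fit.draws:
        raise KeyError(f"class {cls!r} was not a covariate of this fit")
    return fit.stacked(key)


def time_ratio(
    fit: PosteriorFit, class_a: str, class_b: str = "pasture"
) -> RatioResult:
    """Posterior of the time ratio exp(b_a - b_b); > 1 means slower in a."""
    if class_a == class_b:
        draws = np.ones_like(next(iter(fit.draws.values())).reshape(-1))
        return RatioResult(f"time[{class_a}/{class_b}]", draws, 1.0, 1.0, 1.0, None)
    ba = _coef_draws(fit, "beta", class_a, "pasture")
    bb = _coef_draws(fit, "beta", class_b, "pasture")
    return RatioResult.from_draws(f"time[{class_a}/{class_b}]", np.exp(ba - bb))


# ---------------------------------------------------------------------------
# Habitat-selection submodel (conditional logit)
# ---------------------------------------------------------------------------

def selection_loglik(alpha: np.ndarray, x: np.ndarray, chosen: np.ndarray) -> float:
    """Conditional-logit log-likelihood over choice sets.

    ``x`` has shape (n_sets, n_candidates, n_covariates); ``chosen`` gives
    the index of the selected candidate in each set.
    """
    util = x @ np.asarray(alpha, dtype=float)
    return float(
        util[np.arange(len(chosen)), chosen].sum() - logsumexp(util, axis=1).sum()
    )


def selection_map(
    x: np.ndarray, chosen: np.ndarray, prior_sd: float = 10.0
) -> np.ndarray:
    """Posterior mode (MAP) of the selection coefficients via BFGS."""
    k = x.shape[2]

    def neg(alpha: np.ndarray) -> float:
        return -selection_loglik(alpha, x, chosen) + float(alpha @ alpha) / (
            2 * prior_sd**2
        )

    res = optimize.minimize(neg, np.zeros(k), method="BFGS")
    return res.x


def fit_selection_submodel(
    x: np.ndarray,
    chosen: np.ndarray,
    covariates: Sequence[str],
    mcmc: MCMCConfig = MCMCConfig(),
    prior_sd: float = 10.0,
) -> PosteriorFit:
    """Adaptive random-walk Metropolis for the conditional-logit posterior.

    The proposal is an isotropic Gaussian whose scale adapts during
    burn-in towards an acceptance rate in the 0.2-0.4 band.  Complete
    separation is not fatal: the Normal(0, 10^2) prior keeps the posterior
    proper (a warning is emitted when the MAP norm is extreme).
    """
    x = np.asarray(x, dtype=float)
    chosen = np.asarray(chosen, dtype=int)
    if x.ndim != 3:
        raise ValueError("x must have shape (n_sets, n_candidates, n_covariates)")
    covariates = list(covariates)
    k = x.shape[2]
    if len(covariates) != k:
        raise ValueError("covariate names must match x's last dimension")

    def logpost(alpha: np.ndarray) -> float:
        ll = selection_loglik(alpha, x, chosen) if len(chosen) else 0.0
        return ll - float(alpha @ alpha) / (2 * prior_sd**2)

    n_kept = mcmc.n_iter - mcmc.n_burn
    alpha_draws = np.empty((mcmc.n_chains, n_kept, k))
    for chain in range(mcmc.n_chains):
        rng = mcmc.chain_rng(chain)
        alpha = np.zeros(k)
        lp = logpost(alpha)
        log_step = np.log(0.1)
        accepted = window = 0
        for it in range(mcmc.n_iter):
            prop = alpha + np.exp(log_step) * rng.standard_normal(k)
            lp_prop = logpost(prop)
            if np.log(rng.random()) < lp_prop - lp:
                alpha, lp = prop, lp_prop
                accepted += 1
            window += 1
            if it < mcmc.n_burn and window == 50:
                rate = accepted / window
                log_step += 0.5 * (rate - 0.3)
                accepted = window = 0
            if it >= mcmc.n_burn:
                alpha_draws[chain, it - mcmc.n_burn] = alpha

    draws = {f"alpha[{c}]": alpha_draws[:, :, j] for j, c in enumerate(covariates)}
    if len(chosen):
        map_est = selection_map(x, chosen, prior_sd)
        if np.linalg.norm(map_est) > 3 * prior_sd:
            warnings.warn(
                "extreme selection coefficients: possible complete separation; "
                "posterior is regularized by the prior"
            )
    return PosteriorFit(
        draws=draws,
        covariates=tuple(covariates),
        summary=summarize_draws(draws, mcmc),
        mcmc=mcmc,
    )


def odds_ratio(fit: PosteriorFit, class_k: str, baseline: str = "pasture") -> RatioResult:
    """Posterior odds ratio exp(a_k); > 1 = selection, < 1 = avoidance."""
    if class_k == baseline:
        draws = np.ones_like(next(iter(fit.draws.values())).reshape(-1))
        return RatioResult(f"or[{class_k}]", draws, 1.0, 1.0, 1.0, None)
    return RatioResult.from_draws(f"or[{class_k}]", np.exp(_coef_draws(fit, "alpha", class_k, baseline)))


# ---------------------------------------------------------------------------
# Population tallies
# ---------------------------------------------------------------------------

def tally_population(records: pd.DataFrame) -> pd.DataFrame:
    """Count individuals with CI-significant effects per class, by sex.

    ``records`` needs columns ``individual_id, sex, class, direction``
    where direction is ``"above"``, ``"below"`` or ``None``/NaN per fitted
    class (one row per individual x class for which the class was
    retained).  Returns counts and percentages for groups all/female/male;
    denominators are the individuals with that class retained.
    """
    required = {"individual_id", "sex", "class", "direction"}
    if not required.issubset(records.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    out = []
    groups = [("all", records)] + [
        (sex, records[records["sex"] == sex]) for sex in ("female", "male")
    ]
    for group, sub in groups:
        for cls, cls_rows in sub.groupby("class"):
            denom = cls_rows["individual_id"].nunique()
            for direction in ("above", "below"):
                n = int((cls_rows["direction"] == direction).sum())
                out.append(
                    {
                        "group": group,
                        "class": cls,
                        "direction": direction,
                        "n_significant": n,
                        "n_individuals": denom,
                        "percent": 100.0 * n / denom if denom else np.nan,
                    }
                )
    return pd.DataFrame(out)
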