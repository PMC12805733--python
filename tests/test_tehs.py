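"""Time and habitat-selection submodels: conjugate oracles, invariances."""

import numpy as np
import pandas as pd
import pytest

import mosaicmove as mm
from mosaicmove.tehs import PosteriorFit, summarize_draws


def _fit_from_draws(draws_1d: dict) -> PosteriorFit:
    mcmc = mm.MCMCConfig(n_iter=2, n_burn=1, n_chains=1, seed=0)
    draws = {k: np.asarray(v)[None, :] for k, v in draws_1d.items()}
    return PosteriorFit(
        draws=draws,
        covariates=tuple(
            k.split("[")[1][:-1] for k in draws_1d if "[" in k
        ),
        summary=summarize_draws(draws, mcmc),
        mcmc=mcmc,
    )


# -- time submodel -----------------------------------------------------------

def test_posterior_matches_conjugate_closed_form_known_sigma():
    """With sigma known the posterior is exactly multivariate normal."""
    rng = np.random.default_rng(2)
    n, sigma = 50, 0.3
    d = np.exp(rng.normal(4, 1, n))
    p = rng.dirichlet(np.ones(3), n)[:, :2]
    x = np.column_stack([np.ones(n), np.log(d), p])
    truth = np.array([1.0, 0.2, 0.5, -0.3])
    t = np.exp(x @ truth + rng.normal(0, sigma, n))
    fit = mm.fit_time_submodel(
        d, t, p, ["forest", "savanna"],
        mm.MCMCConfig(n_iter=6000, n_burn=1000, n_chains=2, seed=1),
        sigma_fixed=sigma,
    )
    prec = x.T @ x / sigma**2 + np.eye(4) / 100.0
    cov = np.linalg.inv(prec)
    mean = cov @ (x.T @ np.log(t)) / sigma**2
    names = ["beta0", "gamma", "beta[forest]", "beta[savanna]"]
    for j, name in enumerate(names):
        draws = fit.stacked(name)
        assert abs(draws.mean() - mean[j]) < 4 * np.sqrt(cov[j, j] / 200)
        assert draws.var(ddof=1) == pytest.approx(cov[j, j], rel=0.2)


def test_time_recovery_at_five_thousand_steps():
    df = mm.simulate_time_steps(5000, rng=np.random.default_rng(5))
    covars = ["forest", "savanna", "wetland", "eucalyptus", "mosaic"]
    fit = mm.fit_time_submodel(
        df["d"].to_numpy(), df["t_min"].to_numpy(), df[covars].to_numpy(), covars,
        mm.MCMCConfig(n_iter=1500, n_burn=500, n_chains=2, seed=3),
    )
    s = fit.summary["mean"]
    assert abs(s["beta0"] - 1.0) < 0.1
    assert abs(s["gamma"] - 0.2) < 0.1
    assert abs(s["beta[forest]"] - 0.5) < 0.1
    assert abs(s["sigma"] - 0.3) < 0.1


def test_time_scale_shift_moves_only_intercept():
    """Multiplying all durations by c shifts beta0 by log c, nothing else."""
    df = mm.simulate_time_steps(800, rng=np.random.default_rng(8))
    covars = ["forest", "savanna", "wetland", "eucalyptus", "mosaic"]
    mcmc = mm.MCMCConfig(n_iter=1500, n_burn=500, n_chains=1, seed=4)
    args = (df["d"].to_numpy(), df[covars].to_numpy(), covars, mcmc)
    f1 = mm.fit_time_submodel(args[0], df["t_min"].to_numpy(), *args[1:])
    c = 3.0
    f2 = mm.fit_time_submodel(args[0], c * df["t_min"].to_numpy(), *args[1:])
    assert f2.summary["mean"]["beta0"] - f1.summary["mean"]["beta0"] == pytest.approx(
        np.log(c), abs=0.05
    )
    for name in ["gamma", "sigma"] + [f"beta[{x}]" for x in covars]:
        assert f2.summary["mean"][name] == pytest.approx(
            f1.summary["mean"][name], abs=0.05
        )


def test_zero_variance_covariate_dropped_with_warning():
    df = mm.simulate_time_steps(200, rng=np.random.default_rng(1))
    p = df[["forest"]].to_numpy()
    p = np.column_stack([p, np.zeros(len(p))])
    with pytest.warns(UserWarning, match="zero variance"):
        fit = mm.fit_time_submodel(
            df["d"].to_numpy(), df["t_min"].to_numpy(), p, ["forest", "ghost"],
            mm.MCMCConfig(n_iter=200, n_burn=100, n_chains=1, seed=0),
        )
    assert fit.covariates == ("forest",)


def test_prior_predictive_time_submodel():
    """With no data the posterior is the prior (sampler correctness smoke)."""
    fit = mm.fit_time_submodel(
        np.empty(0), np.empty(0), np.empty((0, 1)), ["forest"],
        mm.MCMCConfig(n_iter=6000, n_burn=2000, n_chains=2, seed=6),
    )
    b = fit.stacked("beta0")
    assert abs(b.mean()) < 1.0 and b.std() == pytest.approx(10.0, rel=0.15)
    s = fit.stacked("sigma")
    # Half-Normal(0, 5): mean 5*sqrt(2/pi) ~ 3.99
    assert s.mean() == pytest.approx(5 * np.sqrt(2 / np.pi), rel=0.25)


# -- ratios ------------------------------------------------------------------

def test_time_ratio_identity_and_transform_oracle():
    rng = np.random.default_rng(0)
    draws = {"beta0": rng.normal(size=100), "beta[forest]": rng.normal(0.4, 0.05, 100)}
    fit = _fit_from_draws(draws)
    same = mm.time_ratio(fit, "forest", "forest")
    assert same.mean == 1.0 and same.direction is None
    tr = mm.time_ratio(fit, "forest")  # vs pasture baseline (coef 0)
    assert np.allclose(tr.draws, np.exp(draws["beta[forest]"]))
    assert tr.direction == "above"  # ratio > 1 = slower in forest


def test_odds_ratio_null_and_baseline():
    fit = _fit_from_draws({"alpha[forest]": np.zeros(50)})
    orr = mm.odds_ratio(fit, "forest")
    assert np.all(orr.draws == 1.0) and orr.direction is None
    base = mm.odds_ratio(fit, "pasture")
    assert base.mean == 1.0 and base.direction is None


# -- selection submodel ------------------------------------------------------

def test_null_coefficients_give_uniform_choice_probability():
    x, chosen = mm.simulate_choice_sets(40, np.zeros(3), np.random.default_rng(0))
    ll = mm.selection_loglik(np.zeros(3), x, chosen)
    assert ll == pytest.approx(40 * np.log(1 / 5), abs=1e-12)


def test_map_matches_grid_search_oracle():
    """Posterior mode under a near-flat prior equals the brute-force
    grid-search maximizer of the conditional-logit likelihood (20 sets)."""
    x, chosen = mm.simulate_choice_sets(20, np.array([1.0, -0.5]), np.random.default_rng(6))
    est = mm.selection_map(x, chosen, prior_sd=1000.0)
    # coarse-to-fine grid at final resolution 0.01
    centre = np.zeros(2)
    for res, half in ((0.1, 3.0), (0.01, 0.15)):
        g = np.arange(-half, half + res / 2, res)
        aa, bb = np.meshgrid(centre[0] + g, centre[1] + g, indexing="ij")
        grid = np.column_stack([aa.ravel(), bb.ravel()])
        util = np.einsum("nck,gk->gnc", x, grid)
        ll = util[:, np.arange(20), chosen].sum(axis=1) - (
            np.log(np.exp(util - util.max(axis=2, keepdims=True)).sum(axis=2))
            + util.max(axis=2)
        ).sum(axis=1)
        centre = grid[np.argmax(ll)]
    assert np.all(np.abs(est - centre) <= 0.015)


def test_location_invariance_of_conditional_logit():
    """Adding a candidate-constant covariate leaves the likelihood flat in
    its coefficient (within-set location invariance)."""
    x, chosen = mm.simulate_choice_sets(30, np.array([0.7, 0.1]), np.random.default_rng(3))
    ones = np.ones((30, 5, 1))
    x_aug = np.concatenate([x, ones], axis=2)
    base = mm.selection_loglik(np.array([0.7, 0.1, 0.0]), x_aug, chosen)
    for gamma in (-5.0, 1.3, 42.0):
        assert mm.selection_loglik(
            np.array([0.7, 0.1, gamma]), x_aug, chosen
        ) == pytest.approx(base, abs=1e-9)


def test_selection_recovery_at_two_thousand_sets():
    truth = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    x, chosen = mm.simulate_choice_sets(2000, truth, np.random.default_rng(9))
    covars = ["forest", "savanna", "wetland", "eucalyptus", "mosaic"]
    fit = mm.fit_selection_submodel(
        x, chosen, covars, mm.MCMCConfig(n_iter=2500, n_burn=500, n_chains=2, seed=2)
    )
    assert abs(fit.summary["mean"]["alpha[forest]"] - 1.0) < 0.2


def test_prior_predictive_selection_submodel():
    fit = mm.fit_selection_submodel(
        np.empty((0, 5, 2)), np.empty(0, dtype=int), ["forest", "savanna"],
        mm.MCMCConfig(n_iter=12000, n_burn=4000, n_chains=2, seed=5),
    )
    a = fit.stacked("alpha[forest]")
    assert abs(a.mean()) < 1.5
    assert a.std() == pytest.approx(10.0, rel=0.3)


# -- tallies -----------------------------------------------------------------

def test_tally_all_individuals_selecting():
    rec = pd.DataFrame(
        {
            "individual_id": ["a", "b", "c"],
            "sex": ["female", "male", "female"],
            "class": "forest",
            "direction": "above",
        }
    )
    tally = mm.tally_population(rec)
    row = tally[(tally["group"] == "all") & (tally["direction"] == "above")].iloc[0]
    assert row["n_significant"] == 3 and row["percent"] == 100.0


def test_tally_matches_hand_enumeration():
    rec = pd.DataFrame(
        [
            ("a", "female", "forest", "above"),
            ("b", "male", "forest", None),
            ("c", "female", "forest", "below"),
            ("a", "female", "savanna", "above"),
            ("c", "female", "savanna", "above"),
        ],
        columns=["individual_id", "sex", "class", "direction"],
    )
    tally = mm.tally_population(rec).set_index(["group", "class", "direction"])
    assert tally.loc[("all", "forest", "above"), "n_significant"] == 1
    assert tally.loc[("all", "forest", "below"), "n_significant"] == 1
    assert tally.loc[("all", "forest", "above"), "n_individuals"] == 3
    assert tally.loc[("female", "savanna", "above"), "n_significant"] == 2
    assert tally.loc[("female", "savanna", "above"), "percent"] == 100.0
    assert tally.loc[("male", "forest", "above"), "n_significant"] == 0
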