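"""Two-state behavioural HMM with categorical emissions, fit by Gibbs/FFBS.

Each retained step is summarized by a step-length bin (eight bins with
breakpoints 0, 30, 60, 90, 120, 150, 180, 210, 512 m; 512 m is the 99.9th
percentile of step length, longer steps are clamped into the last bin) and
a turning-angle bin (eight equal-width bins on [-pi, pi], missing at burst
starts and zero-length segments).  A hidden two-state Markov chain
(resting / active) emits the two bins independently given the state, each
from its own categorical distribution — a nonparametric alternative to
gamma / von Mises step-and-turn models.

The sampler alternates
(a) an exact forward-filter backward-sample draw of the latent states per
    burst (a burst is a maximal run of contiguous retained steps), and
(b) conjugate Dirichlet(1,...,1) updates of the initial distribution, the
    transition matrix rows and the per-state emission rows given state
    counts.

Label switching is resolved deterministically: at every stored iteration
"resting" is the state with the smaller expected step-length bin index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .landscape import ConfigurationError
from .preprocess import retained_mask

RESTING, ACTIVE = 0, 1


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin definitions for step lengths and turning angles.

    Step bins are half-open [lo, hi) except the last, which is closed at
    the upper break; lengths beyond it are clamped into the last bin.
    Angle bin j covers [-pi + j*pi/4, -pi + (j+1)*pi/4) with +pi included
    in the last bin.
    """

    step_breaks: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 512.0)
    n_angle_bins: int = 8

    def __post_init__(self) -> None:
        if list(self.step_breaks) != sorted(set(self.step_breaks)):
            raise ConfigurationError("step_breaks must be strictly increasing")

    @property
    def n_step_bins(self) -> int:
        return len(self.step_breaks) - 1

    def step_bin(self, d: np.ndarray) -> np.ndarray:
        """0-based step-length bin, overflow clamped into the last bin."""
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(self.step_breaks, d, side="right") - 1
        return np.clip(idx, 0, self.n_step_bins - 1)

    def angle_bin(self, theta: np.ndarray) -> np.ndarray:
        """0-based angle bin; NaN angles map to -1 (missing)."""
        theta = np.asarray(theta, dtype=float)
        width = 2 * np.pi / self.n_angle_bins
        idx = np.floor((theta + np.pi) / width).astype(float)
        idx = np.clip(idx, 0, self.n_angle_bins - 1)
        return np.where(np.isnan(theta), -1, idx).astype(int)


@dataclass
class Burst:
    """A maximal run of contiguous retained steps of one individual."""

    individual_id: str
    step_ids: list[str]
    step_bin: np.ndarray
    angle_bin: np.ndarray  # -1 encodes a missing turning angle

    def __len__(self) -> int:
        return len(self.step_ids)


def discretize(
    steps: pd.DataFrame,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    nominal_interval_min: float | None = None,
) -> list[Burst]:
    """Split retained steps into bursts and discretize them.

    A burst breaks wherever a step was removed by a cleaning rule, the fix
    chain is non-contiguous, or (when ``nominal_interval_min`` is given)
    the step duration departs from the nominal fix interval by more than
    half a minute.
    """
    if (steps["d"] < 0).any():
        raise ValueError("negative step length encountered")
    bursts: list[Burst] = []
    for ind, grp in steps.groupby("individual_id", sort=False):
        grp = grp.sort_values("fix_index")
        kept = grp[retained_mask(grp)]
        if kept.empty:
            continue
        fix_idx = kept["fix_index"].to_numpy()
        t_min = kept["t_min"].to_numpy()
        breaks = np.ones(len(kept), dtype=bool)
        breaks[1:] = fix_idx[1:] != fix_idx[:-1] + 1
        if nominal_interval_min is not None:
            breaks |= np.abs(t_min - nominal_interval_min) > 0.5
        burst_id = np.cumsum(breaks)
        for _, sub in kept.groupby(burst_id):
            angle_bin = scheme.angle_bin(sub["theta"].to_numpy())
            angle_bin[0] = -1  # burst start: previous heading unavailable
            bursts.append(
                Burst(
                    individual_id=str(ind),
                    step_ids=list(sub["step_id"]),
                    step_bin=scheme.step_bin(sub["d"].to_numpy()),
                    angle_bin=angle_bin,
                )
            )
    return bursts


# ---------------------------------------------------------------------------
# Core recursions
# ---------------------------------------------------------------------------

def _emission_matrix(
    burst: Burst, lam_step: np.ndarray, lam_angle: np.ndarray
) -> np.ndarray:
    """(T, 2) per-step emission probabilities; missing angles contribute 1."""
    b = lam_step[:, burst.step_bin].T.copy()
    has_angle = burst.angle_bin >= 0
    b[has_angle] *= lam_angle[:, burst.angle_bin[has_angle]].T
    return np.maximum(b, 1e-300)


def forward_backward(
    b: np.ndarray, pi: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, float]:
    """Smoothed state marginals and log-likelihood for one burst.

    ``b`` is the (T, 2) emission-probability matrix.
    """
    t_len = b.shape[0]
    alpha = np.empty((t_len, 2))
    c = np.empty(t_len)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ phi) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.ones(2)
    gamma = np.empty((t_len, 2))
    gamma[-1] = alpha[-1]
    for t in range(t_len - 2, -1, -1):
        beta = phi @ (b[t + 1] * beta)
        beta /= beta.max()
        g = alpha[t] * beta
        gamma[t] = g / g.sum()
    return gamma, float(np.log(c).sum())


def ffbs(
    b: np.ndarray, pi: np.ndarray, phi: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Forward-filter backward-sample draw of the latent state path."""
    t_len = b.shape[0]
    alpha = np.empty((t_len, 2))
    c = np.empty(t_len)
    a = pi * b[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, t_len):
        a = (alpha[t - 1] @ phi) * b[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    z = np.empty(t_len, dtype=np.int8)
    u = rng.random(t_len)
    p1 = alpha[-1, 1]
    z[-1] = u[-1] < p1
    for t in range(t_len - 2, -1, -1):
        w = alpha[t] * phi[:, z[t + 1]]
        p1 = w[1] / (w[0] + w[1])
        z[t] = u[t] < p1
    return z, float(np.log(c).sum())


def _label_permutation(lam_step: np.ndarray) -> np.ndarray:
    """State order making 'resting' the smaller-expected-step-bin state.

    Exact tie: identity (state 0 stays resting), the documented tie-break.
    """
    bins = np.arange(lam_step.shape[1])
    expected = lam_step @ bins
    if expected[1] < expected[0]:
        return np.array([1, 0])
    return np.array([0, 1])


def label_states(draws: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Relabel every stored iteration so resting/active order is canonical.

    Operates on a draws dict with keys ``pi`` (n, 2), ``Phi`` (n, 2, 2),
    ``lam_step`` (n, 2, B), ``lam_angle`` (n, 2, B).  Idempotent, and
    invariant to permuting state indices of any input iteration.
    """
    out = {k: v.copy() for k, v in draws.items()}
    for i in range(out["lam_step"].shape[0]):
        perm = _label_permutation(out["lam_step"][i])
        out["pi"][i] = out["pi"][i][perm]
        out["Phi"][i] = out["Phi"][i][np.ix_(perm, perm)]
        out["lam_step"][i] = out["lam_step"][i][perm]
        out["lam_angle"][i] = out["lam_angle"][i][perm]
    return out


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

@dataclass
class HMMFit:
    """Posterior draws, likelihood trace and state probabilities."""

    draws: dict[str, np.ndarray]  # labeled, post-burn-in
    loglik_trace: np.ndarray  # every iteration, including burn-in
    state_probs: pd.DataFrame  # step_id, burst, p_active_sampled
    n_iter: int
    n_burn: int
    seed: int

    @property
    def posterior_means(self) -> dict[str, np.ndarray]:
        return {k: v.mean(axis=0) for k, v in self.draws.items()}


def fit_hmm_gibbs(
    bursts: Sequence[Burst],
    n_iter: int = 1000,
    n_burn: int = 500,
    prior_concentration: float = 1.0,
    seed: int = 0,
    scheme: DiscretizationScheme = DiscretizationScheme(),
    fixed_states: Sequence[np.ndarray] | None = None,
) -> HMMFit:
    """Gibbs sampler alternating FFBS state draws and Dirichlet updates.

    ``fixed_states`` is a test hook: when given, latent states are held at
    the supplied per-burst sequences and only the conjugate parameter
    updates run, exposing the closed-form Dirichlet posteriors.

    The per-iteration log-likelihood (given the current parameters) is
    recorded for trace inspection and a Geweke diagnostic.
    """
    bursts = [b for b in bursts if len(b) >= 1]
    if not bursts or not any(len(b) >= 2 for b in bursts):
        raise ValueError("need at least one burst of length >= 2")
    n_sbin = scheme.n_step_bins
    n_abin = scheme.n_angle_bins
    all_bins = np.concatenate([b.step_bin for b in bursts])
    if np.unique(all_bins).size == 1:
        warnings.warn("all observations fall in a single step bin; states weakly identified")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    pi = rng.dirichlet(np.ones(2))
    phi = np.vstack([rng.dirichlet(np.ones(2)) for _ in range(2)])
    lam_step = np.vstack([rng.dirichlet(np.ones(n_sbin))[None] for _ in range(2)]).reshape(2, n_sbin)
    lam_angle = np.vstack([rng.dirichlet(np.ones(n_abin))[None] for _ in range(2)]).reshape(2, n_abin)

    n_kept = n_iter - n_burn
    kept = {
        "pi": np.empty((n_kept, 2)),
        "Phi": np.empty((n_kept, 2, 2)),
        "lam_step": np.empty((n_kept, 2, n_sbin)),
        "lam_angle": np.empty((n_kept, 2, n_abin)),
    }
    loglik_trace = np.empty(n_iter)
    n_total = sum(len(b) for b in bursts)
    active_count = np.zeros(n_total)

    for it in range(n_iter):
        init_counts = np.zeros(2)
        trans_counts = np.zeros((2, 2))
        step_counts = np.zeros((2, n_sbin))
        angle_counts = np.zeros((2, n_abin))
        ll = 0.0
        states_iter: list[np.ndarray] = []
        for bi, burst in enumerate(bursts):
            if fixed_states is not None:
                z = np.asarray(fixed_states[bi], dtype=np.int8)
                b_mat = _emission_matrix(burst, lam_step, lam_angle)
                _, burst_ll = forward_backward(b_mat, pi, phi)
            else:
                b_mat = _emission_matrix(burst, lam_step, lam_angle)
                z, burst_ll = ffbs(b_mat, pi, phi, rng)
            ll += burst_ll
            states_iter.append(z)
            init_counts[z[0]] += 1
            np.add.at(trans_counts, (z[:-1], z[1:]), 1)
            np.add.at(step_counts, (z, burst.step_bin), 1)
            has_angle = burst.angle_bin >= 0
            np.add.at(angle_counts, (z[has_angle], burst.angle_bin[has_angle]), 1)
        loglik_trace[it] = ll

        pi = rng.dirichlet(prior_concentration + init_counts)
        phi = np.vstack(
            [rng.dirichlet(prior_concentration + trans_counts[s]) for s in range(2)]
        )
        lam_step = np.vstack(
            [rng.dirichlet(prior_concentration + step_counts[s]) for s in range(2)]
        )
        lam_angle = np.vstack(
            [rng.dirichlet(prior_concentration + angle_counts[s]) for s in range(2)]
        )

        if it >= n_burn:
            i = it - n_burn
            perm = _label_permutation(lam_step)
            kept["pi"][i] = pi[perm]
            kept["Phi"][i] = phi[np.ix_(perm, perm)]
            kept["lam_step"][i] = lam_step[perm]
            kept["lam_angle"][i] = lam_angle[perm]
            # Under the relabelling, 'active' is whichever sampled state maps
            # to index 1; perm[s] gives the canonical index of raw state s.
            inv = np.argsort(perm)
            z_all = np.concatenate([inv[z] for z in states_iter])
            active_count += z_all == ACTIVE

    step_ids = [sid for b in bursts for sid in b.step_ids]
    burst_ids = np.concatenate(
        [np.full(len(b), i) for i, b in enumerate(bursts)]
    )
    state_probs = pd.DataFrame(
        {
            "step_id": step_ids,
            "burst": burst_ids,
            "p_active_sampled": active_count / n_kept,
        }
    )
    return HMMFit(
        draws=kept,
        loglik_trace=loglik_trace,
        state_probs=state_probs,
        n_iter=n_iter,
        n_burn=n_burn,
        seed=seed,
    )


def decode(
    bursts: Sequence[Burst],
    pi: np.ndarray,
    phi: np.ndarray,
    lam_step: np.ndarray,
    lam_angle: np.ndarray,
) -> pd.DataFrame:
    """Smoothed P(active) and modal state per step at fixed parameters.

    Typically called at the labeled posterior means; complements the
    per-iteration sampled-state average stored by the Gibbs fit.
    """
    rows = []
    for i, burst in enumerate(bursts):
        b = _emission_matrix(burst, np.asarray(lam_step), np.asarray(lam_angle))
        gamma, _ = forward_backward(b, np.asarray(pi), np.asarray(phi))
        for sid, p_active in zip(burst.step_ids, gamma[:, ACTIVE]):
            rows.append({"step_id": sid, "burst": i, "p_active": float(p_active)})
    df = pd.DataFrame(rows)
    df["modal_state"] = np.where(df["p_active"] >= 0.5, "active", "resting")
    return df


def geweke_z(trace: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early and late trace segments.

    Standard errors use batch means to absorb autocorrelation.
    """
    trace = np.asarray(trace, dtype=float)
    a = trace[: int(first * len(trace))]
    b = trace[int((1 - last) * len(trace)) :]

    def batch_se(x: np.ndarray, n_batches: int = 20) -> float:
        n_batches = min(n_batches, max(2, len(x) // 2))
        batches = np.array_split(x, n_batches)
        means = np.array([bb.mean() for bb in batches])
        return float(means.std(ddof=1) / np.sqrt(len(means)))

    return float((a.mean() - b.mean()) / np.hypot(batch_se(a), batch_se(b)))
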