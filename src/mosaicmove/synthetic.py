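"""Synthetic landscapes and telemetry with known ground truth.

Every downstream stage (cleaning rules, buffered-path extraction, the
traversal-time and habitat-selection submodels, the behavioural-state HMM,
diel summaries) is verified by parameter recovery on data generated here,
so the generative structure deliberately matches the fitted models:

* a latent two-state (resting/active) Markov chain drives step lengths
  drawn from state-specific length-bin distributions;
* the heading of each step is chosen among K evenly spaced candidates with
  probability proportional to ``exp(alpha . p)`` where ``p`` is the
  buffered land-cover composition of the candidate path (alpha = 0 while
  resting) — K defaults to 8, deliberately finer than the four cardinal
  alternatives the fitted choice model uses;
* a ground-truth traversal time ``log t = b0 + g*log d + sum_k b_k p_k +
  N(0, s)`` is recorded per step alongside the nominal fix interval;
* GPS defects (missing fixes, outlier jumps, duplicated coordinates) are
  injected afterwards with exact labels, so filter precision/recall is
  computable.

All randomness derives from one seed through named sub-streams
(`substream`), so any draw can be reproduced independently by an oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .landscape import (
    BASELINE_CLASS,
    CLASS_ORDER,
    ConfigurationError,
    LandscapeRaster,
    generate_landscape,
)
from .lulc import buffer_proportions
from .preprocess import Trajectory, write_movebank_csv

# Named RNG sub-stream purposes (spawn-key component 0).
STREAM_LANDSCAPE = 0
STREAM_TRAJECTORY = 1
STREAM_ARTIFACTS = 2


def substream(seed: int, purpose: int, index: int = 0) -> np.random.Generator:
    """Deterministic named sub-stream: ``SeedSequence(seed, spawn_key=(purpose, index))``.

    Oracles re-create any simulator draw by requesting the same stream.
    """
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(purpose, index))
    )


# ---------------------------------------------------------------------------
# Ground-truth parameter defaults (the simulated study conditions)
# ---------------------------------------------------------------------------

#: Step-length bin edges shared with the HMM discretization.
STEP_BREAKS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 512.0)

DEFAULT_TIME_PARAMS: dict = {
    "beta0": 1.0,
    "gamma": 0.2,
    "sigma": 0.3,
    # Slower traversal (positive log-time effect) in native classes,
    # relative to the pasture baseline.
    "beta": {"forest": 0.5, "savanna": 0.4, "wetland": 0.4, "eucalyptus": 0.2, "mosaic": 0.1},
}

DEFAULT_SELECTION_PARAMS: dict = {
    # Log-odds of choosing a pure-class path over a pure-pasture path.
    "alpha": {"forest": 1.0, "savanna": 0.8, "wetland": 0.6, "eucalyptus": 0.3, "mosaic": 0.1}
}

DEFAULT_HMM_PARAMS: dict = {
    "pi": [0.5, 0.5],  # state 0 = resting, state 1 = active
    "Phi": [[0.9, 0.1], [0.1, 0.9]],
    # Resting: short steps (bins 1-2).  Active: longer steps (bins 4-8).
    "lam_step": [
        [0.65, 0.30, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.05, 0.20, 0.25, 0.20, 0.15, 0.15],
    ],
    # Resting: undirected headings.  Active: forward-biased (bins 4-5
    # straddle a zero turning angle).
    "lam_angle": [
        [0.125] * 8,
        [0.05, 0.05, 0.10, 0.25, 0.25, 0.10, 0.10, 0.10],
    ],
}

DEFAULT_LANDSCAPE_PROPORTIONS: dict = {
    "pasture": 0.50,
    "forest": 0.20,
    "savanna": 0.15,
    "wetland": 0.05,
    "eucalyptus": 0.05,
    "mosaic": 0.05,
}


@dataclass
class SimConfig:
    """Simulation configuration with ground-truth parameters.

    Defaults emulate the study conditions: 20-minute fix intervals, a
    pasture-dominated patchy six-class mosaic, preference for native
    classes, slower traversal of native classes, and a persistent
    resting/active switching process, with realistic GPS defect rates.
    """

    n_individuals: int = 6
    sex_split: Mapping[str, int] = field(
        default_factory=lambda: {"female": 3, "male": 3}
    )
    fix_interval_min: float = 20.0
    n_fixes: int = 2000
    true_time_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_TIME_PARAMS)))
    true_selection_params: dict = field(
        default_factory=lambda: json.loads(json.dumps(DEFAULT_SELECTION_PARAMS))
    )
    true_hmm_params: dict = field(default_factory=lambda: json.loads(json.dumps(DEFAULT_HMM_PARAMS)))
    missing_fix_rate: float = 0.05
    outlier_rate: float = 0.002
    zero_step_rate: float = 0.02
    n_headings: int = 8
    buffer_m: float = 30.0
    rng_seed: int = 0
    start_time: str = "2018-01-01T00:00:00Z"
    tz_offset_hours: float = -4.0
    #: Optional habitat/diel modulation of the latent state process:
    #: {"classes": [...], "hour_range": (lo, hi), "boost": p} forces the
    #: resting state with probability p when the animal currently sits in
    #: one of the classes during the local-hour window.  Off by default.
    rest_bias: dict | None = None

    def __post_init__(self) -> None:
        for name in ("missing_fix_rate", "outlier_rate", "zero_step_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1), got {v}")
        if self.n_fixes < 3:
            raise ConfigurationError("n_fixes must be at least 3")
        if self.fix_interval_min <= 0:
            raise ConfigurationError("fix_interval must be positive")
        if self.n_headings < 8:
            raise ConfigurationError("at least 8 candidate headings required")

    def sex_of(self, individual_index: int) -> str:
        n_female = int(self.sex_split.get("female", 0))
        return "female" if individual_index < n_female else "male"

    def individual_id(self, individual_index: int) -> str:
        return f"sim{individual_index:03d}"


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------

def _draw_step_length(rng: np.random.Generator, lam_row: Sequence[float]) -> float:
    """Step length: bin from the categorical, uniform within the bin."""
    b = rng.choice(len(lam_row), p=np.asarray(lam_row, dtype=float))
    lo, hi = STEP_BREAKS[b], STEP_BREAKS[b + 1]
    return float(rng.uniform(lo, hi))


def _reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a coordinate into [lo, hi] (assumes excursion < span)."""
    if v < lo:
        return 2 * lo - v
    if v > hi:
        return 2 * hi - v
    return v


def simulate_trajectory(
    landscape: LandscapeRaster, config: SimConfig, individual_index: int
) -> Trajectory:
    """Simulate one individual's fixed-interval trajectory with ground truth.

    The returned ``Trajectory.truth`` dict holds, per step: the latent
    behavioural state, the drawn ground-truth traversal time, and the
    buffered composition of the chosen path, plus the generating
    parameters.  Timestamps are exactly ``fix_interval_min`` apart; defects
    are injected separately by :func:`inject_artifacts`.
    """
    if landscape.grid.size < 4:
        raise ConfigurationError("landscape too small to simulate movement")
    rng = substream(config.rng_seed, STREAM_TRAJECTORY, individual_index)
    hmm = config.true_hmm_params
    pi = np.asarray(hmm["pi"], dtype=float)
    phi = np.asarray(hmm["Phi"], dtype=float)
    lam_step = np.asarray(hmm["lam_step"], dtype=float)
    tp = config.true_time_params
    covars = list(tp["beta"].keys())
    beta = np.array([tp["beta"][c] for c in covars])
    alpha_map = config.true_selection_params["alpha"]
    class_names = sorted(set(landscape.class_table.values()))
    alpha_full = {c: float(alpha_map.get(c, 0.0)) for c in class_names}

    xmin, ymin, xmax, ymax = landscape.extent
    margin = config.buffer_m + 2 * landscape.cell_size + STEP_BREAKS[-1]
    lo_x, hi_x = xmin + margin, xmax - margin
    lo_y, hi_y = ymin + margin, ymax - margin
    if lo_x >= hi_x or lo_y >= hi_y:
        raise ConfigurationError(
            "landscape too small for the simulated step lengths and buffer"
        )

    n_steps = config.n_fixes - 1
    x = np.empty(config.n_fixes)
    y = np.empty(config.n_fixes)
    x[0] = (lo_x + hi_x) / 2.0
    y[0] = (lo_y + hi_y) / 2.0
    states = np.empty(n_steps, dtype=int)
    t_true = np.empty(n_steps)
    chosen_candidate = np.empty(n_steps, dtype=int)
    comp_rows = []

    start = pd.Timestamp(config.start_time)
    local_hours = (
        (start + pd.to_timedelta(
            np.arange(config.n_fixes) * config.fix_interval_min
            + config.tz_offset_hours * 60.0,
            unit="m",
        )).hour.to_numpy()
    )
    bias = config.rest_bias

    k = config.n_headings
    state = rng.choice(2, p=pi)
    for i in range(n_steps):
        if i > 0:
            state = rng.choice(2, p=phi[state])
        if bias is not None:
            lo_h, hi_h = bias["hour_range"]
            if (
                lo_h <= local_hours[i] < hi_h
                and landscape.class_at(x[i], y[i]) in bias["classes"]
                and rng.random() < bias["boost"]
            ):
                state = 0  # resting
        states[i] = state
        d = _draw_step_length(rng, lam_step[state])
        base = rng.uniform(0.0, 2 * np.pi)
        angles = base + 2 * np.pi * np.arange(k) / k
        ex = np.array([_reflect(x[i] + d * np.cos(a), lo_x, hi_x) for a in angles])
        ey = np.array([_reflect(y[i] + d * np.sin(a), lo_y, hi_y) for a in angles])
        comps = [
            buffer_proportions(((x[i], y[i]), (ex[j], ey[j])), landscape, config.buffer_m)
            for j in range(k)
        ]
        util = np.zeros(k)
        if state == 1:  # selection operates only while active
            for j in range(k):
                util[j] = sum(alpha_full[c] * comps[j].get(c, 0.0) for c in class_names)
        w = np.exp(util - util.max())
        j = rng.choice(k, p=w / w.sum())
        chosen_candidate[i] = j
        x[i + 1], y[i + 1] = ex[j], ey[j]
        p_obs = comps[j]
        comp_rows.append(p_obs)
        eta = (
            tp["beta0"]
            + tp["gamma"] * np.log(max(d, 1e-9))
            + float(beta @ np.array([p_obs.get(c, 0.0) for c in covars]))
        )
        t_true[i] = np.exp(eta + rng.normal(0.0, tp["sigma"]))

    timestamps = start + pd.to_timedelta(
        np.arange(config.n_fixes) * config.fix_interval_min, unit="m"
    )
    fixes = pd.DataFrame({"timestamp": timestamps, "x": x, "y": y})
    truth = {
        "states": states,
        "t_true_min": t_true,
        "chosen_candidate": chosen_candidate,
        "compositions": pd.DataFrame(comp_rows).fillna(0.0),
        "params": {
            "time": tp,
            "selection": config.true_selection_params,
            "hmm": hmm,
        },
    }
    return Trajectory(
        individual_id=config.individual_id(individual_index),
        sex=config.sex_of(individual_index),
        fixes=fixes,
        truth=truth,
    )


def inject_artifacts(traj: Trajectory, config: SimConfig, individual_index: int = 0) -> Trajectory:
    """Inject GPS defects with exact ground-truth labels.

    Three independent Bernoulli label vectors are drawn over the interior
    fixes (first and last fix never touched), in this fixed order from the
    ``STREAM_ARTIFACTS`` sub-stream: missing, outlier, zero.  Then:

    * *missing* fixes are deleted (gaps become multiples of the interval);
    * *outlier* fixes are displaced 2-5 km in a random direction (well
      above the 99.9th percentile of clean step lengths);
    * *zero* fixes copy the coordinates of the preceding surviving fix
      (an outlier label on the same fix wins).

    ``truth["artifacts"]`` records the original fix index of every label.
    """
    n = traj.n_fixes
    rng = substream(config.rng_seed, STREAM_ARTIFACTS, individual_index)
    interior = np.arange(1, n - 1)
    missing = interior[rng.random(interior.size) < config.missing_fix_rate]
    outlier = interior[rng.random(interior.size) < config.outlier_rate]
    zero = interior[rng.random(interior.size) < config.zero_step_rate]
    zero = np.setdiff1d(zero, outlier)
    outlier = np.setdiff1d(outlier, missing)
    zero = np.setdiff1d(zero, missing)

    fixes = traj.fixes.copy()
    keep = np.ones(n, dtype=bool)
    keep[missing] = False
    fixes = fixes[keep].reset_index(drop=True)
    # Map original index -> position among survivors.
    survivors = np.flatnonzero(keep)
    pos = {orig: i for i, orig in enumerate(survivors)}

    x = fixes["x"].to_numpy().copy()
    y = fixes["y"].to_numpy().copy()
    for orig in outlier:
        i = pos[orig]
        ang = rng.uniform(0.0, 2 * np.pi)
        dist = rng.uniform(2000.0, 5000.0)
        x[i] += dist * np.cos(ang)
        y[i] += dist * np.sin(ang)
    for orig in zero:
        i = pos[orig]
        if i > 0:
            x[i], y[i] = x[i - 1], y[i - 1]
    fixes["x"], fixes["y"] = x, y

    truth = dict(traj.truth)
    truth["artifacts"] = {
        "missing": missing.tolist(),
        "outlier": outlier.tolist(),
        "zero": zero.tolist(),
    }
    return Trajectory(
        individual_id=traj.individual_id, sex=traj.sex, fixes=fixes, truth=truth
    )


def simulate_dataset(
    config: SimConfig,
    landscape: LandscapeRaster | None = None,
    *,
    with_artifacts: bool = True,
) -> tuple[LandscapeRaster, list[Trajectory]]:
    """Landscape plus one trajectory per configured individual."""
    if landscape is None:
        landscape = generate_landscape(
            400,
            400,
            DEFAULT_LANDSCAPE_PROPORTIONS,
            patch_scale=10.0,
            rng_seed=substream(config.rng_seed, STREAM_LANDSCAPE),
        )
    trajectories = []
    for i in range(config.n_individuals):
        traj = simulate_trajectory(landscape, config, i)
        if with_artifacts:
            traj = inject_artifacts(traj, config, i)
        trajectories.append(traj)
    return landscape, trajectories


def write_simulation(
    config: SimConfig,
    out_dir: str | Path,
    landscape: LandscapeRaster | None = None,
    with_artifacts: bool = True,
) -> dict:
    """Write telemetry CSV, ASCII landscape, legend and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    landscape, trajectories = simulate_dataset(
        config, landscape, with_artifacts=with_artifacts
    )
    write_movebank_csv(trajectories, out / "tracks.csv")
    landscape.to_ascii_grid(out / "landscape.asc", out / "legend.json")
    truth = {
        "config": {
            "n_individuals": config.n_individuals,
            "fix_interval_min": config.fix_interval_min,
            "n_fixes": config.n_fixes,
            "rng_seed": config.rng_seed,
            "rates": {
                "missing": config.missing_fix_rate,
                "outlier": config.outlier_rate,
                "zero": config.zero_step_rate,
            },
        },
        "params": {
            "time": config.true_time_params,
            "selection": config.true_selection_params,
            "hmm": config.true_hmm_params,
        },
        "individuals": {
            t.individual_id: {
                "sex": t.sex,
                "artifacts": t.truth.get("artifacts", {}),
                "states": t.truth["states"].tolist(),
            }
            for t in trajectories
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# Direct model-level simulators (for recovery and coverage studies)
# ---------------------------------------------------------------------------

def simulate_choice_sets(
    n: int,
    alpha: np.ndarray,
    rng: np.random.Generator,
    n_candidates: int = 5,
    concentration: float = 0.3,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw conditional-choice data directly from the discrete-choice model.

    Candidate covariates are Dirichlet compositions over ``len(alpha) + 1``
    classes with the baseline column dropped; the default concentration
    (0.3) makes compositions cluster near single classes, as 30 m buffered
    paths in a patchy mosaic do.  The chosen index follows the
    conditional-logit probabilities under ``alpha``.  Returns
    ``(X, chosen)`` with X of shape (n, n_candidates, len(alpha)).
    """
    alpha = np.asarray(alpha, dtype=float)
    k = alpha.size
    comp = rng.dirichlet(np.full(k + 1, concentration), size=(n, n_candidates))
    x = comp[:, :, :k]
    util = x @ alpha
    w = np.exp(util - util.max(axis=1, keepdims=True))
    p = w / w.sum(axis=1, keepdims=True)
    u = rng.random(n)
    chosen = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return x, chosen


def simulate_time_steps(
    n: int,
    params: Mapping | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw traversal-time data directly from the log-normal time model."""
    params = dict(DEFAULT_TIME_PARAMS if params is None else params)
    rng = np.random.default_rng(0) if rng is None else rng
    covars = list(params["beta"].keys())
    beta = np.array([params["beta"][c] for c in covars])
    d = np.exp(rng.normal(np.log(100.0), 1.0, size=n))
    p = rng.dirichlet(np.ones(len(covars) + 1), size=n)[:, : len(covars)]
    eta = params["beta0"] + params["gamma"] * np.log(d) + p @ beta
    t = np.exp(eta + rng.normal(0.0, params["sigma"], size=n))
    df = pd.DataFrame({"d": d, "t_min": t})
    for j, c in enumerate(covars):
        df[c] = p[:, j]
    return df
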