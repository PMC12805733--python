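"""Diel resting-pattern summaries by land-cover class, and the pipeline driver.

Each retained step gets a land-cover label (the dominant class of its
buffered path), a two-hour diel bin from its local start time, and a
behavioural state from the HMM; the cross-tabulated proportion of resting
steps per (class, hour-bin) cell describes how the landscape shapes the
diel activity rhythm.  ``run_pipeline`` chains every stage — simulate
(optional), preprocess, extract land cover, fit the two TEHS submodels,
fit the HMM, report — behind one config file and writes a reproducibility
manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .landscape import CLASS_ORDER, LandscapeRaster
from .lulc import (
    RetainedClassSet,
    extract_step_compositions,
    prune_rare_classes,
    renormalize_compositions,
)
from .preprocess import (
    DEFAULT_TZ_OFFSET_HOURS,
    build_step_table,
    filter_summary,
    floor_zero_steps,
    preprocess_steps,
    read_tracks,
    retained_mask,
)
from . import hmm as hmm_mod
from . import synthetic as synth_mod
from . import tehs as tehs_mod

#: Twelve two-hour diel bins partitioning the 24-hour day.
DIEL_BIN_LABELS: tuple[str, ...] = tuple(
    f"[{2 * k:02d}-{2 * k + 2:02d})" for k in range(12)
)


def assign_step_lulc(composition: Mapping[str, float]) -> str:
    """Dominant-class label of a path composition.

    Ties are broken by the canonical class order (forest, savanna,
    wetland, eucalyptus, mosaic, pasture).
    """
    items = [(c, composition[c]) for c in CLASS_ORDER if c in composition]
    items += [(c, v) for c, v in composition.items() if c not in CLASS_ORDER]
    if not items:
        raise ValueError("empty composition")
    best = max(v for _, v in items)
    for c, v in items:
        if v == best:
            return c
    raise AssertionError("unreachable")


def diel_bin(hour: int | np.ndarray) -> np.ndarray | str:
    """Two-hour diel bin label for a local clock hour (0-23)."""
    idx = np.asarray(hour, dtype=int) // 2
    if np.any((idx < 0) | (idx > 11)):
        raise ValueError("hour must be in 0..23")
    labels = np.asarray(DIEL_BIN_LABELS, dtype=object)[idx]
    return labels if isinstance(hour, (np.ndarray, pd.Series, list)) else str(labels)


def resting_proportion(
    step_states: pd.DataFrame,
    min_support: int = 20,
    classes: Sequence[str] = CLASS_ORDER,
) -> pd.DataFrame:
    """Diel table: proportion of resting steps per (class, hour bin).

    ``step_states`` needs columns ``lulc_class``, ``hour_bin``,
    ``modal_state`` ("resting"/"active") and optionally ``p_active`` for a
    probability-weighted variant.  Steps are pooled (every step weighs
    equally); the full classes x 12-bins grid is returned with explicit
    ``n`` per cell, and cells with fewer than ``min_support`` steps are
    flagged low-support.
    """
    df = step_states.copy()
    df["resting"] = (df["modal_state"] == "resting").astype(float)
    grouped = df.groupby(["lulc_class", "hour_bin"], sort=False)
    agg = grouped.agg(
        n=("resting", "size"),
        prop_resting=("resting", "mean"),
    )
    if "p_active" in df.columns:
        agg["prop_resting_weighted"] = 1.0 - grouped["p_active"].mean()
    grid = pd.MultiIndex.from_product(
        [list(classes), list(DIEL_BIN_LABELS)], names=["lulc_class", "hour_bin"]
    )
    out = agg.reindex(grid)
    out["n"] = out["n"].fillna(0).astype(int)
    out["low_support"] = out["n"] < min_support
    return out.reset_index()


def plot_diel_curves(diel: pd.DataFrame, path: str | Path) -> None:
    """Line plot of resting proportion by hour bin, one line per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for cls, sub in diel.groupby("lulc_class", sort=False):
        sub = sub.set_index("hour_bin").reindex(list(DIEL_BIN_LABELS))
        ax.plot(range(12), sub["prop_resting"], marker="o", label=str(cls))
    ax.set_xticks(range(12), DIEL_BIN_LABELS, rotation=45, fontsize=7)
    ax.set_xlabel("local time bin")
    ax.set_ylabel("proportion resting")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, ncols=3)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Per-individual model fitting (shared by the pipeline and the CLI)
# ---------------------------------------------------------------------------

def fit_tehs_per_individual(
    kept_steps: pd.DataFrame,
    comps: pd.DataFrame,
    retained_set: RetainedClassSet,
    mcmc: "tehs_mod.MCMCConfig",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit both TEHS submodels separately for every individual.

    Returns (ratio records, posterior summaries): one ratio row per
    individual x submodel x non-baseline class with its 95% CI verdict,
    ready for :func:`mosaicmove.tehs.tally_population`.
    """
    covars = list(retained_set.covariates)
    records: list[dict] = []
    summaries: list[pd.DataFrame] = []
    for ind, grp in kept_steps.groupby("individual_id"):
        obs = comps[
            (comps["individual_id"] == ind) & (comps["candidate"] == "observed")
        ].set_index("step_id")
        time_steps = floor_zero_steps(grp)
        time_steps = time_steps[time_steps["step_id"].isin(obs.index)]
        p = obs.loc[time_steps["step_id"], covars].to_numpy()
        tfit = tehs_mod.fit_time_submodel(
            time_steps["d"].to_numpy(), time_steps["t_min"].to_numpy(), p, covars, mcmc
        )
        sel_sets = comps[(comps["individual_id"] == ind) & comps["valid_choice_set"]]
        x, chosen = choice_arrays(sel_sets, covars)
        sfit = tehs_mod.fit_selection_submodel(x, chosen, covars, mcmc)
        sex = grp["sex"].iloc[0] if "sex" in grp.columns else "unknown"
        for cls in covars:
            if cls in tfit.covariates:
                tr = tehs_mod.time_ratio(tfit, cls)
                records.append(
                    {
                        "individual_id": ind, "sex": sex, "model": "time",
                        "class": cls, "direction": tr.direction,
                        "ratio_mean": tr.mean, "q2.5": tr.q2_5, "q97.5": tr.q97_5,
                    }
                )
            orr = tehs_mod.odds_ratio(sfit, cls)
            records.append(
                {
                    "individual_id": ind, "sex": sex, "model": "selection",
                    "class": cls, "direction": orr.direction,
                    "ratio_mean": orr.mean, "q2.5": orr.q2_5, "q97.5": orr.q97_5,
                }
            )
        for label, fit in (("time", tfit), ("selection", sfit)):
            s = fit.summary.reset_index()
            s.insert(0, "individual_id", ind)
            s.insert(1, "model", label)
            summaries.append(s)
    return pd.DataFrame(records), pd.concat(summaries, ignore_index=True)


def fit_hmm_per_individual(
    steps: pd.DataFrame, n_iter: int = 1000, n_burn: int = 500, seed: int = 0
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Fit the two-state HMM per individual and decode states.

    Returns the per-step state table (sampled-state and smoothed P(active),
    modal label, Geweke z of the likelihood trace) and the per-individual
    log-likelihood traces.
    """
    state_frames = []
    traces: dict[str, np.ndarray] = {}
    for ind, grp in steps.groupby("individual_id"):
        bursts = hmm_mod.discretize(grp)
        fit = hmm_mod.fit_hmm_gibbs(bursts, n_iter=n_iter, n_burn=n_burn, seed=seed)
        means = fit.posterior_means
        dec = hmm_mod.decode(
            bursts, means["pi"], means["Phi"], means["lam_step"], means["lam_angle"]
        )
        dec = dec.merge(fit.state_probs, on=["step_id", "burst"])
        dec.insert(0, "individual_id", ind)
        dec["geweke_z"] = hmm_mod.geweke_z(fit.loglik_trace[fit.n_burn :])
        state_frames.append(dec)
        traces[str(ind)] = fit.loglik_trace
    return pd.concat(state_frames, ignore_index=True), traces


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": None,  # SimConfig kwargs, or None to read inputs
    "inputs": {"tracks": None, "landscape": None, "legend": None},
    "preprocess": {
        "quantile": 0.99,
        "max_gap_min": 60.0,
        "tz_offset_hours": DEFAULT_TZ_OFFSET_HOURS,
    },
    "lulc": {"buffer_m": 30.0, "prune_threshold": 0.10},
    "tehs": {"n_iter": 4000, "n_burn": 2000, "n_chains": 3},
    "hmm": {"n_iter": 1000, "n_burn": 500},
    "report": {"min_support": 20, "plots": False},
}


def _merge_config(config: Mapping | None) -> dict:
    out = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping | str | Path, out_dir: str | Path) -> Path:
    """Execute every stage under one config; returns the run directory.

    Stages: (optional) simulate -> preprocess -> extract-lulc -> fit-tehs
    -> fit-hmm -> report.  Any stage failure aborts with the stage name;
    partial outputs are left in place.  Two runs with identical config are
    byte-identical.
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    stage = "simulate"
    try:
        if cfg["simulate"] is not None:
            sim_cfg = synth_mod.SimConfig(rng_seed=seed, **cfg["simulate"])
            data_dir = out / "data"
            synth_mod.write_simulation(sim_cfg, data_dir)
            tracks_path = data_dir / "tracks.csv"
            landscape = LandscapeRaster.from_ascii_grid(
                data_dir / "landscape.asc", data_dir / "legend.json"
            )
            input_files = [tracks_path, data_dir / "landscape.asc"]
        else:
            tracks_path = Path(cfg["inputs"]["tracks"])
            landscape = LandscapeRaster.from_ascii_grid(
                cfg["inputs"]["landscape"], cfg["inputs"].get("legend")
            )
            input_files = [tracks_path, Path(cfg["inputs"]["landscape"])]

        stage = "preprocess"
        trajectories = read_tracks(tracks_path)
        steps = build_step_table(
            trajectories, tz_offset_hours=cfg["preprocess"]["tz_offset_hours"]
        )
        steps = preprocess_steps(
            steps,
            quantile=cfg["preprocess"]["quantile"],
            max_gap_minutes=cfg["preprocess"]["max_gap_min"],
        )
        steps.to_csv(out / "steps.csv", index=False)
        filter_summary(steps).to_csv(out / "filter_summary.csv", index=False)

        stage = "extract-lulc"
        kept = steps[retained_mask(steps)]
        comps = extract_step_compositions(
            kept, landscape, buffer_m=cfg["lulc"]["buffer_m"]
        )
        retained_set = prune_rare_classes(
            comps, threshold=cfg["lulc"]["prune_threshold"]
        )
        comps = renormalize_compositions(comps, retained_set)
        comps.to_csv(out / "compositions.csv", index=False)

        stage = "fit-tehs"
        mcmc = tehs_mod.MCMCConfig(
            n_iter=cfg["tehs"]["n_iter"],
            n_burn=cfg["tehs"]["n_burn"],
            n_chains=cfg["tehs"]["n_chains"],
            seed=seed,
        )
        ratio_records, posterior_summaries = fit_tehs_per_individual(
            kept, comps, retained_set, mcmc
        )
        ratio_records.to_csv(out / "tehs_ratios.csv", index=False)
        posterior_summaries.to_csv(out / "tehs_posteriors.csv", index=False)
        for model in ("time", "selection"):
            sub = ratio_records[ratio_records["model"] == model]
            tehs_mod.tally_population(sub).to_csv(
                out / f"tally_{model}.csv", index=False
            )

        stage = "fit-hmm"
        states, traces = fit_hmm_per_individual(
            steps, n_iter=cfg["hmm"]["n_iter"], n_burn=cfg["hmm"]["n_burn"], seed=seed
        )
        for ind, trace in traces.items():
            pd.DataFrame({"loglik": trace}).to_csv(
                out / f"hmm_trace_{ind}.csv", index=False
            )
        states.to_csv(out / "hmm_states.csv", index=False)

        stage = "report"
        obs_comps = comps[comps["candidate"] == "observed"].set_index("step_id")
        merged = states.merge(
            steps[["step_id", "hour"]], on="step_id", how="inner"
        )
        merged = merged[merged["step_id"].isin(obs_comps.index)]
        labels = [
            assign_step_lulc(obs_comps.loc[sid, list(retained_set.retained)].to_dict())
            for sid in merged["step_id"]
        ]
        merged["lulc_class"] = labels
        merged["hour_bin"] = diel_bin(merged["hour"].to_numpy())
        diel = resting_proportion(
            merged,
            min_support=cfg["report"]["min_support"],
            classes=retained_set.retained,
        )
        diel.to_csv(out / "diel_table.csv", index=False)
        per_ind = []
        for ind, grp in merged.groupby("individual_id"):
            tbl = resting_proportion(
                grp,
                min_support=cfg["report"]["min_support"],
                classes=retained_set.retained,
            )
            tbl.insert(0, "individual_id", ind)
            per_ind.append(tbl)
        pd.concat(per_ind, ignore_index=True).to_csv(
            out / "diel_table_by_individual.csv", index=False
        )
        if cfg["report"]["plots"]:
            plot_diel_curves(diel, out / "diel_curves.png")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "mosaicmove_version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "config": cfg,
        "input_hashes": {p.name: _file_hash(p) for p in input_files},
        "retained_classes": list(retained_set.retained),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def choice_arrays(
    comps: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Wide (n_sets, 5, k) candidate array with the observed path first."""
    from .lulc import CANDIDATES

    x_list = []
    for _, grp in comps.groupby("step_id", sort=False):
        grp = grp.set_index("candidate")
        if not all(c in grp.index for c in CANDIDATES):
            continue
        x_list.append(grp.loc[list(CANDIDATES), list(covariates)].to_numpy())
    if not x_list:
        return np.empty((0, 5, len(covariates))), np.empty(0, dtype=int)
    x = np.stack(x_list)
    return x, np.zeros(len(x_list), dtype=int)
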