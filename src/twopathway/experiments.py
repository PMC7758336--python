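"""Named, reproducible experiments over the library's operations.

Each experiment is a function from an :class:`ExperimentConfig` to one or
more tidy tables.  :func:`run_experiment` dispatches by name, writes the
tables as CSV, and records a JSON manifest with the full configuration,
seed lineage and per-stage timings, so a run can be reproduced exactly
from its manifest.

Experiments are registered under the figure-style names used throughout
the package's documentation (``fig1d`` ... ``fig6d``, ``suppfig1`` ...);
``list_experiments`` enumerates them.  Default parameters are the
figure-scale settings; the ``desk`` preset shrinks network sizes and run
counts for quick interactive runs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import pathways, perceptron, reaching, reinforce, theory
from .patterns import child_seeds, generate_patterns, make_repetition_schedule

__all__ = ["ExperimentConfig", "run_experiment", "list_experiments",
           "load_config", "EXPERIMENTS"]

# Reduced-scale overrides for quick desk runs
DESK_PRESET = {"N": 250, "n_runs": 50, "n_networks": 5, "n_trials": 1000}


@dataclass
class ExperimentConfig:
    """A named experiment, its parameters, seed and output directory."""

    experiment: str
    seed: int = 0
    out_dir: str = "results"
    preset: str = "full"          # "full" or "desk"
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)


def load_config(path) -> ExperimentConfig:
    """Read an experiment configuration from a YAML file."""
    with open(path) as fh:
        return ExperimentConfig.from_dict(yaml.safe_load(fh))


def _p(cfg: ExperimentConfig, key: str, default):
    """Parameter lookup: explicit param > desk preset > default."""
    if key in cfg.params:
        return cfg.params[key]
    if cfg.preset == "desk" and key in DESK_PRESET:
        return DESK_PRESET[key]
    return default


# ---------------------------------------------------------------------------
# experiment implementations; each returns {table_name: DataFrame}

def _fig1d(cfg):
    """Single-pathway forgetting curve, simulation vs. theory."""
    N = _p(cfg, "N", 1000)
    fc = perceptron.estimate_forgetting_curve(
        N_x=N, P=_p(cfg, "P", 2 * N), n_runs=_p(cfg, "n_runs", 200),
        seed=cfg.seed)
    th = theory.theory_curve(fc.tau[::max(1, len(fc.tau) // 100)], beta=0.0)
    return {"simulation": fc.to_frame(), "theory": th.to_frame()}


def _suppfig1(cfg):
    """Forgetting curve under the gradient-descent training variant."""
    N = _p(cfg, "N", 250)
    fc = perceptron.estimate_forgetting_curve(
        N_x=N, n_runs=_p(cfg, "n_runs", 100), seed=cfg.seed,
        gradient_descent=(_p(cfg, "learning_rate", 0.2),
                          _p(cfg, "n_steps", 100)))
    return {"simulation": fc.to_frame()}


def _fig2b(cfg):
    """Forgetting curves with six repeated patterns vs. none repeated."""
    N = _p(cfg, "N", 1000)
    P = _p(cfg, "P", 2 * N)
    n_rep = _p(cfg, "n_rep", 10)
    k = _p(cfg, "n_repeated_patterns", 6)
    positions = [int(round(p)) for p in np.linspace(0.1, 0.9, k) * P]
    curves = pathways.estimate_two_pathway_forgetting_curve(
        N_x=N, N_y=N, alpha=_p(cfg, "alpha", 1.0), beta=_p(cfg, "beta", 1.0),
        P=P, repeated={pos: n_rep for pos in positions},
        n_runs=_p(cfg, "n_runs", 100), seed=cfg.seed)
    baseline = pathways.estimate_two_pathway_forgetting_curve(
        N_x=N, N_y=N, alpha=_p(cfg, "alpha", 1.0), beta=_p(cfg, "beta", 1.0),
        P=P, repeated={}, n_runs=_p(cfg, "n_runs", 100), seed=cfg.seed + 1)
    out = {name: c.to_frame() for name, c in curves.items()}
    out["baseline_unrepeated"] = baseline["unrepeated"].to_frame()
    return out


def _fig2c(cfg):
    """Repeated-pattern error vs. lag, one curve per repetition count."""
    N = _p(cfg, "N", 1000)
    lag_grid = _p(cfg, "lags", [N // 4, N // 2, N, 2 * N])
    frames = []
    for n_rep in _p(cfg, "n_reps", [1, 2, 5, 10, 20]):
        c = pathways.repeated_pattern_error(
            N, N, _p(cfg, "alpha", 1.0), _p(cfg, "beta", 1.0), n_rep,
            lag_grid, n_runs=_p(cfg, "n_runs", 200), seed=cfg.seed + n_rep)
        df = c.to_frame()
        df["n_rep"] = n_rep
        frames.append(df)
    return {"curves": pd.concat(frames, ignore_index=True)}


def _fig2d(cfg):
    """Error vs. repetition count at fixed testing intervals."""
    N = _p(cfg, "N", 1000)
    frames = []
    for lag in _p(cfg, "lags", [N // 2, N, 2 * N]):
        for n_rep in _p(cfg, "n_reps", [1, 2, 3, 5, 8, 12, 20]):
            c = pathways.repeated_pattern_error(
                N, N, _p(cfg, "alpha", 1.0), _p(cfg, "beta", 1.0), n_rep,
                [lag], n_runs=_p(cfg, "n_runs", 200),
                seed=cfg.seed + 31 * lag + n_rep)
            df = c.to_frame()
            df["n_rep"] = n_rep
            frames.append(df)
    return {"curves": pd.concat(frames, ignore_index=True)}


def _fig2e(cfg):
    """Repetitions needed to beat an error threshold vs. interval."""
    N = _p(cfg, "N", 500)
    rows = []
    for interval in _p(cfg, "intervals", [N // 4, N // 2, N, 3 * N // 2, 2 * N]):
        n, attained = pathways.repetitions_to_threshold(
            N, N, _p(cfg, "alpha", 1.0), _p(cfg, "beta", 1.0), interval,
            _p(cfg, "p_theta", 0.05), n_runs=_p(cfg, "n_runs", 200),
            seed=cfg.seed, n_cap=_p(cfg, "n_cap", 4096))
        rows.append({"interval": interval, "tau": interval / N,
                     "n_required": n, "attained": attained})
    return {"repetitions": pd.DataFrame(rows)}


def _fig3c(cfg):
    """Alignment and control-ratio growth while one pattern is repeated.

    The network is first brought to the stationary regime by training a
    sequence of background patterns once each (from zero weights and a
    single pattern the two currents are trivially parallel); the probe
    pattern is then repeated and its decomposition recorded per repetition.
    """
    N = _p(cfg, "N", 1000)
    N_z = _p(cfg, "N_z", min(N, 1000))
    n_rep = _p(cfg, "n_rep", 20)
    n_nets = _p(cfg, "n_networks", 20)
    n_background = _p(cfg, "n_background", N)
    rows = []
    for i, s in enumerate(child_seeds(cfg.seed, n_nets)):
        ens = generate_patterns(n_background + 1, N, N, N_z, seed=s)
        state = pathways.TwoPathwayState.zeros(N, N, N_z)
        for mu in range(n_background):
            pathways.present_pattern(state, ens.X[mu], ens.Y[mu],
                                     ens.Zhat[mu], n=1)
        traces = pathways.present_pattern(state, ens.X[-1], ens.Y[-1],
                                          ens.Zhat[-1], n=n_rep)
        for rep, dec in enumerate(traces, start=1):
            rows.append({"network": i, "repetition": rep,
                         "alignment": dec.alignment,
                         "control_ratio": dec.control_ratio(ens.Zhat[-1])})
    return {"traces": pd.DataFrame(rows)}


def _train_population_with_repeat(cfg, N, N_z, P, rep_pos, n_rep, seed):
    ens = generate_patterns(P, N, N, N_z, seed=seed)
    schedule = make_repetition_schedule(P, {rep_pos: n_rep})
    state = pathways.TwoPathwayState.zeros(N, N, N_z, nbar=schedule.nbar,
                                           alpha=_p(cfg, "alpha", 1.0),
                                           beta=_p(cfg, "beta", 1.0))
    pathways.train_two_pathway(ens, schedule, state)
    return ens, state


def _fig3d(cfg):
    """Population lesion test: silence either pathway after training."""
    N = _p(cfg, "N", 1000)
    N_z = _p(cfg, "N_z", N)
    P = _p(cfg, "P", N)
    rep_pos = _p(cfg, "repeated_position", P // 2)
    n_rep = _p(cfg, "n_rep", 10)
    n_nets = _p(cfg, "n_networks", 10)
    frames = []
    for i, s in enumerate(child_seeds(cfg.seed, n_nets)):
        ens, state = _train_population_with_repeat(cfg, N, N_z, P, rep_pos,
                                                   n_rep, s)
        for mode in ("intact", "m_zero", "h_zero"):
            err = pathways.lesion_test(state, ens, mode)
            frames.append(pd.DataFrame({
                "network": i, "pattern": np.arange(P), "mode": mode,
                "repeated": np.arange(P) == rep_pos, "error": err}))
    return {"lesions": pd.concat(frames, ignore_index=True)}


def _fig5b(cfg):
    """Error under graded noise perturbations of the fast-pathway current."""
    N = _p(cfg, "N", 1000)
    N_z = _p(cfg, "N_z", N)
    P = _p(cfg, "P", N)
    rep_pos = P // 2
    rows = []
    for n_rep in _p(cfg, "n_reps", [1, 5, 10, 20]):
        ens, state = _train_population_with_repeat(
            cfg, N, N_z, P, rep_pos, n_rep, cfg.seed + n_rep)
        for sigma in _p(cfg, "sigmas", [0.0, 0.5, 1.0, 2.0, 4.0]):
            err = pathways.lesion_test(state, ens, "intact", sigma_m=sigma,
                                       n_noise=_p(cfg, "n_noise", 100),
                                       seed=cfg.seed)
            rows.append({"n_rep": n_rep, "sigma_m": sigma,
                         "error_repeated": err[rep_pos]})
        err0 = pathways.lesion_test(state, ens, "m_zero")
        rows.append({"n_rep": n_rep, "sigma_m": np.inf,
                     "error_repeated": err0[rep_pos]})
    return {"perturbation": pd.DataFrame(rows)}


def _fig5c(cfg):
    """Activity similarity under single-pathway silencing vs. repetitions.

    The probe pattern is trained last: the similarity prediction concerns
    the population state right after practice, before the fast-pathway
    current is overwritten by subsequent learning.
    """
    N = _p(cfg, "N", 1000)
    N_z = _p(cfg, "N_z", N)
    P = _p(cfg, "P", N)
    rep_pos = P - 1
    rows = []
    for n_rep in _p(cfg, "n_reps", [1, 2, 5, 10, 20, 50]):
        ens, state = _train_population_with_repeat(
            cfg, N, N_z, P, rep_pos, n_rep, cfg.seed + n_rep)
        ov_mh, ov_mi = pathways.population_similarity(
            state, ens.X[rep_pos], ens.Y[rep_pos])
        rows.append({"n_rep": n_rep, "overlap_m0_h0": ov_mh,
                     "overlap_m0_intact": ov_mi})
    return {"similarity": pd.DataFrame(rows)}


def _fig4ab(cfg):
    """RL+HL vs RL+RL: alignment, control transfer, robustness to lesion."""
    N = _p(cfg, "N", 1000)
    n_trials = _p(cfg, "n_trials", 3000)
    s_pat, s_net, s_tr = child_seeds(cfg.seed, 3)
    rng = np.random.default_rng(s_pat)
    x = rng.standard_normal(N)
    y = rng.standard_normal(N)
    zhat = np.where(rng.random(_p(cfg, "N_z", 10)) < 0.5, -1.0, 1.0)
    out = {}
    for variant in ("RL_plus_HL", "RL_plus_RL"):
        state = reinforce.RLState.random(N, N, len(zhat), seed=s_net,
                                         eta=_p(cfg, "eta", 1.0),
                                         beta=_p(cfg, "beta", 0.01),
                                         eta2=_p(cfg, "eta2", 0.01),
                                         variant=variant)
        out[variant] = reinforce.train_rl(state, x, y, zhat, n_trials,
                                          seed=s_tr)
    return out


def _fig4d(cfg):
    """Habit persistence: trials to re-learn after a target switch."""
    rows = []
    cap = _p(cfg, "trial_cap", 10_000)
    for n_nu in _p(cfg, "n_nus", [0, 25, 50, 100, 200, 400]):
        for variant in ("RL_only", "RL_plus_HL"):
            res = reinforce.habit_experiment(
                variant, n_nu, N_x=_p(cfg, "N", 1000),
                N_y=_p(cfg, "N", 1000), N_z=_p(cfg, "N_z", 10),
                trial_cap=cap, seed=cfg.seed + n_nu)
            rows.append({"n_nu": n_nu, "variant": variant,
                         "trials_to_criterion": res.trials_to_criterion,
                         "attained": res.attained})
    return {"habit": pd.DataFrame(rows)}


def _fig6cd(cfg):
    """Reaching task: block training traces and retention comparison."""
    spec = reaching.ReachingSpec()
    n_nets = _p(cfg, "n_networks", 21)
    df = reaching.retention_experiment(
        ("SL_only", "SL_plus_HL", "SL_interleaved"), n_networks=n_nets,
        seed=cfg.seed, spec=spec)
    _, trace_hl = reaching.train_blocks(
        reaching.ReachingSpec(condition="SL_plus_HL"), seed=cfg.seed)
    _, trace_sl = reaching.train_blocks(
        reaching.ReachingSpec(condition="SL_only"), seed=cfg.seed)
    trace_hl["condition"] = "SL_plus_HL"
    trace_sl["condition"] = "SL_only"
    return {"retention": df,
            "training_traces": pd.concat([trace_hl, trace_sl],
                                         ignore_index=True)}


def _sweep(cfg, key, values, **fixed):
    """Shared helper for the parameter-sweep studies."""
    N = _p(cfg, "N", 500)
    frames = []
    for val in values:
        kw = dict(alpha=1.0, beta=1.0)
        kw.update(fixed)
        kw[key] = val
        ratio = kw.pop("ratio", 1.0)
        c = pathways.repeated_pattern_error(
            N, int(round(ratio * N)), kw["alpha"], kw["beta"],
            _p(cfg, "n_rep", 1),
            _p(cfg, "lags", [N // 4, N // 2, N, 2 * N]),
            n_runs=_p(cfg, "n_runs", 200), seed=cfg.seed)
        df = c.to_frame()
        df[key] = val
        frames.append(df)
    return {"curves": pd.concat(frames, ignore_index=True)}


def _suppfig2(cfg):
    return _sweep(cfg, "alpha", _p(cfg, "alphas", [0.25, 0.5, 1.0, 2.0]))


def _suppfig3(cfg):
    return _sweep(cfg, "beta", _p(cfg, "betas", [0.0, 0.5, 1.0, 2.0]))


def _suppfig4(cfg):
    """Error of unrepeated patterns as the number of repeated ones grows."""
    N = _p(cfg, "N", 500)
    P = 2 * N
    rows = []
    for k in _p(cfg, "n_repeated_patterns", [0, 2, 6, 20, 60]):
        positions = ([int(round(p)) for p in np.linspace(0.1, 0.6, k) * P]
                     if k else [])
        curves = pathways.estimate_two_pathway_forgetting_curve(
            N_x=N, N_y=N, P=P,
            repeated={pos: _p(cfg, "n_rep", 10) for pos in positions},
            n_runs=_p(cfg, "n_runs", 50), seed=cfg.seed + k)
        unrep = curves["unrepeated"]
        recent = unrep.tau <= 1.0
        rows.append({"n_repeated_patterns": k,
                     "mean_error_recent_unrepeated":
                         float(unrep.error[recent].mean())})
    return {"interference": pd.DataFrame(rows)}


def _suppfig6(cfg):
    """Spaced vs. massed repetition: error after training with gaps."""
    N = _p(cfg, "N", 500)
    P = 2 * N
    n_rep = _p(cfg, "n_rep", 10)
    rep_pos = P // 4
    n_runs = _p(cfg, "n_runs", 100)
    rows = []
    for gap in _p(cfg, "gaps", [0, 1, 5, 20, 100]):
        err = 0.0
        for s in child_seeds(cfg.seed + gap, n_runs):
            ens = generate_patterns(P, N, N, 1, seed=s)
            schedule = make_repetition_schedule(P, {rep_pos: n_rep},
                                                default_gap=gap)
            state = pathways.TwoPathwayState.zeros(N, N, 1,
                                                   nbar=schedule.nbar)
            pathways.train_two_pathway(ens, schedule, state)
            # classification of the repeated pattern at the end of training
            u_rep = (state.W[0] @ ens.X[rep_pos] + state.V[0] @ ens.Y[rep_pos])
            err += float(perceptron.sign(u_rep) != ens.Zhat[rep_pos, 0])
        rows.append({"gap": gap, "error_repeated": err / n_runs})
    return {"spacing": pd.DataFrame(rows)}


EXPERIMENTS = {
    "fig1d": _fig1d,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig2d": _fig2d,
    "fig2e": _fig2e,
    "fig3c": _fig3c,
    "fig3d": _fig3d,
    "fig4ab": _fig4ab,
    "fig4d": _fig4d,
    "fig5b": _fig5b,
    "fig5c": _fig5c,
    "fig6cd": _fig6cd,
    "suppfig1": _suppfig1,
    "suppfig2": _suppfig2,
    "suppfig3": _suppfig3,
    "suppfig4": _suppfig4,
    "suppfig6": _suppfig6,
}


def list_experiments() -> list[str]:
    return sorted(EXPERIMENTS)


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run a named experiment; write CSV tables, manifest and log.

    Returns ``{"tables": {name: DataFrame}, "manifest": dict}``.  The
    manifest echoes the full configuration (so a rerun is seed-identical),
    the derived child-seed lineage and per-stage timings.
    """
    if cfg.experiment not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {cfg.experiment!r}; "
            f"available: {', '.join(list_experiments())}")
    if cfg.preset not in ("full", "desk"):
        raise ValueError("preset must be 'full' or 'desk'")
    out_dir = Path(cfg.out_dir) / cfg.experiment
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    tables = EXPERIMENTS[cfg.experiment](cfg)
    elapsed = time.time() - t0
    manifest = {
        "config": cfg.to_dict(),
        "seed_lineage": child_seeds(cfg.seed, 8),
        "tables": sorted(tables),
        "elapsed_seconds": elapsed,
    }
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    return {"tables": tables, "manifest": manifest}
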