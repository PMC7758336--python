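"""Center-out reaching with a two-pathway network and a hidden layer.

A cursor starts at the origin and must reach one of four targets at
(1,0), (0,1), (-1,0), (0,-1) in ``T = 10`` timesteps, following a
minimum-jerk velocity profile.  A network with one hidden layer controls
the cursor velocity: two input populations (sizes ``N_x`` and ``N_y``)
each receive a tonic target-specific cue plus a fixed random projection of
the current cursor position; the hidden layer (size ``N_z``, tanh units)
receives them through the plastic matrices ``W`` (trained by gradient
descent on the velocity error, SL) and ``V`` (trained by the Hebbian rule
``dV_ij = eta_HL (-V_ij + z_i y_j)`` per step, HL); a fixed linear readout
maps the hidden layer to a 2-D velocity.

Training is block-sequential (a long block on target 1, then shorter
blocks on targets 2-4), so later blocks overwrite earlier learning in
``W``; the Hebbian pathway protects the heavily practiced first target.
An interleaved condition (targets drawn at random each trial) is the
no-forgetting control.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .patterns import child_seeds

__all__ = [
    "ReachingSpec",
    "ReachingNetwork",
    "TrialTrace",
    "minimum_jerk_velocity",
    "build_network",
    "simulate_trial",
    "train_blocks",
    "evaluate_retention",
    "retention_experiment",
    "TARGETS",
]

TARGETS = np.array([(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)])

CONDITIONS = ("SL_only", "SL_plus_HL", "SL_interleaved")


@dataclass
class ReachingSpec:
    """Task geometry, network sizes, learning rates and training schedule."""

    targets: np.ndarray = field(default_factory=lambda: TARGETS.copy())
    T: int = 10
    N_x: int = 50
    N_y: int = 50
    N_z: int = 10
    eta_sl: float = 1e-3
    eta_hl: float = 1e-6
    block_schedule: tuple = ((0, 6000), (1, 1500), (2, 1500), (3, 1500))
    condition: str = "SL_plus_HL"
    feedback: str = "position"    # or "velocity": previous-step readout
    cue_scale: float = 1.0        # amplitude of the tonic target cue
    cue_mode_x: str = "gaussian"    # fast-pathway cues: random overlap
    cue_mode_y: str = "orthogonal"  # slow-pathway cues: no tonic overlap
    readout_scale: float = 1.0    # gain of the fixed linear readout

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.float64)
        if self.eta_sl < 0 or self.eta_hl < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.feedback not in ("position", "velocity"):
            raise ValueError("feedback must be 'position' or 'velocity'")
        for mode in (self.cue_mode_x, self.cue_mode_y):
            if mode not in ("orthogonal", "gaussian"):
                raise ValueError("cue modes must be 'orthogonal' or 'gaussian'")


def minimum_jerk_velocity(t: int, T: int, target: np.ndarray) -> np.ndarray:
    """Target velocity ``r [30 u^2 - 60 u^3 + 30 u^4]`` with ``u = t/T``.

    The quartic speed profile is bell-shaped, vanishes at both endpoints,
    and integrates to 1 over ``u in [0, 1]``, so the continuous-time
    displacement equals the target vector exactly.
    """
    if not 0 <= t <= T:
        raise ValueError("t must be in [0, T]")
    u = t / T
    return np.asarray(target, dtype=np.float64) * (30 * u**2 - 60 * u**3 + 30 * u**4)


@dataclass
class ReachingNetwork:
    """Plastic pathways plus the fixed scaffolding drawn at construction."""

    W: np.ndarray       # (N_z, N_x), supervised pathway
    V: np.ndarray       # (N_z, N_y), Hebbian pathway
    A: np.ndarray       # (2, N_z), fixed linear readout
    B_x: np.ndarray     # (N_x, 2), fixed position feedback projection
    B_y: np.ndarray     # (N_y, 2)
    C_x: np.ndarray     # (n_targets, N_x), tonic cue vectors
    C_y: np.ndarray     # (n_targets, N_y)
    seed: int = 0

    def copy(self) -> "ReachingNetwork":
        return ReachingNetwork(W=self.W.copy(), V=self.V.copy(), A=self.A,
                               B_x=self.B_x, B_y=self.B_y, C_x=self.C_x,
                               C_y=self.C_y, seed=self.seed)


def build_network(spec: ReachingSpec, seed: int = 0) -> ReachingNetwork:
    """Draw the fixed cues, feedback projections and initial weights.

    ``W`` starts at small random values scaled by the inverse square root
    of its fan-in; ``V`` starts at zero in every condition, so the two
    conditions differ only in whether ``V`` is trained.
    """
    rng = np.random.default_rng(seed)
    n_t = spec.targets.shape[0]
    W = rng.standard_normal((spec.N_z, spec.N_x)) / np.sqrt(spec.N_x)
    V = np.zeros((spec.N_z, spec.N_y))
    A = spec.readout_scale * rng.standard_normal((2, spec.N_z)) / np.sqrt(spec.N_z)
    B_x = rng.standard_normal((spec.N_x, 2))
    B_y = rng.standard_normal((spec.N_y, 2))

    def draw_cues(n_dim, mode):
        C = rng.standard_normal((n_t, n_dim))
        if mode == "orthogonal":
            # mutually orthogonal cues with the same per-entry scale as
            # Gaussian ones: no tonic overlap between target contexts, so
            # pathway associations do not cross-contaminate across targets
            q, _ = np.linalg.qr(C.T)
            C = q.T * np.sqrt(n_dim)
        return spec.cue_scale * C

    C_x = draw_cues(spec.N_x, spec.cue_mode_x)
    C_y = draw_cues(spec.N_y, spec.cue_mode_y)
    return ReachingNetwork(W=W, V=V, A=A, B_x=B_x, B_y=B_y, C_x=C_x,
                           C_y=C_y, seed=seed)


@dataclass
class TrialTrace:
    """One trial's kinematics and loss."""

    positions: np.ndarray    # (T+1, 2)
    velocities: np.ndarray   # (T, 2)
    step_losses: np.ndarray  # (T,)

    @property
    def loss(self) -> float:
        """Mean squared velocity error over steps and output dimensions."""
        return float(self.step_losses.mean())


def simulate_trial(net: ReachingNetwork, spec: ReachingSpec,
                   target_index: int, learn: bool = False) -> TrialTrace:
    """Roll the network for one trial; optionally apply the plasticity.

    At step ``t`` (1..T) the input populations see the cue for the cued
    target plus projections of the cursor position after step ``t-1``; the
    hidden layer is ``z = tanh(W x + V y)``; the velocity is the fixed
    linear readout of ``z`` and the position advances by ``velocity / T``.

    Learning (per-trial batch): gradient descent on ``W`` against the
    summed squared velocity error, treating each step's inputs as data
    (no backpropagation through the position feedback), plus the per-step
    Hebbian update of ``V`` when the condition includes HL.
    """
    T = spec.T
    r = spec.targets[target_index]
    pos = np.zeros(2)
    vel = np.zeros(2)
    positions = np.zeros((T + 1, 2))
    velocities = np.zeros((T, 2))
    step_losses = np.zeros(T)
    hebbian = learn and spec.condition == "SL_plus_HL" and spec.eta_hl > 0
    if learn:
        dW = np.zeros_like(net.W)
    for t in range(1, T + 1):
        fb = pos if spec.feedback == "position" else vel
        x = net.C_x[target_index] + net.B_x @ fb
        y = net.C_y[target_index] + net.B_y @ fb
        z = np.tanh(net.W @ x + net.V @ y)
        vel = net.A @ z
        u_hat = minimum_jerk_velocity(t, T, r)
        err = vel - u_hat
        step_losses[t - 1] = float(err @ err) / 2.0
        if learn:
            delta = (net.A.T @ err) * (1.0 - z * z)
            dW += np.outer(delta, x)
            if hebbian:
                net.V += spec.eta_hl * (-net.V + np.outer(z, y))
        pos = pos + vel / T
        velocities[t - 1] = vel
        positions[t] = pos
    if learn and spec.eta_sl > 0:
        net.W -= spec.eta_sl * dW
    return TrialTrace(positions=positions, velocities=velocities,
                      step_losses=step_losses)


def train_blocks(spec: ReachingSpec, seed: int = 0
                 ) -> tuple[ReachingNetwork, pd.DataFrame]:
    """Train through the block schedule; return the network and loss traces.

    In the ``SL_interleaved`` condition the same total number of trials is
    used but the target is drawn uniformly at random each trial.
    """
    if not spec.block_schedule:
        raise ValueError("block_schedule must be nonempty")
    s_net, s_interleave = child_seeds(seed, 2)
    net = build_network(spec, seed=s_net)
    rows = []
    trial = 0
    if spec.condition == "SL_interleaved":
        rng = np.random.default_rng(s_interleave)
        total = sum(n for _, n in spec.block_schedule)
        for _ in range(total):
            tgt = int(rng.integers(spec.targets.shape[0]))
            trace = simulate_trial(net, spec, tgt, learn=True)
            rows.append({"trial": trial, "block": -1, "target": tgt,
                         "loss": trace.loss})
            trial += 1
    else:
        for block, (tgt, n_trials) in enumerate(spec.block_schedule):
            for _ in range(n_trials):
                trace = simulate_trial(net, spec, tgt, learn=True)
                rows.append({"trial": trial, "block": block, "target": tgt,
                             "loss": trace.loss})
                trial += 1
    return net, pd.DataFrame(rows)


def evaluate_retention(networks: list[ReachingNetwork], spec: ReachingSpec,
                       n_test_trials: int = 1) -> pd.DataFrame:
    """Frozen-weight test losses per target, summarized over networks.

    Returns a frame with one row per (network, target): the mean loss over
    ``n_test_trials`` rollouts (the dynamics are deterministic, so one
    trial suffices; the parameter exists for protocol symmetry).  An empty
    frame if ``n_test_trials`` is 0.
    """
    rows = []
    if n_test_trials < 1:
        return pd.DataFrame(columns=["network", "target", "loss"])
    for i, net in enumerate(networks):
        for tgt in range(spec.targets.shape[0]):
            losses = [simulate_trial(net, spec, tgt, learn=False).loss
                      for _ in range(n_test_trials)]
            rows.append({"network": i, "target": tgt,
                         "loss": float(np.mean(losses))})
    return pd.DataFrame(rows)


def retention_experiment(conditions=("SL_only", "SL_plus_HL"),
                         n_networks: int = 21, seed: int = 0,
                         spec: ReachingSpec | None = None) -> pd.DataFrame:
    """Matched-seed retention comparison across training conditions.

    Trains ``n_networks`` networks per condition (network ``i`` shares its
    construction seed across conditions, so the conditions differ only in
    the plasticity) and returns tidy per-(condition, network, target) test
    losses.
    """
    base = spec or ReachingSpec()
    seeds = child_seeds(seed, n_networks)
    frames = []
    for condition in conditions:
        cspec = replace(base, targets=base.targets.copy(),
                        condition=condition)
        nets = [train_blocks(cspec, seed=s)[0] for s in seeds]
        df = evaluate_retention(nets, cspec)
        df["condition"] = condition
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
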