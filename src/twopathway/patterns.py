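"""Random classification tasks and repetition schedules.

Every experiment in this package trains on the same kind of synthetic task:
``P`` random input patterns drawn i.i.d. from a standard normal distribution,
each mapped onto a random binary target.  Inputs arrive through two parallel
pathways, ``x`` (dimension ``N_x``) and ``y`` (dimension ``N_y``); the
single-pathway model is the special case ``N_y = 0``.  A repetition schedule
says how many times each pattern is presented during training and in what
order, including spaced repetitions where other patterns are interleaved
between presentations of a repeated one.

All randomness in the package flows through :func:`numpy.random.SeedSequence`
children of a single root seed, so that pattern draws, learning noise and
perturbation noise are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PatternEnsemble",
    "RepetitionSchedule",
    "generate_patterns",
    "make_repetition_schedule",
    "child_seeds",
    "save_ensemble",
    "load_ensemble",
]


def child_seeds(root_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from one root seed."""
    ss = np.random.SeedSequence(root_seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class PatternEnsemble:
    """A batch of random patterns with binary targets and repeat counts.

    Attributes
    ----------
    X : ndarray, shape (P, N_x)
        First-pathway input patterns, i.i.d. standard normal.
    Y : ndarray, shape (P, N_y)
        Second-pathway input patterns; ``N_y = 0`` encodes the
        single-pathway model.
    Zhat : ndarray, shape (P, N_z)
        Target outputs, entries exactly +1 or -1.
    repeats : ndarray, shape (P,)
        Number of presentations of each pattern during training.
    seed : int
        Seed used to draw the ensemble.
    """

    X: np.ndarray
    Y: np.ndarray
    Zhat: np.ndarray
    repeats: np.ndarray = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        self.Zhat = np.asarray(self.Zhat, dtype=np.float64)
        if self.repeats is None:
            self.repeats = np.ones(self.X.shape[0], dtype=np.int64)
        self.repeats = np.asarray(self.repeats, dtype=np.int64)
        P = self.X.shape[0]
        if P < 1:
            raise ValueError("P must be >= 1")
        if self.X.shape[1] < 1:
            raise ValueError("N_x must be >= 1")
        if self.Zhat.shape[1] < 1:
            raise ValueError("N_z must be >= 1")
        if self.Y.shape[0] != P or self.Zhat.shape[0] != P or self.repeats.shape[0] != P:
            raise ValueError("X, Y, Zhat and repeats must agree on P")
        if not np.all(np.abs(self.Zhat) == 1.0):
            raise ValueError("Zhat entries must be exactly +1 or -1")
        if np.any(self.repeats < 1):
            raise ValueError("repeats must be >= 1 elementwise")

    @property
    def P(self) -> int:
        return self.X.shape[0]

    @property
    def N_x(self) -> int:
        return self.X.shape[1]

    @property
    def N_y(self) -> int:
        return self.Y.shape[1]

    @property
    def N_z(self) -> int:
        return self.Zhat.shape[1]

    @property
    def nbar(self) -> float:
        """Mean number of presentations per pattern."""
        return float(self.repeats.mean())


def generate_patterns(P: int, N_x: int, N_y: int = 0, N_z: int = 1,
                      seed: int = 0) -> PatternEnsemble:
    """Draw a fresh ensemble of Gaussian patterns with fair +/-1 targets.

    Parameters
    ----------
    P, N_x, N_y, N_z : int
        Number of patterns, first- and second-pathway input dimensions, and
        number of readout units.  ``N_y = 0`` gives the single-pathway task.
    seed : int
        Same seed and dimensions reproduce the ensemble bit-for-bit.
    """
    if P < 1 or N_x < 1 or N_z < 1:
        raise ValueError("P, N_x and N_z must be positive")
    if N_y < 0:
        raise ValueError("N_y must be nonnegative")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((P, N_x))
    Y = rng.standard_normal((P, N_y))
    Zhat = np.where(rng.random((P, N_z)) < 0.5, -1.0, 1.0)
    return PatternEnsemble(X=X, Y=Y, Zhat=Zhat, seed=seed)


@dataclass
class RepetitionSchedule:
    """Repeat counts plus the presentation order they induce.

    ``order`` lists pattern indices (0-based) in the order they are trained;
    a pattern with ``repeats[i] = n`` appears ``n`` times.
    """

    repeats: np.ndarray
    order: np.ndarray

    @property
    def nbar(self) -> float:
        return float(self.repeats.mean())


def make_repetition_schedule(P: int, special: dict[int, int] | None = None,
                             default_gap: int = 0) -> RepetitionSchedule:
    """Build a presentation schedule in which some patterns are repeated.

    Patterns run in index order ``0 .. P-1``, each presented once, except
    patterns listed in ``special`` which are presented ``special[i]`` times.
    With ``default_gap = 0`` the extra presentations are consecutive; with
    ``default_gap = g > 0`` each pair of successive presentations of a
    repeated pattern is separated by ``g`` presentations of other patterns
    (spaced repetition).  Repetitions still pending when the base sequence
    runs out are appended consecutively.
    """
    special = dict(special or {})
    for idx, n in special.items():
        if not (0 <= idx < P):
            raise ValueError(f"special index {idx} out of range [0, {P})")
        if n < 1:
            raise ValueError("repetition counts must be >= 1")
    if default_gap < 0:
        raise ValueError("default_gap must be >= 0")

    repeats = np.ones(P, dtype=np.int64)
    for idx, n in special.items():
        repeats[idx] = n

    order: list[int] = []
    if default_gap == 0:
        for p in range(P):
            order.extend([p] * int(repeats[p]))
    else:
        # pending re-presentations: [index, remaining, others seen since last]
        pending: list[list[int]] = []

        def emit(p: int) -> None:
            order.append(p)
            for item in pending:
                if item[0] != p:
                    item[2] += 1
            due = [it for it in pending if it[1] > 0 and it[2] >= default_gap]
            for item in due:
                order.append(item[0])
                item[1] -= 1
                item[2] = 0
                for other in pending:
                    if other is not item:
                        other[2] += 1

        for p in range(P):
            if repeats[p] > 1:
                pending.append([p, int(repeats[p]) - 1, 0])
            emit(p)
        for item in pending:  # flush leftovers consecutively
            order.extend([item[0]] * item[1])

    return RepetitionSchedule(repeats=repeats, order=np.asarray(order, dtype=np.int64))


def save_ensemble(ensemble: PatternEnsemble, path) -> None:
    """Serialize an ensemble to a ``.npz`` container with its seed."""
    np.savez(path, X=ensemble.X, Y=ensemble.Y, Zhat=ensemble.Zhat,
             repeats=ensemble.repeats, seed=np.asarray(ensemble.seed))


def load_ensemble(path) -> PatternEnsemble:
    with np.load(path) as data:
        return PatternEnsemble(X=data["X"], Y=data["Y"], Zhat=data["Zhat"],
                               repeats=data["repeats"], seed=int(data["seed"]))
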