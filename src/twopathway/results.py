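"""Result containers shared across modules: forgetting and theory curves."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ForgettingCurve", "TheoryCurve", "isotonic_residual"]


@dataclass
class ForgettingCurve:
    """Monte-Carlo recall-error estimates as a function of normalized lag.

    ``tau`` is the lag between training and testing a pattern, measured in
    units of the first-pathway input count: ``tau = (P - nu) / N_x``.
    ``error`` is the estimated misclassification probability at each lag and
    ``se`` its binomial standard error over ``n_runs`` independent networks.
    """

    tau: np.ndarray
    error: np.ndarray
    se: np.ndarray
    n_runs: int
    label: str = ""
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau, "error": self.error,
                             "se": self.se, "n_runs": self.n_runs})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def at(self, tau: float) -> tuple[float, float]:
        """Error and SE at the grid point closest to ``tau``."""
        i = int(np.argmin(np.abs(self.tau - tau)))
        return float(self.error[i]), float(self.se[i])


@dataclass
class TheoryCurve:
    """Semi-analytic error predictions on a lag grid.

    ``method`` records how the curve was evaluated (drift-diffusion
    quadrature); parameters are echoed in ``params``.
    """

    tau: np.ndarray
    error: np.ndarray
    params: dict
    method: str = "numeric_drift_diffusion"

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"tau": self.tau, "error": self.error})
        df["method"] = self.method
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def isotonic_residual(tau: np.ndarray, error: np.ndarray) -> np.ndarray:
    """Residuals of the best non-decreasing fit to ``error`` over ``tau``.

    Pool-adjacent-violators on the sequence ordered by ``tau``.  Used to
    check that a forgetting curve is monotone up to Monte-Carlo noise.
    """
    order = np.argsort(tau)
    y = np.asarray(error, dtype=float)[order]
    # PAVA: maintain blocks of (weighted) means
    vals: list[float] = []
    wts: list[float] = []
    for v in y:
        vals.append(float(v))
        wts.append(1.0)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            w = wts[-2] + wts[-1]
            m = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / w
            vals[-2:] = [m]
            wts[-2:] = [w]
    fit = np.repeat(vals, np.asarray(wts, dtype=int))
    resid = np.empty_like(y)
    resid[:] = y - fit
    out = np.empty_like(resid)
    out[order] = resid
    return out
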