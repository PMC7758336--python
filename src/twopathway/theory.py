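"""Semi-analytic forgetting curves via a drift-diffusion description.

In a long random training sequence, the signed margin of one tested pattern
evolves under the updates triggered by all subsequently trained patterns.
Because those patterns are random with respect to the tested one, the
evolution is a drift-diffusion (Ornstein-Uhlenbeck) process, and the recall
error is a Gaussian average that can be evaluated by quadrature instead of
by simulation.

Notation: ``s_w`` is the fast-pathway contribution ``(w . x) * zhat`` to the
tested pattern's signed margin, ``s_h`` the slow-pathway contribution
``(v . y) * zhat``, ``tau = (P - nu) / N_x`` the normalized lag, ``kappa``
the margin, ``r = N_y / N_x``, and ``n_ratio = n_nu / nbar`` the tested
pattern's relative repetition count.

Derivation sketch (validated against Monte-Carlo simulation in the tests):

* For a random pattern in the stationary regime the total signed margin
  ``s = s_w + s_h`` is Gaussian with variance ``sigma_tot^2``; a supervised
  update fires with probability ``q = Phi(kappa / sigma_tot)``.
* Each subsequent supervised update moves the tested pattern's ``s_w`` by a
  random amount with conditional mean ``-q s_w / N_x`` (Stein's lemma
  applied to the trigger indicator) and variance ``C / N_x``, where
  ``C = E[(kappa - s)^2 ; s < kappa]``.  Over a lag ``tau`` this is an OU
  process with reversion rate ``q`` and stationary variance
  ``sigma_w^2 = C / (2 q)`` -- which is also the self-consistency condition
  fixing ``sigma_tot``.
* The Hebbian weights decay by ``alpha / (N_y nbar)`` per presentation and
  receive independent pattern-driven kicks, an OU process with rate
  ``alpha / (r nbar)`` per unit ``tau`` and stationary variance
  ``sigma_h^2 = beta^2 / (alpha nbar)``.
* Training the tested pattern sets its total margin to ``kappa`` if it was
  below (probability ``q``), and each of its ``n_nu`` repetitions adds
  ``sqrt(2) beta / nbar`` to ``s_h``.  The recall error is the probability
  that the OU-evolved total margin is negative at lag ``tau``, averaged
  over the stationary initial condition.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .results import TheoryCurve

__all__ = [
    "stationary_margin_stats",
    "theoretical_error_single",
    "theoretical_error_two_pathway",
    "theory_curve",
]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)


def _trigger_moment(sigma_tot: float, kappa: float) -> tuple[float, float]:
    """(q, C): update-trigger probability and conditional squared step."""
    k = kappa / sigma_tot
    q = norm.cdf(k)
    C = sigma_tot**2 * ((1 + k**2) * norm.cdf(k) + k * norm.pdf(k))
    return q, C


def stationary_margin_stats(beta: float = 0.0, alpha: float = 1.0,
                            nbar: float = 1.0, kappa: float = 1.0
                            ) -> tuple[float, float, float]:
    """Solve the stationary self-consistency for the margin statistics.

    Returns ``(sigma_w, sigma_h, q)``: the stationary standard deviations of
    the fast- and slow-pathway margin contributions of a random pattern, and
    the probability that presenting a random pattern triggers a supervised
    update.
    """
    if beta < 0 or alpha < 0:
        raise ValueError("alpha and beta must be nonnegative")
    if beta > 0 and alpha == 0:
        raise ValueError("a stationary regime requires alpha > 0 when beta > 0")
    sigma_h = beta / np.sqrt(alpha * nbar) if beta > 0 else 0.0

    def gap(sigma_w: float) -> float:
        sigma_tot = np.hypot(sigma_w, sigma_h)
        q, C = _trigger_moment(sigma_tot, kappa)
        return sigma_w**2 - C / (2 * q)

    hi = 10.0 * max(1.0, kappa, sigma_h)
    sigma_w = optimize.brentq(gap, 1e-9, hi, rtol=1e-12)
    q, _ = _trigger_moment(np.hypot(sigma_w, sigma_h), kappa)
    return float(sigma_w), float(sigma_h), float(q)


def theoretical_error_two_pathway(tau, ratio: float = 1.0, alpha: float = 1.0,
                                  beta: float = 1.0, n_ratio: float = 1.0,
                                  nbar: float = 1.0, kappa: float = 1.0):
    """Predicted recall error of the two-pathway model at lag ``tau``.

    Parameters mirror the generalized forgetting curve: the lag in units of
    ``N_x``, the pathway size ratio ``N_y / N_x``, the Hebbian decay and
    strength rates, and the tested pattern's repetition count relative to
    the mean.  ``beta = 0`` reduces to the single-pathway curve.  Scalar or
    array ``tau``.
    """
    taus = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(taus < 0):
        raise ValueError("tau must be nonnegative")
    if beta > 0 and ratio <= 0:
        raise ValueError("ratio N_y/N_x must be positive when beta > 0")

    sigma_w, sigma_h, q = stationary_margin_stats(beta, alpha, nbar, kappa)
    a_h = alpha / (ratio * nbar) if sigma_h > 0 else 0.0
    kick = np.sqrt(2.0) * beta * n_ratio

    if sigma_h > 0:
        s_hp = np.sqrt(2.0) * sigma_h * _GH_NODES
        hp_w = _GH_WEIGHTS / np.sqrt(np.pi)
    else:
        s_hp = np.zeros(1)
        hp_w = np.ones(1)

    out = np.empty_like(taus)
    for it, t in enumerate(taus):
        if t == 0.0:
            out[it] = 0.0
            continue
        dw = np.exp(-q * t)
        dh = np.exp(-a_h * t)
        sd = np.sqrt(sigma_w**2 * (1 - dw**2) + sigma_h**2 * (1 - dh**2))
        total = 0.0
        for shp, wgt in zip(s_hp, hp_w):
            s_h0 = shp + kick
            # branch 1: training triggered an update, s_w0 = kappa - s_hp
            p_trig = norm.cdf((kappa - shp) / sigma_w)
            mean1 = (kappa - shp) * dw + s_h0 * dh
            term1 = p_trig * norm.cdf(-mean1 / sd)
            # branch 2: margin already >= kappa, s_w0 from the upper tail
            def integrand(s_wp: float) -> float:
                mean2 = s_wp * dw + s_h0 * dh
                return (norm.pdf(s_wp / sigma_w) / sigma_w
                        * norm.cdf(-mean2 / sd))
            lo = kappa - shp
            term2, _ = integrate.quad(integrand, lo, lo + 8 * sigma_w,
                                      epsabs=1e-10, epsrel=1e-6)
            total += wgt * (term1 + term2)
        out[it] = total
    return out if np.ndim(tau) else float(out[0])


def theoretical_error_single(tau, kappa: float = 1.0):
    """Predicted recall error of the single-pathway margin perceptron."""
    return theoretical_error_two_pathway(tau, ratio=0.0, alpha=1.0, beta=0.0,
                                         n_ratio=1.0, kappa=kappa)


def theory_curve(taus, ratio: float = 1.0, alpha: float = 1.0,
                 beta: float = 1.0, n_ratio: float = 1.0, nbar: float = 1.0,
                 kappa: float = 1.0) -> TheoryCurve:
    """Evaluate the predicted forgetting curve on a lag grid."""
    taus = np.asarray(taus, dtype=float)
    err = theoretical_error_two_pathway(taus, ratio, alpha, beta, n_ratio,
                                        nbar, kappa)
    return TheoryCurve(tau=taus, error=np.asarray(err),
                       params={"ratio": ratio, "alpha": alpha, "beta": beta,
                               "n_ratio": n_ratio, "nbar": nbar,
                               "kappa": kappa})
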