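"""Displacement-assay analysis: tracer K_D fit, Hill EC50 fit and exact K_i.

The chain mirrors a TRIC (temperature-related intensity change) competition
experiment: a fluorescent tracer peptide C is pre-bound to the target protein
T, an unlabelled competitor L displaces it, and the normalized fluorescence
F_norm traces the bound-tracer fraction.  A Hill fit of F_norm against
competitor concentration yields an EC50, which is converted to the
competitor's true dissociation constant K_i with the exact bound-fraction
correction

    K_i = K_D / (2 - gamma) * ( EC50 / ( T_t/gamma - K_D/(2-gamma) - C_t/2 ) - gamma )

where gamma is the equilibrium bound fraction of tracer in the absence of
competitor,

    gamma = ( T_t + C_t + K_D - sqrt((T_t + C_t + K_D)^2 - 4 T_t C_t) ) / (2 C_t),

T_t and C_t the total target and tracer concentrations and K_D the tracer's
dissociation constant.  A brute-force three-species equilibrium solver serves
as the independent oracle for both closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq, least_squares

from .types import CompetitionSetup, HillFit

__all__ = [
    "gamma",
    "ki_from_ec50",
    "solve_competitive_equilibrium",
    "exact_ec50",
    "fit_direct_kd",
    "fit_hill",
]


class AssayWindowError(ValueError):
    """Tracer/target too concentrated relative to the measured EC50."""


def gamma(setup: CompetitionSetup) -> float:
    """Equilibrium bound fraction of tracer with no competitor present.

    Closed-form root of the two-species binding quadratic; equals TC/C_t.
    Always in (0, min(1, T_t/C_t)].
    """
    T, C, K = setup.T_t, setup.C_t, setup.K_D_tracer
    s = T + C + K
    disc = s * s - 4.0 * T * C
    if disc < 0:  # impossible for positive inputs; numerical guard only
        raise ArithmeticError("negative discriminant in gamma()")
    # conjugate form of (s - sqrt(disc)) / (2C): avoids cancellation when
    # the bound fraction is small
    return 2.0 * T / (s + np.sqrt(disc))


def ki_from_ec50(ec50: float, setup: CompetitionSetup) -> float:
    """Convert a displacement EC50 to the competitor K_i (exact correction).

    Raises :class:`AssayWindowError` when the denominator
    ``T_t/gamma - K_D/(2-gamma) - C_t/2`` is not positive, or when the EC50
    falls at or below the displacement floor ``gamma * denominator`` (the
    midpoint a zero-affinity assay would show) — in both cases tracer/target
    are too concentrated relative to the measured EC50 and no positive K_i
    exists.
    """
    if ec50 <= 0:
        raise ValueError("EC50 must be positive")
    g = gamma(setup)
    K = setup.K_D_tracer
    denom = setup.T_t / g - K / (2.0 - g) - setup.C_t / 2.0
    if denom <= 0 or ec50 <= g * denom:
        raise AssayWindowError(
            "assay window violated: EC50 at or below the zero-affinity floor "
            f"(EC50 {ec50:.3g} M, floor {g * max(denom, 0.0):.3g} M); "
            "reduce tracer/target concentrations"
        )
    return K / (2.0 - g) * (ec50 / denom - g)


def solve_competitive_equilibrium(
    T_t: float, C_t: float, L_t: float, K_D: float, K_i: float
) -> tuple[float, float, float]:
    """Exact three-species competitive equilibrium (free T, TC, TL).

    Target T binds tracer C (constant ``K_D``) and competitor L (constant
    ``K_i``) in 1:1 complexes TC and TL.  Mass balance on the target reduces
    the system to one equation in free target T,

        T + C_t*T/(K_D+T) + L_t*T/(K_i+T) = T_t,

    whose left side is strictly increasing in T; it is bracketed on
    [0, T_t] and solved by Brent's method to ~1e-15 relative tolerance.
    Independent oracle for :func:`gamma` and :func:`ki_from_ec50`.
    """
    if min(T_t, C_t, L_t) < 0:
        raise ValueError("total concentrations must be non-negative")
    if not (K_D > 0 and K_i > 0):
        raise ValueError("dissociation constants must be positive")
    if T_t == 0:
        return 0.0, 0.0, 0.0

    def balance(T: float) -> float:
        return T + C_t * T / (K_D + T) + L_t * T / (K_i + T) - T_t

    T_free = brentq(balance, 0.0, T_t, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    TC = C_t * T_free / (K_D + T_free)
    TL = L_t * T_free / (K_i + T_free)
    return T_free, TC, TL


def bound_tracer_fraction(setup: CompetitionSetup, L_t: float, K_i: float) -> float:
    """TC/C_t at competitor concentration ``L_t`` from the exact equilibrium."""
    _, TC, _ = solve_competitive_equilibrium(
        setup.T_t, setup.C_t, L_t, setup.K_D_tracer, K_i
    )
    return TC / setup.C_t


def exact_ec50(setup: CompetitionSetup, K_i: float) -> float:
    """Competitor concentration at which the bound-tracer fraction is gamma/2.

    The true displacement midpoint (between the no-competitor level gamma and
    the full-displacement level 0), found by root bracketing on the exact
    equilibrium.  Feeding this EC50 to :func:`ki_from_ec50` returns ``K_i``
    up to solver tolerance — the oracle round-trip behind the closed form.
    """
    g = gamma(setup)
    target = g / 2.0

    def f(logL: float) -> float:
        return bound_tracer_fraction(setup, 10.0**logL, K_i) - target

    return 10.0 ** brentq(f, -15.0, 2.0, xtol=1e-13, maxiter=200)


# ---------------------------------------------------------------------------
# Direct tracer K_D fit (tight-binding quadratic isotherm)
# ---------------------------------------------------------------------------

def _quadratic_bound_fraction(T_t, C_t, K_D):
    s = T_t + C_t + K_D
    return (s - np.sqrt(s * s - 4.0 * T_t * C_t)) / (2.0 * C_t)


def fit_direct_kd(
    concs, signal, tracer_conc: float = 1e-9
) -> tuple[float, float, float, float]:
    """Fit the tracer-target K_D from a direct titration of the target.

    Model: signal = bottom + (top - bottom) * gamma(T=conc, C=tracer_conc, K_D),
    the tight-binding quadratic isotherm (exact, unlike the hyperbolic
    approximation, when K_D is comparable to the tracer concentration).

    Parameters are (K_D, bottom, top); K_D is optimized in log10 space.
    Returns (K_D, bottom, top, se_K_D).  Raises on non-identifiable
    (flat/degenerate) data.
    """
    concs = np.asarray(concs, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if len(concs) < 6:
        raise ValueError("need >= 6 concentrations spanning the transition")
    if np.ptp(signal) == 0:
        raise ValueError("non-identifiable: signal is constant")

    lo, hi = signal.min(), signal.max()

    def resid(p):
        kd = 10.0 ** p[0]
        return p[1] + (p[2] - p[1]) * _quadratic_bound_fraction(
            concs, tracer_conc, kd
        ) - signal

    best = None
    for kd0 in np.logspace(np.log10(concs[concs > 0].min()), np.log10(concs.max()), 7):
        res = least_squares(resid, x0=[np.log10(kd0), lo, hi], method="lm")
        if best is None or res.cost < best.cost:
            best = res
    kd = 10.0 ** best.x[0]
    se_kd = _param_se(best)[0] * kd * np.log(10.0)
    if not np.isfinite(se_kd) or se_kd > 10.0 * kd:
        raise ValueError("non-identifiable: K_D unconstrained by the data")
    return kd, best.x[1], best.x[2], se_kd


# ---------------------------------------------------------------------------
# Hill (four-parameter logistic) fit
# ---------------------------------------------------------------------------

def _param_se(res) -> np.ndarray:
    """Standard errors from a least_squares result (pseudo-inverse covariance)."""
    m, p = res.fun.size, res.x.size
    if m <= p:
        return np.zeros(p)
    s2 = 2.0 * res.cost / (m - p)
    cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit_hill(concs, f_norm) -> HillFit:
    """Fit a 4-parameter logistic in log10 concentration.

    y(c) = bottom + (top - bottom) / (1 + (c/EC50)^h), h in [0.3, 5].
    Orientation (displacement vs activation) is carried by top/bottom, so a
    reversed curve yields the same EC50.  For displacement-oriented data the
    bottom plateau is bounded to [0, 1.5*min(signal)], which stabilizes
    16-point fits.  When the fitted EC50 lies outside the concentration grid
    the estimate is flagged as a bound ("ec50_at_edge"); a fitted dynamic
    range indistinguishable from zero is flagged "no_transition".
    """
    concs = np.asarray(concs, dtype=float)
    y = np.asarray(f_norm, dtype=float)
    if len(concs) < 5:
        raise ValueError("need >= 5 points for a Hill fit")
    if np.any(concs <= 0):
        raise ValueError("concentrations must be strictly positive")

    order = np.argsort(concs)
    c_s, y_s = concs[order], y[order]
    logc = np.log10(c_s)
    descending = y_s[: len(y_s) // 2].mean() >= y_s[len(y_s) // 2:].mean()

    def model(p):
        logec50, h, top, bottom = p
        return bottom + (top - bottom) / (1.0 + 10.0 ** (h * (logc - logec50)))

    def resid(p):
        return model(p) - y_s

    lo_b = [logc.min() - 2.0, 0.3, -np.inf, -np.inf]
    hi_b = [logc.max() + 2.0, 5.0, np.inf, np.inf]
    if descending and y.min() >= 0:
        # displacement curve: pin the fully-displaced plateau near zero signal
        lo_b[3], hi_b[3] = 0.0, max(1.5 * y.min(), 1e-12)

    top0 = y_s[0] if descending else y_s[-1]
    bot0 = y_s[-1] if descending else y_s[0]
    if descending and y.min() >= 0:
        bot0 = min(max(bot0, lo_b[3]), hi_b[3])
    best = None
    for logec0 in np.linspace(logc.min(), logc.max(), 5):
        res = least_squares(
            resid, x0=[logec0, 1.0, top0, bot0], bounds=(lo_b, hi_b),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        if best is None or res.cost < best.cost:
            best = res

    logec50, h, top, bottom = best.x
    se = _param_se(best)
    ec50 = 10.0 ** logec50
    resid_sd = np.sqrt(2.0 * best.cost / max(len(y_s) - 4, 1))
    scale = max(np.abs(y_s).max(), 1e-300)
    flag = None
    if abs(top - bottom) < max(3.0 * resid_sd, 1e-3 * scale):
        flag = "no_transition"
    elif not (c_s.min() <= ec50 <= c_s.max()):
        flag = "ec50_at_edge"
    # report with displacement orientation: top = low-conc plateau
    return HillFit(
        ec50=ec50,
        hill_slope=h,
        top=top,
        bottom=bottom,
        se_ec50=se[0] * ec50 * np.log(10.0),
        se_hill=se[1],
        se_top=se[2],
        se_bottom=se[3],
        rss=2.0 * best.cost,
        flag=flag,
    )
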