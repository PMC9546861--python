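"""Double referencing and 1:1 single-exponential kinetic fitting.

The observable follows the pseudo-first-order 1:1 model: an association
transient S(t) = A (1 - exp(-k_obs t)) with k_obs = k_on*C + k_off, and a
dissociation decay S(t) = S0 exp(-k_off t).  The global fit shares k_on and
k_off across all analyte concentrations with one free amplitude per curve,
which is what separates the two rate constants even from sparse
concentration series.  Raw traces are corrected by double referencing —
subtracting a real-time reference spot and a blank (buffer) run — before
fitting.

Exponential least squares is initialization-sensitive; fits here use a
deterministic multi-start (log-spaced k_obs grid, best RSS, ties to the
smaller rate) plus data-driven starts from a log-linear dissociation fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares

from .types import KineticFit, PeptideArchitecture, SensorTrace

__all__ = [
    "double_reference",
    "fit_single_curve",
    "fit_global",
    "association_level",
    "build_rate_map",
    "ISO_AFFINITY_KDS",
]

#: Iso-affinity guide lines drawn on rate maps (K_D in molar).
ISO_AFFINITY_KDS = {"10 uM": 1e-5, "1 uM": 1e-6, "100 nM": 1e-7}

_KOBS_GRID = np.logspace(-4, 1, 13)  # s^-1, multi-start initial values


class GridMismatchError(ValueError):
    """Traces do not share an identical time grid / phase structure."""


def double_reference(
    meas: SensorTrace,
    ref: SensorTrace,
    blank_meas: SensorTrace,
    blank_ref: SensorTrace,
) -> SensorTrace:
    """Double-referencing correction: (meas - ref) - (blank_meas - blank_ref).

    All four traces must share the identical time grid and phase structure;
    no interpolation is attempted.  Phase labels and the measurement's
    analyte concentration are preserved.
    """
    for name, tr in (
        ("reference", ref),
        ("blank_measurement", blank_meas),
        ("blank_reference", blank_ref),
    ):
        if not meas.same_grid(tr):
            raise GridMismatchError(
                f"{name} trace grid does not match the measurement grid"
            )
    corrected = (meas.signal - ref.signal) - (blank_meas.signal - blank_ref.signal)
    return SensorTrace(
        time=meas.time.copy(),
        signal=corrected,
        phase=meas.phase.copy(),
        analyte_conc=meas.analyte_conc,
        spot_role="measurement",
        trace_id=meas.trace_id + ":corrected" if meas.trace_id else "corrected",
    )


# ---------------------------------------------------------------------------
# Single-curve fit
# ---------------------------------------------------------------------------

@dataclass
class SingleCurveFit:
    k_obs: float  # s^-1
    amplitude: float  # a.u.
    k_off: float  # s^-1; nan when no dissociation phase present
    se_k_obs: float = 0.0
    se_amplitude: float = 0.0
    se_k_off: float = 0.0
    rss: float = 0.0
    flag: str | None = None


def _fit_association(t: np.ndarray, y: np.ndarray):
    """Best-of-starts fit of A(1 - exp(-k t)); ties go to the smaller k."""
    a0 = y[-max(1, len(y) // 10):].mean()

    def model(t, a, k):
        return a * (1.0 - np.exp(np.clip(-k * t, None, 700.0)))

    best = None
    for k0 in _KOBS_GRID:
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[a0 if a0 != 0 else 1.0, k0], maxfev=5000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((model(t, *popt) - y) ** 2))
        if (
            best is None
            or rss < best[2] * (1 - 1e-12)
            or (abs(rss - best[2]) <= 1e-12 * max(best[2], 1.0) and popt[1] < best[0][1])
        ):
            best = (popt, pcov, rss)
    if best is None:
        return None
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return float(popt[0]), abs(float(popt[1])), float(se[0]), float(se[1]), rss


def _fit_dissociation(t: np.ndarray, y: np.ndarray):
    """Fit S0 exp(-k t); log-linear initialization when signals allow."""
    s0_init = y[0] if y[0] != 0 else max(y.max(), 1.0)
    k_init = 1e-3
    pos = y > 0.05 * max(abs(y).max(), 1e-300)
    if pos.sum() >= 3:
        slope, icpt = np.polyfit(t[pos], np.log(y[pos]), 1)
        if slope < 0:
            k_init = -slope
            s0_init = np.exp(icpt)

    def model(t, s0, k):
        return s0 * np.exp(np.clip(-k * t, None, 700.0))

    try:
        popt, pcov = curve_fit(model, t, y, p0=[s0_init, k_init], maxfev=5000)
    except RuntimeError:
        return None
    rss = float(np.sum((model(t, *popt) - y) ** 2))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return float(popt[0]), abs(float(popt[1])), float(se[1]), rss


def fit_single_curve(trace: SensorTrace, conc: float | None = None) -> SingleCurveFit:
    """Fit one double-referenced trace: association k_obs/A and (if present)
    dissociation k_off.

    Flags the result "not_determinable" when the fitted amplitude is below
    3x the residual noise SD or any relative standard error exceeds 100%.
    """
    t_a = trace.phase_time("association")
    y_a = trace.phase_signal("association")
    if len(t_a) < 10:
        raise ValueError("association phase needs >= 10 points")
    res_a = _fit_association(t_a, y_a)
    if res_a is None:
        return SingleCurveFit(np.nan, np.nan, np.nan, flag="not_determinable")
    amp, k_obs, se_amp, se_kobs, rss = res_a

    k_off, se_koff = np.nan, 0.0
    t_d = trace.phase_time("dissociation")
    if len(t_d) >= 3:
        res_d = _fit_dissociation(t_d, trace.phase_signal("dissociation"))
        if res_d is not None:
            _, k_off, se_koff, rss_d = res_d
            rss += rss_d

    n_pts = len(t_a) + len(t_d)
    noise_sd = np.sqrt(rss / max(n_pts - 4, 1))
    flag = None
    if abs(amp) < max(3.0 * noise_sd, 1e-12):
        flag = "not_determinable"
    elif not np.isfinite(se_kobs) or se_kobs > abs(k_obs) or se_amp > abs(amp):
        flag = "not_determinable"
    return SingleCurveFit(
        k_obs=k_obs,
        amplitude=amp,
        k_off=k_off,
        se_k_obs=se_kobs,
        se_amplitude=se_amp,
        se_k_off=se_koff,
        rss=rss,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# Global fit
# ---------------------------------------------------------------------------

def fit_global(traces: list[SensorTrace], concs: list[float] | None = None) -> KineticFit:
    """Global 1:1 fit: shared k_on/k_off, one amplitude per concentration.

    Model per curve i (analyte concentration C_i):
    association  A_i (1 - exp(-(k_on C_i + k_off) t)),
    dissociation continues from the association end level with exp(-k_off t).
    Rates are optimized in log space; standard errors come from the residual
    Jacobian at the optimum.  When the k_off standard error exceeds the
    estimate itself, K_D is only an upper bound and the fit is flagged
    "koff_upper_bound".
    """
    if not traces:
        raise ValueError("need at least one trace")
    if concs is None:
        concs = [tr.analyte_conc for tr in traces]
    if len(concs) != len(traces):
        raise ValueError("one concentration per trace required")
    concs = [float(c) for c in concs]
    if any(c <= 0 for c in concs):
        raise ValueError("analyte concentrations must be positive")

    segs = []  # (C, t_assoc, y_assoc, T_assoc_end, t_diss, y_diss)
    any_diss = False
    for tr, c in zip(traces, concs):
        t_a, y_a = tr.phase_time("association"), tr.phase_signal("association")
        if len(t_a) < 10:
            raise ValueError("association phase needs >= 10 points")
        t_d, y_d = tr.phase_time("dissociation"), tr.phase_signal("dissociation")
        any_diss |= len(t_d) > 0
        dt = np.median(np.diff(t_a))
        segs.append((c, t_a, y_a, t_a[-1] + dt, t_d, y_d))
    if len(set(concs)) < 2 and not any_diss:
        raise ValueError(
            "k_on and k_off are not separable: single concentration and no "
            "dissociation phase"
        )

    n = len(segs)

    def residuals(p):
        k_on, k_off = np.exp(np.clip(p[0], -60, 60)), np.exp(np.clip(p[1], -60, 60))
        amps = p[2:]
        out = []
        for (c, t_a, y_a, t_end, t_d, y_d), a in zip(segs, amps):
            k_obs = k_on * c + k_off
            out.append(a * (1.0 - np.exp(np.clip(-k_obs * t_a, None, 700.0))) - y_a)
            if len(t_d):
                s_end = a * (1.0 - np.exp(np.clip(-k_obs * t_end, None, 700.0)))
                out.append(s_end * np.exp(np.clip(-k_off * t_d, None, 700.0)) - y_d)
        return np.concatenate(out)

    # data-driven start: per-curve k_obs, pooled dissociation k_off
    kobs0, koff0s = [], []
    for c, t_a, y_a, _, t_d, y_d in segs:
        res = _fit_association(t_a, y_a)
        if res is not None:
            kobs0.append((c, res[1]))
        if len(t_d) >= 3:
            res_d = _fit_dissociation(t_d, y_d)
            if res_d is not None and res_d[1] > 0:
                koff0s.append(res_d[1])
    koff0 = float(np.median(koff0s)) if koff0s else 1e-3
    if kobs0:
        kon_cands = [(k - koff0) / c for c, k in kobs0 if k > koff0]
        kon0 = float(np.median(kon_cands)) if kon_cands else 1e4
    else:
        kon0 = 1e4
    amps0 = [max(abs(y_a).max(), 1e-6) for _, _, y_a, _, _, _ in segs]

    starts = [[np.log(max(kon0, 1e-3)), np.log(max(koff0, 1e-8))] + list(amps0)]
    for kon_g in (1e3, 1e5, 1e7):
        starts.append([np.log(kon_g), np.log(koff0)] + list(amps0))
    best = None
    for x0 in starts:
        res = least_squares(residuals, x0=x0, method="lm", max_nfev=20000)
        if best is None or res.cost < best.cost * (1 - 1e-12):
            best = res

    k_on, k_off = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    amps = {c: float(a) for (c, *_), a in zip(segs, best.x[2:])}
    m = best.fun.size
    p_n = best.x.size
    rss = float(2.0 * best.cost)
    se_log = np.zeros(p_n)
    if m > p_n:
        s2 = rss / (m - p_n)
        cov = np.linalg.pinv(best.jac.T @ best.jac) * s2
        se_log = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se_kon, se_koff = k_on * se_log[0], k_off * se_log[1]

    noise_sd = np.sqrt(rss / max(m - p_n, 1))
    max_amp = max(abs(a) for a in amps.values())
    flag = None
    if max_amp < 3.0 * noise_sd or (se_kon > k_on and se_koff > k_off):
        flag = "not_determinable"
    elif se_koff > k_off:
        flag = "koff_upper_bound"

    level = np.nan
    try:
        level = association_level(traces[int(np.argmax(concs))]).level
    except ValueError:
        pass
    return KineticFit(
        k_on=k_on,
        k_off=k_off,
        amplitudes=amps,
        association_level=level,
        se_k_on=float(se_kon),
        se_k_off=float(se_koff),
        rss=rss,
        n_curves=n,
        flag=flag,
    )


# ---------------------------------------------------------------------------
# Association level
# ---------------------------------------------------------------------------

@dataclass
class AssociationLevel:
    """Plateau of the association phase: raw tail mean (primary) and the
    fitted exponential amplitude (reported alongside)."""

    level: float
    fitted_amplitude: float


def association_level(trace: SensorTrace) -> AssociationLevel:
    """Mean of the final 10% of association-phase points, plus the fitted
    plateau A of A(1 - exp(-k t))."""
    y = trace.phase_signal("association")
    if len(y) < 10:
        raise ValueError("association phase needs >= 10 points")
    n_tail = max(1, int(np.ceil(0.1 * len(y))))
    tail_mean = float(y[-n_tail:].mean())
    res = _fit_association(trace.phase_time("association"), y)
    fitted = float(res[0]) if res is not None else np.nan
    return AssociationLevel(level=tail_mean, fitted_amplitude=fitted)


# ---------------------------------------------------------------------------
# Rate map
# ---------------------------------------------------------------------------

def build_rate_map(
    fits: dict[str, KineticFit], library: list[PeptideArchitecture]
) -> pd.DataFrame:
    """Join fits with architectures into a rate-map table.

    Non-determinable fits are excluded.  Each entry is annotated with the
    iso-affinity band its K_D falls on (guide lines at 10 uM, 1 uM, 100 nM;
    an entry within 5% of a line is labelled with it).
    """
    by_id: dict[str, PeptideArchitecture] = {}
    for a in library:
        if a.id in by_id:
            raise ValueError(f"duplicate architecture id {a.id!r}")
        by_id[a.id] = a
    rows = []
    for pid, fit in fits.items():
        if not fit.determinable:
            continue
        if pid not in by_id:
            raise KeyError(f"fit id {pid!r} not present in library")
        arch = by_id[pid]
        kd = fit.K_D
        iso = ""
        for label, line in ISO_AFFINITY_KDS.items():
            if abs(np.log10(kd / line)) < np.log10(1.05):
                iso = label
                break
        rows.append(
            {
                "id": pid,
                "k_on": fit.k_on,
                "k_off": fit.k_off,
                "K_D": kd,
                "valency": arch.valency,
                "epitope_length": arch.epitope_length,
                "tokens": arch.token_string,
                "iso_affinity": iso,
                "kd_is_bound": fit.kd_is_bound,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "k_on",
            "k_off",
            "K_D",
            "valency",
            "epitope_length",
            "tokens",
            "iso_affinity",
            "kd_is_bound",
        ],
    )
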