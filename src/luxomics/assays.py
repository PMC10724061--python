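"""Quantitative assay models: Michaelis-Menten effector kinetics, FRAP
recovery fitting, chlorophyll equations, ΔΔCt and m6A/A normalization.

The kinetics route treats plate-reader luminescence endpoints as initial
rates (signal per minute); absolute calibration to product amounts is not
attempted, so Vmax and kcat carry the signal unit. The FRAP route follows
the common two-step normalization (double normalization against a reference
ROI, then full-scale normalization so the pre-bleach plateau is 1 and the
first post-bleach frame is 0) and fits the double-exponential recovery
I(t) = I0 - alpha*exp(-beta*t) - gamma*exp(-delta*t); for a full-scale
normalized curve the mobile fraction equals I0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "KineticSeries", "MMFit", "FrapTrace", "FrapFit", "AbsorbanceRecord", "CtRecord",
    "subtract_background", "fit_michaelis_menten", "effector_fold_change",
    "normalize_frap", "fit_frap", "recovery_at", "half_recovery_time",
    "chlorophyll_content", "delta_delta_ct", "normalize_m6a_ratio",
]


# ---------------------------------------------------------------------------
# Michaelis-Menten kinetics

@dataclass
class KineticSeries:
    """Initial-rate series over substrate concentrations.

    ``rate`` has shape (n_concentrations, n_replicates); ``background`` is the
    no-substrate signal, ``enzyme_conc`` the enzyme concentration in µM.
    """

    substrate_conc: np.ndarray  # µM
    rate: np.ndarray            # signal / min
    background: float = 0.0
    enzyme_conc: float = 1.0    # µM

    def __post_init__(self) -> None:
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.atleast_2d(np.asarray(self.rate, dtype=float))
        if self.rate.shape[0] != self.substrate_conc.size:
            self.rate = self.rate.T
        if self.rate.shape[0] != self.substrate_conc.size:
            raise ValueError("rate rows must match substrate concentrations")
        if np.any(self.substrate_conc < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if self.enzyme_conc <= 0:
            raise ValueError("enzyme_conc must be > 0")
        if np.unique(self.substrate_conc).size < 4:
            raise ValueError("need >= 4 distinct substrate concentrations for identifiability")


@dataclass
class MMFit:
    km: float                 # µM
    vmax: float               # signal / min
    kcat: float               # 1 / min
    catalytic_efficiency: float  # kcat / Km
    km_se: float
    vmax_se: float
    converged: bool
    message: str = ""


def subtract_background(series: KineticSeries) -> KineticSeries:
    """Net rates: max(rate - background, 0); the number of clipped values is logged."""
    net = series.rate - series.background
    n_clip = int((net < 0).sum())
    if n_clip:
        logger.info("subtract_background clipped %d negative net rate(s) to 0", n_clip)
    return KineticSeries(
        substrate_conc=series.substrate_conc.copy(),
        rate=np.maximum(net, 0.0),
        background=0.0,
        enzyme_conc=series.enzyme_conc,
    )


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Km, Vmax) from the Hanes-Woolf line S/v = S/Vmax + Km/Vmax."""
    mask = (v > 0) & (s > 0)
    if mask.sum() < 2:
        return 1.0, max(float(v.max()), 1e-12)
    slope, intercept = np.polyfit(s[mask], s[mask] / v[mask], 1)
    if slope <= 0:
        return float(np.median(s[mask])), max(float(v.max()), 1e-12)
    vmax0 = 1.0 / slope
    km0 = max(intercept * vmax0, 1e-9)
    return km0, vmax0


def fit_michaelis_menten(series: KineticSeries) -> MMFit:
    """Least-squares fit of v = Vmax*S/(Km+S) on replicate-mean net rates."""
    s = series.substrate_conc
    v = series.rate.mean(axis=1)
    if np.all(v <= 0):
        return MMFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, "all rates zero")
    km0, vmax0 = _hanes_woolf_init(s, v)

    def mm(s_, vmax, km):
        return vmax * s_ / (km + s_)

    try:
        popt, pcov = curve_fit(
            mm, s, v, p0=[vmax0, km0], bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000
        )
    except RuntimeError as exc:
        return MMFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, False, str(exc))
    vmax, km = popt
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    at_bound = km <= 2e-12 or not np.isfinite(km)
    kcat = vmax / series.enzyme_conc
    return MMFit(
        km=float(km),
        vmax=float(vmax),
        kcat=float(kcat),
        catalytic_efficiency=float(kcat / km) if km > 0 else np.nan,
        km_se=float(se[1]),
        vmax_se=float(se[0]),
        converged=not at_bound,
        message="Km at bound" if at_bound else "",
    )


def effector_fold_change(ce_with_effector: float, ce_basal: float) -> float:
    """Catalytic-efficiency fold change relative to the basal enzyme (basal = 1.0)."""
    if ce_basal <= 0:
        raise ValueError("basal catalytic efficiency must be > 0")
    return ce_with_effector / ce_basal


# ---------------------------------------------------------------------------
# FRAP

@dataclass
class FrapTrace:
    """Raw FRAP trace: bleach happens between frames n_prebleach-1 and n_prebleach."""

    time: np.ndarray            # seconds, bleach at t=0
    bleached_roi: np.ndarray
    reference_roi: np.ndarray
    n_prebleach: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.bleached_roi = np.asarray(self.bleached_roi, dtype=float)
        self.reference_roi = np.asarray(self.reference_roi, dtype=float)
        if not (len(self.time) == len(self.bleached_roi) == len(self.reference_roi)):
            raise ValueError("time and ROI vectors must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if not 1 <= self.n_prebleach < len(self.time):
            raise ValueError("n_prebleach must be >= 1 and < trace length")


def normalize_frap(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double + full-scale normalization.

    Double normalization corrects acquisition photobleaching against the
    reference ROI: d(t) = (ref_pre / ref(t)) * (I(t) / I_pre) with pre-bleach
    means I_pre, ref_pre. Full-scale normalization then maps the pre-bleach
    plateau to 1 and the first post-bleach frame to 0:
    f(t) = (d(t) - d(t0+)) / (1 - d(t0+)).

    Returns (post-bleach times, full-scale-normalized post-bleach values),
    with time counted from the first post-bleach frame.
    """
    if np.any(trace.reference_roi <= 0):
        raise ValueError("reference ROI must be positive throughout")
    n0 = trace.n_prebleach
    i_pre = trace.bleached_roi[:n0].mean()
    ref_pre = trace.reference_roi[:n0].mean()
    if i_pre <= 0:
        raise ValueError("pre-bleach intensity must be positive")
    d = (ref_pre / trace.reference_roi) * (trace.bleached_roi / i_pre)
    d0 = d[n0]
    if d0 >= 1.0:
        raise ValueError("no bleach depth: first post-bleach frame >= pre-bleach level")
    f = (d - d0) / (1.0 - d0)
    t = trace.time[n0:] - trace.time[n0]
    return t, f[n0:]


@dataclass
class FrapFit:
    i0: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    residual_norm: float
    converged: bool
    message: str = ""

    @property
    def mobile_fraction(self) -> float:
        return self.i0


def _frap_model(t, i0, alpha, beta, gamma, delta):
    return i0 - alpha * np.exp(-beta * t) - gamma * np.exp(-delta * t)


def fit_frap(time: np.ndarray, normalized: np.ndarray) -> FrapFit:
    """Fit I(t) = I0 - alpha*e^(-beta t) - gamma*e^(-delta t) with beta >= delta >= 0.

    Multi-start least squares: the bleach depth I0 - f(0) is split between the
    fast and slow components in several proportions, with rate starts from the
    early and late slopes. The component order beta >= delta is enforced by
    relabelling after the fit (the model is symmetric under component swap).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(normalized, dtype=float)
    if t.size < 8:
        raise ValueError("need >= 8 post-bleach points to fit the double exponential")
    if np.allclose(y, y[0]):
        return FrapFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False, "flat trace")

    plateau0 = float(np.mean(y[max(len(y) - 5, len(y) // 2):]))
    depth0 = max(plateau0 - y[0], 1e-6)
    # crude rate scales from the time to half recovery and the trace span
    above = np.nonzero(y >= y[0] + depth0 / 2)[0]
    t_half = t[above[0]] if above.size else t[-1] / 2.0
    k_fast = np.log(2) / max(t_half, t[1] - t[0], 1e-9)
    k_slow = np.log(2) / max(t[-1] / 2.0, 1e-9)

    best = None
    for frac in (0.3, 0.5, 0.7):
        p0 = [plateau0, depth0 * frac, k_fast, depth0 * (1 - frac), k_slow]
        try:
            popt, _ = curve_fit(
                _frap_model, t, y, p0=p0,
                bounds=([-np.inf, 0.0, 0.0, 0.0, 0.0], [np.inf] * 5),
                maxfev=50000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(_frap_model(t, *popt) - y))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        return FrapFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.inf, False, "non-convergence")
    (i0, alpha, beta, gamma, delta), resid = best
    if beta < delta:  # relabel so beta is the fast rate
        alpha, beta, gamma, delta = gamma, delta, alpha, beta
    return FrapFit(float(i0), float(alpha), float(beta), float(gamma), float(delta), resid, True)


def recovery_at(fit: FrapFit, t: float) -> float:
    """Fitted recovery at time t; the t -> infinity limit is the mobile fraction."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    if t < 0:
        raise ValueError("t must be >= 0")
    if np.isinf(t):
        return fit.i0
    return float(_frap_model(t, fit.i0, fit.alpha, fit.beta, fit.gamma, fit.delta))


def half_recovery_time(fit: FrapFit) -> float:
    """Time to recover 50% of (I0 - f(0)); a neutral summary of recovery speed."""
    f0 = recovery_at(fit, 0.0)
    target = f0 + 0.5 * (fit.i0 - f0)
    lo, hi = 0.0, 1.0
    while recovery_at(fit, hi) < target and hi < 1e9:
        hi *= 2.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if recovery_at(fit, mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Chlorophyll

@dataclass
class AbsorbanceRecord:
    a646: float
    a663: float
    fresh_weight: float = 1.0   # g
    extract_volume: float = 10.0  # ml

    def __post_init__(self) -> None:
        if self.a646 < 0 or self.a663 < 0:
            raise ValueError("absorbances must be >= 0")


def chlorophyll_content(rec: AbsorbanceRecord) -> dict[str, float]:
    """Chlorophyll a/b from 646/663 nm absorbances in 80% acetone.

    chl_a = 12.21*A663 - 2.81*A646 and chl_b = 20.13*A646 - 5.03*A663 (µg/ml);
    total per fresh weight = total * volume / weight / 1000 (mg/g FW).
    A negative concentration (mis-set blank) is reported with a warning flag.
    """
    chl_a = 12.21 * rec.a663 - 2.81 * rec.a646
    chl_b = 20.13 * rec.a646 - 5.03 * rec.a663
    total = chl_a + chl_b
    warn = chl_a < 0 or chl_b < 0
    if warn:
        logger.warning("negative chlorophyll concentration (chl_a=%.3f, chl_b=%.3f)", chl_a, chl_b)
    return {
        "chl_a_ug_ml": chl_a,
        "chl_b_ug_ml": chl_b,
        "total_ug_ml": total,
        "total_mg_g_fw": total * rec.extract_volume / rec.fresh_weight / 1000.0,
        "warning": warn,
    }


# ---------------------------------------------------------------------------
# MeRIP-qPCR and LC-MS/MS ratios

@dataclass
class CtRecord:
    """qPCR cycle thresholds for target and spike-in in the IP and input fractions.

    By default the m6A spike-in normalizes the IP and the non-m6A spike-in
    normalizes the input; the record just carries the paired Cts.
    """

    ct_target_ip: float
    ct_spike_ip: float
    ct_target_input: float
    ct_spike_input: float

    def __post_init__(self) -> None:
        for v in (self.ct_target_ip, self.ct_spike_ip, self.ct_target_input, self.ct_spike_input):
            if not np.isfinite(v):
                raise ValueError("Ct values must be finite")


def delta_delta_ct(rec: CtRecord) -> float:
    """Relative m6A level 2^(-ΔΔCt) with
    ΔΔCt = (Ct_target_IP - Ct_spike_IP) - (Ct_target_input - Ct_spike_input)."""
    ddct = (rec.ct_target_ip - rec.ct_spike_ip) - (rec.ct_target_input - rec.ct_spike_input)
    return float(2.0 ** (-ddct))


def normalize_m6a_ratio(ratios: Mapping[str, float], reference: str = "WT") -> dict[str, float]:
    """Divide each genotype's m6A/A ratio by the reference genotype's (WT -> 1)."""
    if reference not in ratios:
        raise KeyError(f"reference genotype {reference!r} not in ratios")
    ref = ratios[reference]
    if ref <= 0:
        raise ValueError("reference ratio must be > 0")
    return {k: v / ref for k, v in ratios.items()}
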