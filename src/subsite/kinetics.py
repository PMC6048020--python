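"""Enzyme-kinetic characterization for serine proteases.

Covers the standard assay repertoire around a chromogenic/fluorogenic
substrate panel:

* initial-rate estimation from progress curves,
* Michaelis-Menten fits (v = kcat * E_active * S / (KM + S)) with the
  catalytic efficiency kcat/KM and propagated standard errors,
* active-site burst titration with NPGB
  (A(t) = pi * (1 - exp(-k t)) + m t + A0; pi reports the molarity of
  active enzyme through the chromophore extinction coefficient),
* four-parameter log-logistic dose-response (IC50/EC50) fits,
* inhibition-mechanism classification (competitive / noncompetitive /
  uncompetitive / mixed) by global fitting and AICc model selection, with
  Eadie-Hofstee diagnostics,
* hyperbolic activation fits (e.g. Ca2+ stimulation), with an optional
  high-concentration attenuation term.

All fits are deterministic nonlinear least squares (lmfit/Levenberg-
Marquardt) initialized from linearizations of the respective models.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import lmfit

log = logging.getLogger(__name__)

#: default extinction coefficients (M^-1 cm^-1); overridable per call
EPSILON_PNP_410: float = 16600.0  # p-nitrophenol, 410 nm, pH 8.0
EPSILON_PNA_405: float = 9920.0  # p-nitroaniline, 405 nm

MECHANISMS = ("competitive", "noncompetitive", "uncompetitive", "mixed")


class FitError(RuntimeError):
    pass


class NotAnActivatorError(FitError):
    """Rates decrease with modifier concentration; no activation to fit."""


class NoTransitionError(FitError):
    """Dose-response data show no resolvable transition (top ~ bottom)."""


@dataclass
class ProgressCurve:
    """A time course of product signal (absorbance or fluorescence).

    ``calibration`` converts signal units to product concentration
    (signal units per µM product); ``substrate_uM`` (if known) lets the
    initial-rate window be capped at a fraction of substrate consumed.
    """

    times: np.ndarray  # s, strictly increasing
    signal: np.ndarray
    calibration: float = 1.0  # signal units per µM product
    path_length: float = 1.0  # cm, absorbance only
    substrate_uM: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.size < 4:
            raise ValueError("a progress curve needs at least 4 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size != self.signal.size:
            raise ValueError("times and signal must have equal length")


@dataclass
class KineticSeries:
    """Initial rates versus substrate concentration at one modifier level."""

    substrate_uM: np.ndarray
    rates: np.ndarray  # µM/s
    enzyme_total_nM: float = 1.0
    active_fraction: float = 1.0
    modifier: str = ""
    modifier_uM: float = 0.0
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.substrate_uM = np.asarray(self.substrate_uM, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.substrate_uM <= 0):
            raise ValueError("substrate concentrations must be positive")
        if np.any(self.rates < 0):
            raise ValueError("rates must be nonnegative")

    @property
    def enzyme_active_uM(self) -> float:
        return self.enzyme_total_nM * self.active_fraction / 1000.0


# --------------------------------------------------------------- initial rate

def estimate_initial_rate(
    curve: ProgressCurve, max_fraction_consumed: float = 0.10
) -> float:
    """Initial velocity (µM/s) from the linear early phase of a curve.

    The fit window covers at most ``max_fraction_consumed`` of the
    substrate (when the substrate concentration is known) but never fewer
    than 10% of the points or 4 points.
    """
    if curve.calibration <= 0:
        raise ValueError("calibration must be positive")
    t, y = curve.times, curve.signal
    n = t.size
    n_min = max(4, int(math.ceil(0.10 * n)))
    if curve.substrate_uM is not None:
        product = (y - y[0]) / curve.calibration
        limit = max_fraction_consumed * curve.substrate_uM
        within = np.nonzero(product <= limit)[0]
        n_win = (within[-1] + 1) if within.size else 0
        n_win = max(n_win, n_min)
    else:
        n_win = n
    n_win = min(n_win, n)
    if n_win < 4:
        raise ValueError("fewer than 4 usable points in the initial window")
    slope = np.polyfit(t[:n_win], y[:n_win], 1)[0]
    return float(slope / curve.calibration)


# ----------------------------------------------------------- Michaelis-Menten

@dataclass
class MMFit:
    kcat: float  # s^-1
    km: float  # µM
    kcat_se: float
    km_se: float
    efficiency: float  # M^-1 s^-1
    efficiency_se: float
    vmax: float  # µM/s
    covariance: np.ndarray | None
    flagged: bool = False
    flag_reason: str = ""


def catalytic_efficiency(kcat: float, km_uM: float) -> float:
    """kcat/KM as a second-order rate constant in M^-1 s^-1."""
    return kcat / (km_uM * 1e-6)


def _hanes_woolf_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Vmax, KM starting values from the S/v-vs-S linearization."""
    ok = v > 0
    slope, intercept = np.polyfit(s[ok], s[ok] / v[ok], 1)
    if slope <= 0:
        return float(v.max()), float(np.median(s))
    vmax0 = 1.0 / slope
    km0 = intercept / slope
    if km0 <= 0:
        km0 = float(np.median(s))
    return float(vmax0), float(km0)


def fit_michaelis_menten(series: KineticSeries, weighting: str = "none") -> MMFit:
    """Nonlinear least-squares fit of v = kcat * E_active * S / (KM + S).

    The turnover number uses the *active* enzyme concentration (from a
    burst titration), so preparations that are partially active do not
    depress kcat.  Initial values come from a Hanes-Woolf linearization.
    ``weighting="relative"`` minimizes relative residuals, appropriate
    when measurement error scales with the rate (multiplicative noise).
    """
    if weighting not in ("none", "relative"):
        raise ValueError("weighting must be 'none' or 'relative'")
    s, v = series.substrate_uM, series.rates
    if np.unique(s).size < 5:
        raise ValueError("need at least 5 distinct substrate concentrations")
    e_uM = series.enzyme_active_uM
    if e_uM <= 0:
        raise ValueError("active enzyme concentration must be positive")
    vmax0, km0 = _hanes_woolf_init(s, v)
    params = lmfit.Parameters()
    params.add("kcat", value=max(vmax0 / e_uM, 1e-9), min=1e-12)
    params.add("km", value=max(km0, 1e-6), min=1e-9)

    def resid(p):
        model = p["kcat"].value * e_uM * s / (p["km"].value + s)
        return (model - v) / model if weighting == "relative" else model - v

    out = lmfit.minimize(resid, params, method="leastsq")
    kcat = out.params["kcat"].value
    km = out.params["km"].value
    kcat_se = out.params["kcat"].stderr or np.nan
    km_se = out.params["km"].stderr or np.nan
    eff = catalytic_efficiency(kcat, km)
    cov = getattr(out, "covar", None)
    if cov is not None and np.all(np.isfinite(cov)):
        g = np.array([1.0 / km, -kcat / km**2]) * 1e6
        eff_se = float(np.sqrt(g @ cov @ g))
    else:
        eff_se = np.nan
    flagged, reason = False, ""
    if not out.success:
        flagged, reason = True, "fit did not converge"
    elif not (0.01 * s.min() <= km <= 100.0 * s.max()):
        flagged, reason = True, "KM outside 0.01x-100x the design range"
    if flagged:
        log.warning("Michaelis-Menten fit flagged: %s", reason)
    return MMFit(
        kcat=float(kcat),
        km=float(km),
        kcat_se=float(kcat_se),
        km_se=float(km_se),
        efficiency=float(eff),
        efficiency_se=eff_se,
        vmax=float(kcat * e_uM),
        covariance=cov,
        flagged=flagged,
        flag_reason=reason,
    )


# ------------------------------------------------------------ burst titration

@dataclass
class BurstFit:
    burst_amplitude: float  # signal units (pi)
    k_burst: float  # s^-1
    steady_slope: float  # signal units / s
    baseline: float
    active_conc_nM: float
    active_fraction_pct: float
    flagged: bool = False
    flag_reason: str = ""


def fit_burst_titration(
    curve: ProgressCurve,
    epsilon: float = EPSILON_PNP_410,
    path_length: float | None = None,
    enzyme_total_nM: float = 100.0,
) -> BurstFit:
    """Active-site titration from a burst progress curve.

    NPGB acylates the active site rapidly (the exponential burst, one
    chromophore per active enzyme) and deacylates slowly (the linear
    steady state).  Fitting A(t) = pi*(1 - exp(-k t)) + m*t + A0 gives the
    burst amplitude pi, converted via Beer-Lambert to the molar
    concentration of active enzyme and the active fraction of the
    preparation.
    """
    if epsilon <= 0:
        raise ValueError("extinction coefficient must be positive")
    ell = path_length if path_length is not None else curve.path_length
    t, y = curve.times, curve.signal
    tail = t.size // 2
    m0 = max(np.polyfit(t[tail:], y[tail:], 1)[0], 0.0)
    pi0 = max(float(y[-1] - m0 * t[-1] - y[0]), 1e-6 * max(abs(y).max(), 1.0))
    k0 = 3.0 / max(t[min(3, t.size - 1)], 1e-9)
    params = lmfit.Parameters()
    params.add("pi", value=pi0, min=0)
    params.add("k", value=k0, min=1e-9)
    params.add("m", value=m0, min=0)
    params.add("a0", value=float(y[0]))

    def resid(p):
        return (
            p["pi"].value * (1 - np.exp(-p["k"].value * t))
            + p["m"].value * t
            + p["a0"].value
            - y
        )

    out = lmfit.minimize(resid, params, method="leastsq")
    pi = out.params["pi"].value
    k = out.params["k"].value
    m = out.params["m"].value
    a0 = out.params["a0"].value
    flagged, reason = False, ""
    dt = float(np.min(np.diff(t)))
    if k * dt > 3.0:
        # burst complete before the second sample: k is not resolved, but
        # the amplitude is still the intercept of the steady-state line
        flagged = True
        reason = "burst faster than sampling; amplitude from intercept extrapolation"
        m, a0_lin = np.polyfit(t[1:], y[1:], 1)
        pi = float(a0_lin - y[0])
        a0 = float(y[0])
        log.warning("burst titration: %s", reason)
    active_M = pi / (epsilon * ell)
    active_nM = active_M * 1e9
    frac = active_nM / enzyme_total_nM * 100.0
    if not (0.0 <= frac <= 100.0):
        flagged = True
        reason = (reason + "; " if reason else "") + "active fraction outside [0, 100]%"
        log.warning("burst titration: active fraction %.1f%% out of range", frac)
    return BurstFit(
        burst_amplitude=float(pi),
        k_burst=float(k),
        steady_slope=float(m),
        baseline=float(a0),
        active_conc_nM=float(active_nM),
        active_fraction_pct=float(frac),
        flagged=flagged,
        flag_reason=reason,
    )


# ---------------------------------------------------------------- dose-response

@dataclass
class DoseResponseFit:
    ic50: float  # µM (midpoint; EC50 for activation direction)
    hill: float
    top: float
    bottom: float
    ic50_se: float
    hill_se: float
    direction: str = "inhibition"


def fit_dose_response(
    conc_uM: np.ndarray,
    rates: np.ndarray,
    direction: str = "inhibition",
    fix_bottom: float | None = None,
    hill_init: float = 1.0,
    weighting: str = "none",
) -> DoseResponseFit:
    """Four-parameter log-logistic fit of rate versus modifier concentration.

    Inhibition: v = bottom + (top - bottom) / (1 + (C / IC50)^h).
    The reported IC50 is the fitted curve midpoint, v(IC50) =
    (top + bottom) / 2.  ``fix_bottom`` pins the lower plateau (commonly
    0 for complete inhibition).
    """
    c = np.asarray(conc_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if direction not in ("inhibition", "activation"):
        raise ValueError("direction must be 'inhibition' or 'activation'")
    if np.unique(c).size < 5:
        raise ValueError("need at least 5 modifier levels")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin < 1e-12 or (vmax - vmin) < 0.05 * max(vmax, 1e-300):
        raise NoTransitionError("no transition: response is flat (top ~ bottom)")
    sign = -1.0 if direction == "inhibition" else 1.0
    pos = c[c > 0]
    mid0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    params = lmfit.Parameters()
    params.add("top", value=vmax)
    if fix_bottom is not None:
        params.add("bottom", value=fix_bottom, vary=False)
    else:
        params.add("bottom", value=vmin)
    params.add("ic50", value=mid0, min=1e-12)
    params.add("hill", value=hill_init, min=1e-3, max=20)

    def model(p, cc):
        top, bottom = p["top"].value, p["bottom"].value
        ic50, h = p["ic50"].value, p["hill"].value
        ratio = np.zeros_like(cc)
        nz = cc > 0
        ratio[nz] = (cc[nz] / ic50) ** h  # inhibition: fraction falls with c
        frac = 1.0 / (1.0 + ratio)  # = 1 at c = 0
        if sign > 0:  # activation: mirror the curve
            frac = 1.0 - frac
        return bottom + (top - bottom) * frac

    if weighting not in ("none", "relative"):
        raise ValueError("weighting must be 'none' or 'relative'")

    def resid(p):
        m = model(p, c)
        if weighting == "relative":
            scale = np.maximum(np.abs(m), 1e-12 * max(vmax, 1e-300))
            return (m - v) / scale
        return m - v

    out = lmfit.minimize(resid, params, method="leastsq")
    if not out.success:
        raise FitError("dose-response fit did not converge")
    return DoseResponseFit(
        ic50=float(out.params["ic50"].value),
        hill=float(out.params["hill"].value),
        top=float(out.params["top"].value),
        bottom=float(out.params["bottom"].value),
        ic50_se=float(out.params["ic50"].stderr or np.nan),
        hill_se=float(out.params["hill"].stderr or np.nan),
        direction=direction,
    )


# ----------------------------------------------------- inhibition mechanism

def _aicc(rss: float, n: int, k_model: int) -> float:
    """Small-sample AIC for least squares; k counts the residual variance."""
    k = k_model + 1
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


#: a mixed fit whose interaction factor falls in this band has Ki and Ki'
#: within 50% of each other — operationally noncompetitive
MIXED_ALPHA_BAND = (2.0 / 3.0, 1.5)


def _mechanism_rate(mech: str, s, i, vmax, km, ki, alpha=1.0):
    if mech == "competitive":
        return vmax * s / (km * (1 + i / ki) + s)
    if mech == "noncompetitive":
        return (vmax / (1 + i / ki)) * s / (km + s)
    if mech == "uncompetitive":
        return vmax * s / (km + s * (1 + i / ki))
    if mech == "mixed":
        return vmax * s / (km * (1 + i / ki) + s * (1 + i / (alpha * ki)))
    raise ValueError(f"unknown mechanism {mech!r}")


@dataclass
class MechanismFit:
    mechanism: str
    vmax: float
    km: float
    ki: float
    alpha: float
    rss: float
    aicc: float
    weight: float = np.nan


@dataclass
class InhibitionModeResult:
    fits: dict[str, MechanismFit]
    selected: str
    eadie_hofstee: dict[float, np.ndarray]  # inhibitor level -> (v/S, v) pairs

    @property
    def selected_fit(self) -> MechanismFit:
        return self.fits[self.selected]


def eadie_hofstee_points(series: KineticSeries) -> np.ndarray:
    """(v/[S], v) coordinates; slope -KM, intercept Vmax for pure MM data."""
    s, v = series.substrate_uM, series.rates
    return np.column_stack([v / s, v])


def classify_inhibition(panel: list[KineticSeries]) -> InhibitionModeResult:
    """Identify the inhibition mechanism by global fit + AICc selection.

    Fits competitive, noncompetitive, uncompetitive and mixed models
    globally across all inhibitor levels (shared Vmax, KM, Ki) and ranks
    them by small-sample-corrected AIC; Akaike weights quantify the
    relative support.  The mixed model nests the pure mechanisms, so it
    only stays in the weight calculation when its fitted interaction
    factor alpha lies outside the noncompetitive band (Ki' within 50% of
    Ki means the two-constant model adds nothing but a label); its fit is
    still reported.  Eadie-Hofstee coordinates per inhibitor level are
    returned for visual diagnosis (noncompetitive data give parallel
    lines, competitive data a common intercept).
    """
    levels = sorted({float(se.modifier_uM) for se in panel})
    if sum(1 for lv in levels if lv > 0) < 2:
        raise ValueError("need at least 2 nonzero inhibitor levels")
    s = np.concatenate([se.substrate_uM for se in panel])
    i = np.concatenate([np.full(se.rates.size, se.modifier_uM) for se in panel])
    v = np.concatenate([se.rates for se in panel])
    n = v.size
    base = next((se for se in panel if se.modifier_uM == 0), panel[0])
    vmax0, km0 = _hanes_woolf_init(base.substrate_uM, base.rates)
    ki0 = float(np.median([lv for lv in levels if lv > 0]))

    fits: dict[str, MechanismFit] = {}
    for mech in MECHANISMS:
        params = lmfit.Parameters()
        params.add("vmax", value=vmax0, min=1e-12)
        params.add("km", value=km0, min=1e-9)
        params.add("ki", value=ki0, min=1e-9)
        k_par = 3
        if mech == "mixed":
            # alpha outside [0.1, 10] is operationally competitive or
            # uncompetitive; bounding keeps the mixed model identifiable
            params.add("alpha", value=1.0, min=0.1, max=10.0)
            k_par = 4

        def resid(p, mech=mech):
            alpha = p["alpha"].value if "alpha" in p else 1.0
            return (
                _mechanism_rate(mech, s, i, p["vmax"].value, p["km"].value, p["ki"].value, alpha)
                - v
            )

        out = lmfit.minimize(resid, params, method="leastsq")
        rss = float(np.sum(out.residual**2))
        fits[mech] = MechanismFit(
            mechanism=mech,
            vmax=float(out.params["vmax"].value),
            km=float(out.params["km"].value),
            ki=float(out.params["ki"].value),
            alpha=float(out.params["alpha"].value) if mech == "mixed" else 1.0,
            rss=rss,
            aicc=_aicc(max(rss, 1e-300), n, k_par),
        )
    candidates = list(MECHANISMS)
    if MIXED_ALPHA_BAND[0] <= fits["mixed"].alpha <= MIXED_ALPHA_BAND[1]:
        candidates.remove("mixed")
        fits["mixed"].weight = 0.0
    aiccs = np.array([fits[m].aicc for m in candidates])
    delta = aiccs - aiccs.min()
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    for mech, wi in zip(candidates, w):
        fits[mech].weight = float(wi)
    selected = candidates[int(np.argmax(w))]
    eh = {float(se.modifier_uM): eadie_hofstee_points(se) for se in panel}
    log.info("inhibition mechanism: %s (Akaike weight %.3f)", selected, fits[selected].weight)
    return InhibitionModeResult(fits=fits, selected=selected, eadie_hofstee=eh)


# --------------------------------------------------------------- activation

@dataclass
class ActivationFit:
    fold_max: float  # F: maximal fold-stimulation
    k_act: float  # µM
    v0: float  # basal rate
    k_att: float | None  # µM; None = pure saturation model selected
    aicc_pure: float
    aicc_attenuated: float


def _activation_rate(a, v0, fmax, kact, katt=None):
    v = v0 * (1.0 + (fmax - 1.0) * a / (kact + a))
    if katt is not None:
        v = v / (1.0 + a / katt)
    return v


def fit_activation(conc_uM: np.ndarray, rates: np.ndarray) -> ActivationFit:
    """Fit hyperbolic activation v(A) = v0 * (1 + (F-1) * A/(K_act + A)).

    F is the maximal fold-stimulation and K_act the half-maximal activator
    concentration.  An optional attenuation factor 1/(1 + A/K_att)
    captures loss of stimulation at high activator; the pure and
    attenuated models are compared by AICc.
    """
    a = np.asarray(conc_uM, dtype=float)
    v = np.asarray(rates, dtype=float)
    if np.unique(a).size < 5 or 0.0 not in a:
        raise ValueError("need at least 5 activator levels including 0")
    v0_0 = float(np.mean(v[a == 0]))
    v_hi = float(np.mean(v[a == a.max()]))
    if v_hi < v0_0 and float(np.max(v)) <= v0_0 * (1 + 1e-9):
        raise NotAnActivatorError("rates decrease monotonically with activator")
    n = v.size

    def run(with_att: bool):
        params = lmfit.Parameters()
        params.add("v0", value=max(v0_0, 1e-12), min=1e-15)
        params.add("fmax", value=max(v.max() / max(v0_0, 1e-12), 1.01), min=1.0)
        params.add("kact", value=max(float(np.median(a[a > 0])), 1e-6), min=1e-6)
        if with_att:
            params.add("katt", value=float(a.max()) * 2, min=1e-6)

        def resid(p):
            katt = p["katt"].value if with_att else None
            return _activation_rate(a, p["v0"].value, p["fmax"].value, p["kact"].value, katt) - v

        out = lmfit.minimize(resid, params, method="leastsq")
        rss = float(np.sum(out.residual**2))
        return out, _aicc(max(rss, 1e-300), n, 4 if with_att else 3)

    out_pure, aicc_pure = run(False)
    out_att, aicc_att = run(True)
    if aicc_att < aicc_pure:
        out, katt = out_att, float(out_att.params["katt"].value)
    else:
        out, katt = out_pure, None
    fit = ActivationFit(
        fold_max=float(out.params["fmax"].value),
        k_act=float(out.params["kact"].value),
        v0=float(out.params["v0"].value),
        k_att=katt,
        aicc_pure=aicc_pure,
        aicc_attenuated=aicc_att,
    )
    if fit.fold_max < 1.0 + 1e-9 and v_hi < v0_0:
        raise NotAnActivatorError("no stimulation detected (F <= 1)")
    return fit
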