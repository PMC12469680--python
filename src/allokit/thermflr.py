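"""Thermal denaturation (van't Hoff) fits and tryptophan-fluorescence analysis.

Melting curves monitored by intrinsic fluorescence are fitted to a two-state
folded <=> unfolded model with linear pre- and post-transition baselines:

    F(T) = [F_n(T) + F_u(T) * K(T)] / [1 + K(T)]
    K(T) = exp[-(dH_vH / R) * (1/T - 1/Tm)]

where T is absolute temperature, dH_vH the van't Hoff enthalpy (kcal/mol) and
Tm the midpoint at which the folded fraction is exactly 0.5. Baseline
fluorescence of a variant is the ordinary least-squares slope of fluorescence
against protein concentration; the activation-linked fluorescence gain is the
relative step on adding saturating heparin pentasaccharide (about +40% for
wild-type antithrombin).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

__all__ = [
    "R_KCAL",
    "MeltCurve",
    "VantHoffFit",
    "FluorescenceSeries",
    "BaselineFit",
    "GainResult",
    "NoTransitionError",
    "fit_vant_hoff",
    "delta_tm",
    "baseline_fluorescence",
    "fluorescence_gain",
    "buffer_volume_correct",
    "read_melt_csv",
    "read_fluorescence_csv",
]

R_KCAL = 1.987e-3  # kcal mol^-1 K^-1
KELVIN = 273.15


class NoTransitionError(ValueError):
    """Melting curve shows no sigmoidal transition."""


@dataclass
class MeltCurve:
    temperatures_c: np.ndarray  # °C as measured
    fluorescence: np.ndarray
    protein_conc: float = 0.0  # M

    def __post_init__(self) -> None:
        self.temperatures_c = np.asarray(self.temperatures_c, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures_c.shape != self.fluorescence.shape:
            raise ValueError("temperature and fluorescence lengths differ")
        if len(self.temperatures_c) < 8:
            raise ValueError("need at least 8 temperature points")
        if not np.all(np.diff(self.temperatures_c) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.temperatures_c[-1] - self.temperatures_c[0] < 30:
            raise ValueError("scan must span at least 30 °C")

    @property
    def temperatures_k(self) -> np.ndarray:
        return self.temperatures_c + KELVIN


@dataclass(frozen=True)
class VantHoffFit:
    tm_c: float  # °C
    dh_vh: float  # kcal/mol
    native_baseline: tuple[float, float]  # intercept, slope (per K)
    unfolded_baseline: tuple[float, float]
    rss: float
    boundary_warning: bool = False

    def folded_fraction(self, temp_c: float | np.ndarray) -> np.ndarray:
        T = np.asarray(temp_c, dtype=float) + KELVIN
        tm_k = self.tm_c + KELVIN
        K = np.exp(-(self.dh_vh / R_KCAL) * (1.0 / T - 1.0 / tm_k))
        return 1.0 / (1.0 + K)

    def model(self, temp_c: float | np.ndarray) -> np.ndarray:
        T = np.asarray(temp_c, dtype=float) + KELVIN
        f = self.folded_fraction(temp_c)
        fn = self.native_baseline[0] + self.native_baseline[1] * T
        fu = self.unfolded_baseline[0] + self.unfolded_baseline[1] * T
        return fn * f + fu * (1.0 - f)


def _vant_hoff_model(params: np.ndarray, T: np.ndarray) -> np.ndarray:
    an, bn, au, bu, tm_k, dh = params
    K = np.exp(np.clip(-(dh / R_KCAL) * (1.0 / T - 1.0 / tm_k), -500, 500))
    f = 1.0 / (1.0 + K)
    return (an + bn * T) * f + (au + bu * T) * (1.0 - f)


def fit_vant_hoff(curve: MeltCurve, mask_above_c: float | None = None
                  ) -> VantHoffFit:
    """Six-parameter two-state fit: two linear baselines, Tm and dH_vH.

    The initial Tm is the temperature of steepest fluorescence change; the
    baselines are seeded from the scan ends. Points above ``mask_above_c``
    (post-transition aggregation artifacts) can be excluded. A transition must
    be present: the fluorescence range has to exceed 3x the median local
    point-to-point noise.
    """
    tc = curve.temperatures_c
    F = curve.fluorescence
    if mask_above_c is not None:
        keep = tc <= mask_above_c
        tc, F = tc[keep], F[keep]
        if len(tc) < 8:
            raise ValueError("too few points below the post-transition cutoff")
    T = tc + KELVIN

    # transition detection: signal range vs local (second-difference) noise
    local_noise = np.median(np.abs(np.diff(F, 2))) / np.sqrt(6) if len(F) > 2 else 0.0
    # a genuine sigmoid also has curvature: a straight line fits it badly
    lin_resid = F - np.polyval(np.polyfit(T, F, 1), T)
    if np.ptp(F) <= 3 * local_noise or \
            np.max(np.abs(lin_resid)) <= max(3 * local_noise, 1e-12 * max(np.ptp(F), 1.0)):
        raise NoTransitionError("no thermal transition detected in scan")

    dFdT = np.gradient(F, T)
    tm0 = float(T[np.argmax(np.abs(dFdT))])
    tm0 = min(max(tm0, T[0] + 1.0), T[-1] - 1.0)

    # Variable projection: the model is linear in the four baseline
    # parameters given (Tm, dH), so they are profiled out by linear least
    # squares and only the two nonlinear parameters are iterated. This keeps
    # the optimization well conditioned and makes the fitted Tm invariant
    # under affine rescaling of the fluorescence axis (the profiled residual
    # simply scales).
    f_loc = F.mean()
    f_scale = max(np.ptp(F), 1e-9)
    Fs = (F - f_loc) / f_scale
    Ts = (T - T.mean()) / np.ptp(T)

    def design(theta: np.ndarray) -> np.ndarray:
        tm_k, dh = theta
        K = np.exp(np.clip(-(dh / R_KCAL) * (1.0 / T - 1.0 / tm_k),
                           -500, 500))
        f = 1.0 / (1.0 + K)
        return np.column_stack([f, Ts * f, 1.0 - f, Ts * (1.0 - f)])

    def profiled(theta: np.ndarray):
        A = design(theta)
        beta, *_ = np.linalg.lstsq(A, Fs, rcond=None)
        return A, beta

    def resid(theta: np.ndarray) -> np.ndarray:
        A, beta = profiled(theta)
        return A @ beta - Fs

    def jac(theta: np.ndarray) -> np.ndarray:
        # Kaufman variable-projection Jacobian: J_k = P_perp (dA/dtheta_k) b.
        # Its normal equations share the exact stationary point with the full
        # Golub-Pereyra Jacobian, so convergence is not limited by
        # finite-difference noise.
        tm_k, dh = theta
        A, beta = profiled(theta)
        g = np.clip(-(dh / R_KCAL) * (1.0 / T - 1.0 / tm_k), -500, 500)
        K = np.exp(g)
        f = 1.0 / (1.0 + K)
        dfdg = -f * (1.0 - f)
        dg_dtm = -(dh / R_KCAL) / tm_k ** 2
        dg_ddh = -(1.0 / R_KCAL) * (1.0 / T - 1.0 / tm_k)
        cols = []
        for dg in (dfdg * dg_dtm, dfdg * dg_ddh):
            dA = np.column_stack([dg, Ts * dg, -dg, -Ts * dg])
            v = dA @ beta
            proj, *_ = np.linalg.lstsq(A, v, rcond=None)
            cols.append(v - A @ proj)
        return np.column_stack(cols)

    result = least_squares(resid, np.array([tm0, 100.0]), jac=jac,
                           bounds=([T[0] - 5.0, 1.0], [T[-1] + 5.0, 5000.0]),
                           xtol=1e-14, ftol=1e-14, gtol=1e-14)
    # polish with plain Gauss-Newton steps: trust-region termination
    # heuristics stop ~1e-9 K from the stationary point, the bare iteration
    # localizes it to near machine precision
    theta = result.x
    for _ in range(10):
        r = resid(theta)
        step, *_ = np.linalg.lstsq(jac(theta), -r, rcond=None)
        if not np.all(np.isfinite(step)):
            break
        theta = theta + step
        theta[0] = min(max(theta[0], T[0] - 5.0), T[-1] + 5.0)
        theta[1] = min(max(theta[1], 1.0), 5000.0)
        if np.abs(step[0]) < 1e-12 and np.abs(step[1]) < 1e-10:
            break
    if np.sum(resid(theta) ** 2) <= np.sum(resid(result.x) ** 2) * (1 + 1e-12):
        tm_k, dh = theta
    else:
        tm_k, dh = result.x
    _, beta = profiled(np.array([tm_k, dh]))
    # de-standardize: columns were [f, Ts*f, 1-f, Ts*(1-f)] on Fs
    t_mean, t_span = T.mean(), np.ptp(T)
    an = beta[0] * f_scale + f_loc - beta[1] * f_scale * t_mean / t_span
    bn = beta[1] * f_scale / t_span
    au = beta[2] * f_scale + f_loc - beta[3] * f_scale * t_mean / t_span
    bu = beta[3] * f_scale / t_span
    final_resid = _vant_hoff_model(np.array([an, bn, au, bu, tm_k, dh]),
                                   T) - F
    boundary = not (T[0] < tm_k < T[-1])
    return VantHoffFit(tm_c=float(tm_k - KELVIN), dh_vh=float(dh),
                       native_baseline=(float(an), float(bn)),
                       unfolded_baseline=(float(au), float(bu)),
                       rss=float(np.sum(final_resid ** 2)),
                       boundary_warning=boundary)


def delta_tm(fit_variant: VantHoffFit, fit_reference: VantHoffFit) -> float:
    """Signed melting-temperature shift, variant minus reference, °C."""
    return fit_variant.tm_c - fit_reference.tm_c


@dataclass
class FluorescenceSeries:
    concentrations: np.ndarray  # M, volume-adjusted
    fluorescence: np.ndarray  # buffer-corrected units
    excitation_nm: float = 280.0
    emission_nm: float = 345.0

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.concentrations) < 3:
            raise ValueError("need at least 3 concentration points")
        if not np.all(np.diff(self.concentrations) > 0):
            raise ValueError("concentrations must be increasing")


@dataclass(frozen=True)
class BaselineFit:
    slope: float  # fluorescence units per M
    intercept: float
    r_squared: float


@dataclass(frozen=True)
class GainResult:
    percent_gain: float
    f_base: float
    f_sat: float
    pentasaccharide_excess: float = 5.0


def baseline_fluorescence(series: FluorescenceSeries) -> BaselineFit:
    """OLS slope of fluorescence vs protein concentration (the baseline
    fluorescence of the variant)."""
    c, F = series.concentrations, series.fluorescence
    if np.ptp(c) == 0:
        raise ValueError("zero spread in concentrations")
    res = stats.linregress(c, F)
    return BaselineFit(slope=float(res.slope), intercept=float(res.intercept),
                       r_squared=float(res.rvalue ** 2))


def fluorescence_gain(f_base: float, f_sat: float,
                      pentasaccharide_excess: float = 5.0) -> GainResult:
    """Percent fluorescence step on adding saturating pentasaccharide:
    100*(F_sat - F_base)/F_base."""
    if f_base <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return GainResult(percent_gain=100.0 * (f_sat - f_base) / f_base,
                      f_base=f_base, f_sat=f_sat,
                      pentasaccharide_excess=pentasaccharide_excess)


def buffer_volume_correct(f_raw: np.ndarray, f_buffer: float,
                          v_total: np.ndarray, v_initial: float) -> np.ndarray:
    """F_corr = (F_raw - F_buffer) * (V_total / V_initial).

    The dilution-and-blank dialect applied at parse time before any fit.
    """
    return (np.asarray(f_raw, dtype=float) - f_buffer) * (
        np.asarray(v_total, dtype=float) / v_initial)


def read_melt_csv(path: str | Path, protein_conc: float = 0.0) -> MeltCurve:
    """Columns: temp_C, fluorescence."""
    df = pd.read_csv(path)
    return MeltCurve(temperatures_c=df["temp_C"].to_numpy(),
                     fluorescence=df["fluorescence"].to_numpy(),
                     protein_conc=protein_conc)


def read_fluorescence_csv(path: str | Path) -> FluorescenceSeries:
    """Columns: conc_M, fluorescence (already buffer/volume corrected)."""
    df = pd.read_csv(path)
    return FluorescenceSeries(concentrations=df["conc_M"].to_numpy(),
                              fluorescence=df["fluorescence"].to_numpy())
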