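"""Serpin inhibition kinetics.

Progress curves of residual protease activity under pseudo-first-order
conditions (inhibitor in >= 10-fold molar excess) decay as a single
exponential to zero; the fitted observed rate, divided by the effective
inhibitor concentration and corrected for the stoichiometry of inhibition,
gives the second-order association rate constant k2 (M^-1 s^-1). On top of
the rate constants sit two pieces of arithmetic used throughout the analysis
of allosterically activated variants: fold/percent activation relative to the
native -> activated reactivity window, and the two-state R <=> A population
split implied by the observed native rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ProgressCurve",
    "PseudoFirstOrderFit",
    "RateConstant",
    "StoichiometryFit",
    "ActivationSummary",
    "EquilibriumPartition",
    "NoInhibitionError",
    "fit_progress_curve",
    "second_order_rate",
    "fit_stoichiometry",
    "activation_metrics",
    "equilibrium_partition",
    "read_progress_curve_csv",
    "read_titration_csv",
]


class NoInhibitionError(ValueError):
    """Progress curve shows no decay — nothing to fit."""


@dataclass
class ProgressCurve:
    times: np.ndarray  # s
    residual_activity: np.ndarray  # absorbance-slope units
    inhibitor_conc: float  # M
    protease_conc: float = 0.0  # M

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.residual_activity = np.asarray(self.residual_activity,
                                            dtype=float)
        if self.times.shape != self.residual_activity.shape:
            raise ValueError("times and activities differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.residual_activity < 0):
            raise ValueError("residual activities must be >= 0")

    @property
    def pseudo_first_order(self) -> bool:
        """True when inhibitor is at >= 10-fold excess over protease."""
        if self.protease_conc <= 0:
            return True
        return self.inhibitor_conc >= 10.0 * self.protease_conc


@dataclass(frozen=True)
class PseudoFirstOrderFit:
    k_obs: float  # s^-1
    A0: float
    rss: float
    k_obs_se: float


@dataclass(frozen=True)
class RateConstant:
    k2: float  # M^-1 s^-1
    si_corrected: bool
    SI: float
    inhibitor_conc: float


@dataclass(frozen=True)
class StoichiometryFit:
    SI: float  # abscissa intercept
    slope: float
    intercept: float
    n_points_used: int


@dataclass(frozen=True)
class ActivationSummary:
    fold: float
    percent_activation: float
    window_fold: float


@dataclass(frozen=True)
class EquilibriumPartition:
    f_R: float
    f_A: float
    k_R: float
    k_A: float
    k_obs_native: float


def fit_progress_curve(curve: ProgressCurve,
                       relative_weights: bool = False,
                       float_endpoint: bool = False) -> PseudoFirstOrderFit:
    """Fit A(t) = A0 * exp(-k_obs * t) with the endpoint fixed at zero.

    Initial guesses come from a log-linear regression on the positive
    activities. ``float_endpoint`` switches to A(t) = A0*exp(-kt) + C for
    reactions that visibly plateau above zero; it is off by default.
    """
    t = curve.times
    A = curve.residual_activity
    if len(t) < 4:
        raise ValueError("need at least 4 time points")
    a_start = A[: max(1, len(A) // 4)].mean()
    a_end = A[-max(1, len(A) // 4):].mean()
    if a_start <= 0 or a_end >= 0.9 * a_start:
        raise NoInhibitionError("no inhibition detected: activity not decaying")

    pos = A > 0
    slope, logA0 = np.polyfit(t[pos], np.log(A[pos]), 1)
    k0 = max(-slope, 1e-12)
    A00 = float(np.exp(logA0))

    sigma = A if relative_weights else None
    if float_endpoint:
        model = lambda tt, A0, k, C: A0 * np.exp(-k * tt) + C
        p0 = [A00, k0, 0.0]
    else:
        model = lambda tt, A0, k: A0 * np.exp(-k * tt)
        p0 = [A00, k0]
    try:
        popt, pcov = curve_fit(model, t, A, p0=p0, sigma=sigma,
                               absolute_sigma=False, maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - scipy rarely fails here
        raise RuntimeError(f"exponential fit did not converge: {exc}") from exc
    A0_hat, k_hat = float(popt[0]), float(popt[1])
    if k_hat <= 0 or A0_hat <= 0:
        raise NoInhibitionError("no inhibition detected: fitted rate <= 0")
    resid = A - model(t, *popt)
    k_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return PseudoFirstOrderFit(k_obs=k_hat, A0=A0_hat,
                               rss=float(np.sum(resid ** 2)), k_obs_se=k_se)


def second_order_rate(fit: PseudoFirstOrderFit | float, inhibitor_conc: float,
                      SI: float = 1.0) -> RateConstant:
    """k2 = k_obs * SI / [inhibitor].

    The stoichiometry of inhibition corrects for inhibitor consumed through
    the substrate pathway: the effective inhibitor concentration is
    [inhibitor]/SI, so SI > 1 scales k2 up.
    """
    k_obs = fit.k_obs if isinstance(fit, PseudoFirstOrderFit) else float(fit)
    if inhibitor_conc <= 0:
        raise ValueError("inhibitor concentration must be positive")
    if SI < 1.0:
        raise ValueError("SI must be >= 1")
    return RateConstant(k2=k_obs * SI / inhibitor_conc,
                        si_corrected=SI != 1.0, SI=SI,
                        inhibitor_conc=inhibitor_conc)


def fit_stoichiometry(ratios: np.ndarray, activities: np.ndarray,
                      activity_floor_frac: float = 0.05) -> StoichiometryFit:
    """SI from the abscissa intercept of residual activity vs inhibitor:protease ratio.

    Only the declining linear regime is fitted: points below
    ``activity_floor_frac`` of the uninhibited activity are excluded.
    """
    ratios = np.asarray(ratios, dtype=float)
    activities = np.asarray(activities, dtype=float)
    floor = activity_floor_frac * activities.max()
    keep = activities >= floor
    if keep.sum() < 3:
        raise ValueError("fewer than 3 points in the linear decline")
    slope, intercept = np.polyfit(ratios[keep], activities[keep], 1)
    # require a real decline: at least 5% of the uninhibited activity
    # across the fitted ratio range
    if slope >= 0 or -slope * np.ptp(ratios[keep]) < 0.05 * activities.max():
        raise ValueError("no titration: activity does not decline with ratio")
    return StoichiometryFit(SI=float(-intercept / slope), slope=float(slope),
                            intercept=float(intercept),
                            n_points_used=int(keep.sum()))


def activation_metrics(k2_variant: float, k2_native_wt: float,
                       k2_activated_wt: float) -> ActivationSummary:
    """Fold activation and percent of the native->activated reactivity window.

    percent = 100*(fold - 1)/(window - 1), so the unactivated native protein
    maps to 0% and the fully activated form to 100%.
    """
    if min(k2_variant, k2_native_wt, k2_activated_wt) <= 0:
        raise ValueError("rate constants must be positive")
    fold = k2_variant / k2_native_wt
    window = k2_activated_wt / k2_native_wt
    if window <= 1:
        raise ValueError("activation window must exceed 1-fold")
    percent = 100.0 * (fold - 1.0) / (window - 1.0)
    return ActivationSummary(fold=fold, percent_activation=percent,
                             window_fold=window)


def equilibrium_partition(k_obs_native: float, k_R: float, k_A: float
                          ) -> EquilibriumPartition:
    """Two-state R <=> A population split from the observed native rate.

    The native reactivity is the population-weighted average
    k_obs = f_R*k_R + f_A*k_A, so f_A = (k_obs - k_R)/(k_A - k_R).
    """
    if not (k_R < k_obs_native < k_A):
        raise ValueError(
            f"require k_R < k_obs < k_A, got {k_R} < {k_obs_native} < {k_A}")
    f_A = (k_obs_native - k_R) / (k_A - k_R)
    return EquilibriumPartition(f_R=1.0 - f_A, f_A=f_A, k_R=k_R, k_A=k_A,
                                k_obs_native=k_obs_native)


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------

def read_progress_curve_csv(path: str | Path, inhibitor_conc: float,
                            protease_conc: float = 0.0) -> ProgressCurve:
    """Columns: time_s, activity."""
    df = pd.read_csv(path)
    return ProgressCurve(times=df["time_s"].to_numpy(),
                         residual_activity=df["activity"].to_numpy(),
                         inhibitor_conc=inhibitor_conc,
                         protease_conc=protease_conc)


def read_titration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Columns: ratio, activity."""
    df = pd.read_csv(path)
    return df["ratio"].to_numpy(dtype=float), df["activity"].to_numpy(dtype=float)
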