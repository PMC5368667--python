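"""Apparent melting temperatures from CD thermal denaturation scans.

A two-state thermal melt monitored at a single wavelength is reduced to an
apparent melting temperature T_m* as follows: the folded and unfolded
ellipticity baselines are fit as linear functions of temperature over
pre- and post-transition windows, the signal is converted to fraction
folded f(T) = (theta(T) - theta_U(T)) / (theta_F(T) - theta_U(T)), and a
straight line regressed through the transition region of f(T) is solved
for f = 0.5.  T_m* is "apparent" because no reversibility or two-state
thermodynamics is assumed; a second heating scan is used only to quantify
how much folded-state signal returns (reversibility fraction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import uniform_filter1d
from sklearn.base import BaseEstimator

__all__ = [
    "MeltCurve",
    "BaselinePair",
    "TmEstimate",
    "MeltConfig",
    "TwoStateMeltFitter",
    "fit_baselines",
    "fraction_folded",
    "estimate_tm",
    "check_reversibility",
    "mean_residue_ellipticity",
    "summarize_tm",
    "read_melts",
]


class MeltError(ValueError):
    """Raised when a melt curve cannot be analysed."""


@dataclass(frozen=True)
class MeltCurve:
    """One heating scan: (temperature [degC], ellipticity [mdeg or MRE]) points."""

    variant: str
    points: tuple[tuple[float, float], ...]
    scan: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(tuple(p) for p in self.points))
        t = self.temperatures
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([t for t, _ in self.points], dtype=float)

    @property
    def signals(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)


@dataclass(frozen=True)
class BaselinePair:
    """Linear folded/unfolded baselines with the windows they were fit over."""

    folded: tuple[float, float]     # (slope, intercept)
    unfolded: tuple[float, float]
    folded_window: tuple[float, float]
    unfolded_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.folded_window[1] >= self.unfolded_window[0]:
            raise ValueError("folded window must lie entirely below unfolded window")

    def theta_f(self, t: np.ndarray) -> np.ndarray:
        return self.folded[0] * np.asarray(t, float) + self.folded[1]

    def theta_u(self, t: np.ndarray) -> np.ndarray:
        return self.unfolded[0] * np.asarray(t, float) + self.unfolded[1]


@dataclass(frozen=True)
class TmEstimate:
    """Apparent melting temperature with fit diagnostics."""

    variant: str
    tm_app: float
    transition_window: tuple[float, float]
    regression_r2: float
    reversibility: float | None = None
    n_replicates: int = 1
    sd: float = 0.0
    replicate_tms: tuple[float, ...] = ()


@dataclass(frozen=True)
class MeltConfig:
    """Analysis settings.

    baseline_fraction: each baseline window is initially the lowest/highest
    this fraction of the temperature span; windows shrink away from the
    transition while fraction folded inside them departs from 1/0 by more
    than ``baseline_tol``.  The transition region is the contiguous band of
    points with f in [f_lo, f_hi] containing the 0.5 crossing.
    """

    baseline_fraction: float = 0.15
    baseline_tol: float = 0.05
    f_lo: float = 0.35
    f_hi: float = 0.65
    min_window_points: int = 4
    min_transition_points: int = 4


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def fit_baselines(
    curve: MeltCurve,
    folded_window: tuple[float, float],
    unfolded_window: tuple[float, float],
) -> BaselinePair:
    """Ordinary least-squares lines over the stated temperature windows."""
    if folded_window[1] >= unfolded_window[0]:
        raise MeltError("baseline windows overlap")
    t, s = curve.temperatures, curve.signals
    out = []
    for lo, hi in (folded_window, unfolded_window):
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 2:
            raise MeltError(f"baseline window {lo}-{hi} degC holds < 2 points")
        out.append(_ols_line(t[mask], s[mask]))
    return BaselinePair(out[0], out[1], folded_window, unfolded_window)


def fraction_folded(curve: MeltCurve, baselines: BaselinePair) -> np.ndarray:
    """f(T) = (theta - theta_U) / (theta_F - theta_U); not clipped to [0, 1]."""
    t = curve.temperatures
    denom = baselines.theta_f(t) - baselines.theta_u(t)
    if np.any(denom == 0) or np.any(np.sign(denom) != np.sign(denom[0])):
        raise MeltError("folded and unfolded baselines cross inside the scan")
    return (curve.signals - baselines.theta_u(t)) / denom


class TwoStateMeltFitter(BaseEstimator):
    """Estimate T_m* from one heating scan.

    ``fit(T, theta)`` fits baselines (with automatic window shrinking),
    computes fraction folded, and regresses the transition region.

    Attributes (after ``fit``)
    --------------------------
    tm_ : float                apparent melting temperature [degC]
    baselines_ : BaselinePair
    transition_window_ : (float, float)
    r2_ : float                r-squared of the transition regression
    fraction_ : ndarray        fraction folded at every scan point
    """

    def __init__(
        self,
        baseline_fraction: float = 0.15,
        baseline_tol: float = 0.05,
        f_lo: float = 0.35,
        f_hi: float = 0.65,
        min_window_points: int = 4,
        min_transition_points: int = 4,
        folded_window: tuple[float, float] | None = None,
        unfolded_window: tuple[float, float] | None = None,
    ):
        self.baseline_fraction = baseline_fraction
        self.baseline_tol = baseline_tol
        self.f_lo = f_lo
        self.f_hi = f_hi
        self.min_window_points = min_window_points
        self.min_transition_points = min_transition_points
        self.folded_window = folded_window
        self.unfolded_window = unfolded_window

    # -- baseline window selection --------------------------------------
    def _auto_baselines(self, curve: MeltCurve) -> BaselinePair:
        """Fit baselines over automatically located pre/post-transition windows.

        The transition is located on the raw signal, not on fraction folded
        (which needs the very baselines being sought): the smoothed
        temperature derivative of the signal departs strongly from the
        baseline slopes inside the transition, so the windows are everything
        colder/hotter than the contiguous high-|slope| region around the
        derivative peak, with a smoothing-width margin.  Falls back to the
        coldest/hottest ``baseline_fraction`` of the span when no clear
        transition stands out, and never uses fewer points per window than
        ``max(min_window_points, 5%)``.  Wide baseline windows matter: the
        dominant T_m* error is baseline-slope noise amplified by the
        extrapolation to the transition midpoint.
        """
        t = curve.temperatures
        if self.folded_window is not None and self.unfolded_window is not None:
            return fit_baselines(curve, self.folded_window, self.unfolded_window)
        s = curve.signals
        n = len(t)
        k = max(self.min_window_points, n // 10)
        w = max(3, min(9, n // 15))
        smooth = uniform_filter1d(s, size=w, mode="nearest")
        slope = uniform_filter1d(np.gradient(smooth, t), size=w, mode="nearest")
        edge = int(np.ceil(self.baseline_fraction * n))
        baseline_slope = float(np.median(np.concatenate([slope[:edge], slope[-edge:]])))
        excess = np.abs(slope - baseline_slope)
        peak = int(np.argmax(excess))
        if excess[peak] <= 3.0 * np.median(excess):
            # no transition stands out; fall back to the edge windows
            lo_end, hi_start = edge - 1, n - edge
        else:
            thr = 0.15 * excess[peak]
            lo_end = peak
            while lo_end > 0 and excess[lo_end] > thr:
                lo_end -= 1
            hi_start = peak
            while hi_start < n - 1 and excess[hi_start] > thr:
                hi_start += 1
            lo_end -= w   # margin: smoothing smears the transition outward
            hi_start += w
        lo_end = int(np.clip(lo_end, k - 1, n - k - 1))
        hi_start = int(np.clip(hi_start, lo_end + 1, n - k))
        fw, uw = (t[0], t[lo_end]), (t[hi_start], t[-1])
        baselines = fit_baselines(curve, fw, uw)
        baselines = self._refine_baselines_globally(curve, baselines, t[peak])
        denom = baselines.theta_f(t) - baselines.theta_u(t)
        if np.any(np.sign(denom) != np.sign(denom[0])) or np.any(denom == 0):
            # a noisy slope on a short window can make the extrapolated lines
            # cross; flat baselines through the window means never can
            fm, um = (t >= fw[0]) & (t <= fw[1]), (t >= uw[0]) & (t <= uw[1])
            baselines = BaselinePair(
                (0.0, float(s[fm].mean())), (0.0, float(s[um].mean())), fw, uw
            )
        return baselines

    @staticmethod
    def _refine_baselines_globally(
        curve: MeltCurve, initial: BaselinePair, tm_guess: float
    ) -> BaselinePair:
        """Re-estimate the baseline lines by a global two-state fit.

        Window-OLS baselines are noisy when a transition sits close to the
        scan edge (few window points, long extrapolation).  Fitting the whole
        scan with a six-parameter two-state shape -- two linear baselines
        mixed by a van't Hoff sigmoid -- conditions the baseline parameters
        on every point.  Only the refined baselines are kept; T_m* continues
        to come from the transition-region regression of fraction folded.
        Falls back to the window-OLS baselines if the fit fails.
        """
        from scipy.optimize import least_squares

        t = curve.temperatures
        s = curve.signals
        R = 8.314462618e-3  # kJ/(mol K)

        def model(theta):
            af, bf, au, bu, tm, dh = theta
            tk = t + 273.15
            f = 1.0 / (1.0 + np.exp(-dh * (1.0 - tk / (tm + 273.15)) / (R * tk)))
            return f * (af * t + bf) + (1.0 - f) * (au * t + bu)

        x0 = [*initial.folded, *initial.unfolded, float(tm_guess), 350.0]
        try:
            sol = least_squares(
                lambda th: model(th) - s,
                x0=x0,
                bounds=(
                    [-np.inf, -np.inf, -np.inf, -np.inf, t[0], 50.0],
                    [np.inf, np.inf, np.inf, np.inf, t[-1], 3000.0],
                ),
                method="trf",
            )
        except Exception:
            return initial
        if not sol.success or np.mean(sol.fun**2) > max(
            1e-12, 4.0 * np.mean((model(x0) - s) ** 2)
        ):
            return initial
        af, bf, au, bu = sol.x[:4]
        return BaselinePair(
            (float(af), float(bf)),
            (float(au), float(bu)),
            initial.folded_window,
            initial.unfolded_window,
        )

    def fit(self, X, y=None):
        if isinstance(X, MeltCurve):
            curve = X
        else:
            t = np.asarray(X, dtype=float).reshape(-1)
            curve = MeltCurve("<array>", tuple(zip(t, np.asarray(y, float))))
        t = curve.temperatures
        baselines = self._auto_baselines(curve)
        # a real unfolding transition separates the baselines well beyond the
        # within-window residual noise; otherwise fraction folded is undefined
        denom = np.abs(baselines.theta_f(t) - baselines.theta_u(t))
        fm = (t >= baselines.folded_window[0]) & (t <= baselines.folded_window[1])
        resid_rms = float(
            np.sqrt(np.mean((curve.signals[fm] - baselines.theta_f(t[fm])) ** 2))
        )
        floor = 1e-9 * max(1.0, float(np.max(np.abs(curve.signals))))
        if float(np.median(denom)) <= 5.0 * max(resid_rms, floor):
            raise MeltError(
                f"{curve.variant}: no discernible unfolding transition "
                "(baseline separation within noise)"
            )
        f = fraction_folded(curve, baselines)

        # Transition region: contiguous run with f in [f_lo, f_hi] that
        # contains the 0.5 crossing; expanded around the crossing to the
        # minimum point count (sharp transitions may put no points in band).
        crossings = np.nonzero((f[:-1] - 0.5) * (f[1:] - 0.5) <= 0)[0]
        if crossings.size == 0:
            raise MeltError("fraction folded never crosses 0.5")
        # several crossings can occur (noise wiggles on the plateaus);
        # the true transition is the one where f falls steepest
        fs = uniform_filter1d(f, size=max(3, len(f) // 20), mode="nearest")
        local_slope = np.gradient(fs, t)
        ci = int(crossings[np.argmin(local_slope[crossings])])
        lo = ci
        while lo > 0 and self.f_lo <= f[lo] <= self.f_hi:
            lo -= 1
        if not (self.f_lo <= f[lo] <= self.f_hi):
            lo += 1
        hi = ci + 1
        while hi < len(f) - 1 and self.f_lo <= f[hi] <= self.f_hi:
            hi += 1
        if not (self.f_lo <= f[hi] <= self.f_hi):
            hi -= 1
        while hi - lo + 1 < self.min_transition_points:
            if lo > 0:
                lo -= 1
            if hi < len(f) - 1 and hi - lo + 1 < self.min_transition_points:
                hi += 1
            if lo == 0 and hi == len(f) - 1:
                break
        if hi - lo + 1 < self.min_transition_points:
            raise MeltError("fewer than 4 points available for the transition fit")

        tw, fw = t[lo : hi + 1], f[lo : hi + 1]
        if np.any(np.diff(fw) > 0.1):
            warnings.warn(
                f"{curve.variant}: fraction folded non-monotone in the transition",
                stacklevel=2,
            )
        reg = stats.linregress(tw, fw)
        if reg.slope == 0:
            raise MeltError("flat transition regression; cannot solve f = 0.5")
        self.tm_ = float((0.5 - reg.intercept) / reg.slope)
        self.r2_ = float(reg.rvalue**2)
        self.baselines_ = baselines
        self.transition_window_ = (float(tw[0]), float(tw[-1]))
        self.fraction_ = f
        return self


def estimate_tm(curve: MeltCurve, config: MeltConfig | None = None) -> TmEstimate:
    """Apparent T_m* of one scan (the first heating of a melt experiment)."""
    config = config or MeltConfig()
    est = TwoStateMeltFitter(
        baseline_fraction=config.baseline_fraction,
        baseline_tol=config.baseline_tol,
        f_lo=config.f_lo,
        f_hi=config.f_hi,
        min_window_points=config.min_window_points,
        min_transition_points=config.min_transition_points,
    ).fit(curve)
    return TmEstimate(
        variant=curve.variant,
        tm_app=est.tm_,
        transition_window=est.transition_window_,
        regression_r2=est.r2_,
        replicate_tms=(est.tm_,),
    )


def check_reversibility(first: MeltCurve, second: MeltCurve) -> float:
    """Fraction of folded-state signal recovered in the second heating.

    The second scan is interpolated onto the first scan's grid; the ratio of
    mean amplitude above the first scan's unfolded baseline, taken over the
    folded-baseline window, quantifies how much of the protein refolded.
    """
    t1 = first.temperatures
    t2, s2 = second.temperatures, second.signals
    lo, hi = max(t1[0], t2[0]), min(t1[-1], t2[-1])
    if hi <= lo:
        raise MeltError("melt scans cover disjoint temperature ranges")
    fitter = TwoStateMeltFitter().fit(first)
    baselines = fitter.baselines_
    fw_lo, fw_hi = baselines.folded_window
    mask = (t1 >= max(fw_lo, lo)) & (t1 <= min(fw_hi, hi))
    if mask.sum() < 2:
        raise MeltError("folded window not covered by both scans")
    tgrid = t1[mask]
    amp1 = first.signals[mask] - baselines.theta_u(tgrid)
    amp2 = np.interp(tgrid, t2, s2) - baselines.theta_u(tgrid)
    return float(np.mean(amp2) / np.mean(amp1))


def mean_residue_ellipticity(
    theta_mdeg: float,
    conc_g_per_L: float,
    pathlength_cm: float,
    mean_residue_weight: float = 110.0,
) -> float:
    """Mean residue ellipticity [deg cm^2 dmol^-1].

    Convention: MRE = theta[mdeg] * MRW[g/mol] / (10 * l[cm] * c[g/L]).
    """
    if conc_g_per_L <= 0 or pathlength_cm <= 0 or mean_residue_weight <= 0:
        raise ValueError("concentration, pathlength and MRW must be positive")
    return theta_mdeg * mean_residue_weight / (10.0 * pathlength_cm * conc_g_per_L)


def summarize_tm(estimates: Sequence[TmEstimate], variant: str | None = None) -> TmEstimate:
    """Replicate mean and sample SD of T_m* (typically two independent melts)."""
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to summarize")
    variant = variant or estimates[0].variant
    tms = np.array([e.tm_app for e in estimates])
    sd = float(np.std(tms, ddof=1)) if len(tms) > 1 else 0.0
    rev = [e.reversibility for e in estimates if e.reversibility is not None]
    return TmEstimate(
        variant=variant,
        tm_app=float(np.mean(tms)),
        transition_window=estimates[0].transition_window,
        regression_r2=float(np.mean([e.regression_r2 for e in estimates])),
        reversibility=float(np.mean(rev)) if rev else None,
        n_replicates=len(tms),
        sd=sd,
        replicate_tms=tuple(float(x) for x in tms),
    )


# ---------------------------------------------------------------------------
# CSV interface: columns variant, replicate, scan, temp_C, signal
# ---------------------------------------------------------------------------

def read_melts(path_or_df) -> dict[tuple[str, int], dict[int, MeltCurve]]:
    """Load melt scans keyed by (variant, replicate) then scan number."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    if "replicate" not in df.columns:
        df = df.assign(replicate=0)
    out: dict[tuple[str, int], dict[int, MeltCurve]] = {}
    for (variant, rep, scan), grp in df.groupby(["variant", "replicate", "scan"], sort=True):
        grp = grp.sort_values("temp_C")
        out.setdefault((str(variant), int(rep)), {})[int(scan)] = MeltCurve(
            variant=str(variant),
            scan=int(scan),
            points=tuple(zip(grp["temp_C"], grp["signal"])),
        )
    return out
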