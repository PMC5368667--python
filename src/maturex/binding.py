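"""Saturation-binding isotherm fitting for yeast-display titrations.

Mean fluorescence (APC channel) of displayed antibody incubated at antigen
concentration ``c`` is modelled as a one-site saturable isotherm plus a
linear nonspecific term::

    APC(c) = APC_min + APC_sat * c / (c + K_D) + APC_ns * c

Parameters are chosen to minimise the mean squared error between observed
and predicted APC; the association constant is K_A = 1/K_D.  Because the
model has a well-known ridge when K_D lies far above the tested
concentrations (the saturable term degenerates to a second linear term),
the fitter multi-starts K_D on a log grid, solves the three linear
parameters by bounded linear least squares at each start, then polishes
with bounded nonlinear least squares, and flags fits as unmeasurable when
the data cannot support a K_D estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, lsq_linear
from scipy.stats import f as f_dist
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TitrationDataset",
    "BindingFit",
    "AffinitySummary",
    "FitConfig",
    "IsothermFitter",
    "binding_model",
    "fit_isotherm",
    "summarize_affinity",
    "read_titrations",
    "fits_to_frame",
]


class TitrationError(ValueError):
    """Raised when a titration cannot be fit (too few points/decades)."""


@dataclass(frozen=True)
class TitrationDataset:
    """One replicate titration: (concentration [M], signal [a.u.]) points."""

    variant: str
    points: tuple[tuple[float, float], ...]
    replicate_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(tuple(p) for p in self.points))
        if any(c < 0 for c, _ in self.points):
            raise ValueError("concentrations must be >= 0")

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def signals(self) -> np.ndarray:
        return np.array([s for _, s in self.points], dtype=float)

    def validate_for_fit(self) -> None:
        pos = np.unique(self.concentrations[self.concentrations > 0])
        if len(np.unique(self.concentrations)) < 5:
            raise TitrationError(
                f"{self.variant} rep {self.replicate_id}: need >= 5 distinct "
                f"concentrations, got {len(np.unique(self.concentrations))}"
            )
        if len(pos) < 2 or pos.max() / pos.min() < 100.0:
            raise TitrationError(
                f"{self.variant} rep {self.replicate_id}: concentrations must "
                "span at least 2 decades"
            )


@dataclass(frozen=True)
class BindingFit:
    """Fitted isotherm parameters with derived K_A and a measurability flag."""

    variant: str
    replicate_id: int
    apc_min: float
    apc_sat: float
    apc_ns: float
    kd: float
    mse: float
    measurable: bool

    @property
    def ka(self) -> float:
        return 1.0 / self.kd


@dataclass(frozen=True)
class AffinitySummary:
    """Replicate mean/SD of K_A for one variant; carries per-replicate values."""

    variant: str
    mean_ka: float
    sd_ka: float
    n: int
    measurable: bool
    replicate_kas: tuple[float, ...] = ()


@dataclass(frozen=True)
class FitConfig:
    """Fitter settings; defaults are physical-signal bounds and a 7-point start grid."""

    n_starts: int = 7
    kd_bound_lo_factor: float = 1e-3   # lower K_D bound = min conc * this
    kd_bound_hi_factor: float = 1e3    # upper K_D bound = max conc * this
    unmeasurable_kd_factor: float = 10.0   # K_D > this * max conc -> unmeasurable
    unmeasurable_sat_snr: float = 3.0      # APC_sat < this * residual RMS -> unmeasurable
    detection_alpha: float = 0.05          # nested-model F-test level for the saturable term


def binding_model(
    conc: float | np.ndarray,
    apc_min: float,
    apc_sat: float,
    apc_ns: float,
    kd: float,
) -> float | np.ndarray:
    """Evaluate APC_min + APC_sat*c/(c+K_D) + APC_ns*c."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative concentration")
    if kd <= 0:
        raise ValueError("K_D must be positive")
    out = apc_min + apc_sat * conc / (conc + kd) + apc_ns * conc
    return float(out) if out.ndim == 0 else out


def _linear_subproblem(conc: np.ndarray, signal: np.ndarray, kd: float):
    """Best (APC_min, APC_sat>=0, APC_ns>=0) for a fixed K_D, by bounded LLS."""
    A = np.column_stack([np.ones_like(conc), conc / (conc + kd), conc])
    res = lsq_linear(A, signal, bounds=([-np.inf, 0.0, 0.0], np.inf))
    resid = A @ res.x - signal
    return res.x, float(np.mean(resid**2))


class IsothermFitter(BaseEstimator, RegressorMixin):
    """Nonlinear least-squares fitter for the saturation + nonspecific model.

    Parameters
    ----------
    n_starts : int
        Number of K_D starting values, log-spaced over
        [min conc / 100, max conc * 100].
    kd_bound_lo_factor, kd_bound_hi_factor : float
        K_D search bounds as multiples of the smallest / largest positive
        tested concentration.
    unmeasurable_kd_factor, unmeasurable_sat_snr : float
        Measurability thresholds: the fit is flagged unmeasurable when the
        fitted K_D exceeds ``unmeasurable_kd_factor`` times the highest tested
        concentration, or when the fitted saturation amplitude is below
        ``unmeasurable_sat_snr`` times the residual RMS.
    detection_alpha : float
        The saturable term must additionally survive a nested-model F-test
        (full isotherm vs ``APC_min + APC_ns*c``) at this level; otherwise
        the affinity is declared unmeasurable.  Guards against noise being
        absorbed into a spurious saturable component.

    Attributes (after ``fit``)
    --------------------------
    apc_min_, apc_sat_, apc_ns_, kd_, ka_, mse_, measurable_
    """

    def __init__(
        self,
        n_starts: int = 7,
        kd_bound_lo_factor: float = 1e-3,
        kd_bound_hi_factor: float = 1e3,
        unmeasurable_kd_factor: float = 10.0,
        unmeasurable_sat_snr: float = 3.0,
        detection_alpha: float = 0.05,
    ):
        self.n_starts = n_starts
        self.kd_bound_lo_factor = kd_bound_lo_factor
        self.kd_bound_hi_factor = kd_bound_hi_factor
        self.unmeasurable_kd_factor = unmeasurable_kd_factor
        self.unmeasurable_sat_snr = unmeasurable_sat_snr
        self.detection_alpha = detection_alpha

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).reshape(-1)
        signal = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != signal.shape:
            raise ValueError("X and y must have matching lengths")
        if np.any(conc < 0):
            raise ValueError("negative concentration")
        pos = conc[conc > 0]
        if pos.size == 0:
            raise TitrationError("no positive concentrations")

        cmin, cmax = pos.min(), pos.max()
        lo, hi = cmin * self.kd_bound_lo_factor, cmax * self.kd_bound_hi_factor
        starts = np.geomspace(
            max(cmin / 100.0, lo), min(cmax * 100.0, hi), self.n_starts
        )

        def residuals(theta):
            apc_min, apc_sat, apc_ns, log10_kd = theta
            return (
                binding_model(conc, apc_min, apc_sat, apc_ns, 10.0**log10_kd)
                - signal
            )

        best = None
        for kd0 in starts:
            (m0, s0, n0), _ = _linear_subproblem(conc, signal, kd0)
            try:
                sol = least_squares(
                    residuals,
                    x0=[m0, s0, n0, math.log10(kd0)],
                    bounds=(
                        [-np.inf, 0.0, 0.0, math.log10(lo)],
                        [np.inf, np.inf, np.inf, math.log10(hi)],
                    ),
                    method="trf",
                )
            except Exception:
                continue
            mse = float(np.mean(sol.fun**2))
            if best is None or mse < best[0]:
                best = (mse, sol.x)
        if best is None:
            raise TitrationError("optimizer failed to converge from every start")

        mse, (apc_min, apc_sat, apc_ns, log10_kd) = best
        # Polish the linear parameters exactly at the final K_D so the reported
        # optimum is never beaten by its own linear subproblem.
        kd = 10.0**log10_kd
        (m, s, n), lin_mse = _linear_subproblem(conc, signal, kd)
        if lin_mse < mse:
            apc_min, apc_sat, apc_ns, mse = m, s, n, lin_mse

        rms = math.sqrt(mse)
        scale = max(1.0, float(np.max(np.abs(signal))))
        measurable = not (
            kd > self.unmeasurable_kd_factor * cmax
            or apc_sat < self.unmeasurable_sat_snr * max(rms, 1e-6 * scale)
            or not self._saturation_detectable(conc, signal, mse)
        )
        self.apc_min_ = float(apc_min)
        self.apc_sat_ = float(apc_sat)
        self.apc_ns_ = float(apc_ns)
        self.kd_ = float(kd)
        self.ka_ = 1.0 / float(kd)
        self.mse_ = float(mse)
        self.measurable_ = bool(measurable)
        return self

    def _saturation_detectable(self, conc, signal, mse_full) -> bool:
        """Nested-model F-test: does the saturable term beat a pure line?"""
        n = len(conc)
        dof = n - 4
        if dof < 1:
            return True
        sse_full = mse_full * n
        sse_lin = _linear_only_mse(conc, signal) * n
        if sse_full <= 0:
            return sse_lin > 0
        f_stat = ((sse_lin - sse_full) / 2.0) / (sse_full / dof)
        return f_stat > f_dist.ppf(1.0 - self.detection_alpha, 2, dof)

    def predict(self, X):
        conc = np.asarray(X, dtype=float).reshape(-1)
        return binding_model(conc, self.apc_min_, self.apc_sat_, self.apc_ns_, self.kd_)


def _linear_only_mse(conc: np.ndarray, signal: np.ndarray) -> float:
    A = np.column_stack([np.ones_like(conc), conc])
    res = lsq_linear(A, signal, bounds=([-np.inf, 0.0], np.inf))
    return float(np.mean((A @ res.x - signal) ** 2))


def fit_isotherm(data: TitrationDataset, config: FitConfig | None = None) -> BindingFit:
    """Fit one replicate titration; validates the dataset first."""
    config = config or FitConfig()
    data.validate_for_fit()
    est = IsothermFitter(
        n_starts=config.n_starts,
        kd_bound_lo_factor=config.kd_bound_lo_factor,
        kd_bound_hi_factor=config.kd_bound_hi_factor,
        unmeasurable_kd_factor=config.unmeasurable_kd_factor,
        unmeasurable_sat_snr=config.unmeasurable_sat_snr,
        detection_alpha=config.detection_alpha,
    ).fit(data.concentrations, data.signals)
    return BindingFit(
        variant=data.variant,
        replicate_id=data.replicate_id,
        apc_min=est.apc_min_,
        apc_sat=est.apc_sat_,
        apc_ns=est.apc_ns_,
        kd=est.kd_,
        mse=est.mse_,
        measurable=est.measurable_,
    )


def summarize_affinity(fits: Sequence[BindingFit], variant: str | None = None) -> AffinitySummary:
    """Mean and sample SD of K_A over measurable replicates.

    The variant is unmeasurable when more than half of its replicates are;
    then mean/sd are NaN (the dagger convention for low-affinity variants).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    variant = variant or fits[0].variant
    if any(f.variant != variant for f in fits):
        raise ValueError("fits belong to different variants")
    measurable = [f for f in fits if f.measurable]
    if len(measurable) * 2 <= len(fits):
        return AffinitySummary(variant, float("nan"), float("nan"), len(fits), False)
    kas = np.array([f.ka for f in measurable])
    sd = float(np.std(kas, ddof=1)) if len(kas) > 1 else 0.0
    return AffinitySummary(
        variant, float(np.mean(kas)), sd, len(kas), True, tuple(float(k) for k in kas)
    )


# ---------------------------------------------------------------------------
# CSV interface: columns variant, replicate, conc_M, signal
# ---------------------------------------------------------------------------

def read_titrations(path_or_df) -> list[TitrationDataset]:
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    out = []
    for (variant, rep), grp in df.groupby(["variant", "replicate"], sort=True):
        out.append(
            TitrationDataset(
                variant=str(variant),
                replicate_id=int(rep),
                points=tuple(zip(grp["conc_M"], grp["signal"])),
            )
        )
    return out


def fits_to_frame(fits: Iterable[BindingFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variant": f.variant,
                "replicate": f.replicate_id,
                "apc_min": f.apc_min,
                "apc_sat": f.apc_sat,
                "apc_ns": f.apc_ns,
                "kd_M": f.kd,
                "ka_per_M": f.ka,
                "mse": f.mse,
                "measurable": f.measurable,
            }
            for f in fits
        ]
    )
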