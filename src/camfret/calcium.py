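"""Free-Ca2+ calibration, Hill Ca2+-sensitivity fits, and biphasic decomposition.

The Ca2+ assay titrates Ca2+ into a chelator-buffered mix of biosensor,
saturating CaM, and a red-shifted indicator (X-Rhod5F, in vitro K_d for Ca2+
1.6 µM).  Free Ca2+ is read from the indicator's single-site saturation:

    [Ca2+]_free = K_d,ind × (F − F_min) / (F_max − F),

with F_min/F_max the indicator intensities under nominally Ca2+-free and
Ca2+-saturating conditions.  Biosensor fractional response versus free Ca2+
is then fit to a Hill curve,

    BS_fract = A · [Ca2+]^n / (EC50^n + [Ca2+]^n),

globally and — when the curve is biphasic, as for the SMD1 linker — to a
restricted low-Ca2+ segment (free Ca2+ ≤ 1 µM by default) resolving a second,
much more Ca2+-sensitive complex species.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_dist

from .errors import (
    FitFailureError,
    OutOfRangeError,
    ParameterError,
    SaturationError,
)
from .response import fractional_from_ratio
from .series import CaAssaySeries

#: X-Rhod5F in vitro K_d for Ca2+ (µM).
INDICATOR_KD = 1.6

#: Indicator readings may undershoot F_min by this fraction of the dynamic
#: range before being an error; they are clamped with a warning.
INDICATOR_CLAMP_TOL = 0.02

#: Free Ca2+ below the breakpoint resolves complex species 1.
DEFAULT_BREAKPOINT = 1.0  # µM

_HILL_N_BOUNDS = (0.3, 6.0)
_LOG_EC50_BOUNDS = (-3.0, 3.0)  # log10 µM
_EC50_SEEDS = tuple(np.geomspace(1e-3, 1e3, 5))
_N_SEEDS = (0.8, 1.5, 2.5)

#: Points whose indicator reading sits within this fraction of F_max are
#: saturated calibration records: free Ca2+ is not computable there.
_SATURATION_FRACTION = 1e-3


def free_calcium(f, f_min: float, f_max: float, kd_ind: float = INDICATOR_KD):
    """Free Ca2+ (µM) from an indicator fluorescence reading.

    Raises :class:`SaturationError` at or above ``f_max`` and
    :class:`OutOfRangeError` below ``f_min`` by more than the clamp tolerance.
    """
    if f_max <= f_min:
        raise OutOfRangeError("indicator f_max must exceed f_min")
    if kd_ind <= 0:
        raise ParameterError("indicator kd must be > 0")
    arr = np.asarray(f, dtype=float)
    span = f_max - f_min
    low = arr.min()
    if low < f_min - INDICATOR_CLAMP_TOL * span:
        raise OutOfRangeError(
            f"indicator reading {low:.4g} below F_min {f_min:.4g} by more than "
            f"{INDICATOR_CLAMP_TOL:.0%} of the dynamic range"
        )
    if low < f_min:
        _warnings.warn("indicator reading below F_min clamped", stacklevel=2)
        arr = np.clip(arr, f_min, None)
    if arr.max() >= f_max:
        raise SaturationError(
            "indicator at or beyond its Ca2+-saturated intensity; free Ca2+ "
            "is not computable"
        )
    out = kd_ind * (arr - f_min) / (f_max - arr)
    return float(out) if np.ndim(f) == 0 else out


def indicator_fluorescence(ca, f_min: float, f_max: float,
                           kd_ind: float = INDICATOR_KD):
    """Inverse of :func:`free_calcium`: indicator reading at free Ca2+ ``ca``."""
    ca = np.asarray(ca, dtype=float)
    out = f_min + (f_max - f_min) * ca / (kd_ind + ca)
    return float(out) if out.ndim == 0 else out


def predict_hill(ca, ec50: float, n: float, amplitude: float = 1.0):
    """Hill-equation bound fraction at free Ca2+ ``ca`` (µM)."""
    if ec50 <= 0:
        raise ParameterError("ec50 must be > 0")
    if n <= 0:
        raise ParameterError("hill coefficient must be > 0")
    ca = np.asarray(ca, dtype=float)
    with np.errstate(divide="ignore"):
        x = (ca / ec50) ** n
    out = amplitude * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


@dataclass
class HillFit:
    """Fitted Hill Ca2+ dependence of complex formation."""

    ec50: float            # µM
    hill_n: float
    amplitude: float
    ec50_stderr: float
    n_stderr: float
    rss: float
    n_points: int
    converged: bool
    amplitude_free: bool = False

    def predict(self, ca):
        return predict_hill(ca, self.ec50, self.hill_n, self.amplitude)

    def summary(self) -> str:
        return (
            f"EC50(Ca2+) = {self.ec50:.6g} +/- {self.ec50_stderr:.3g} uM, "
            f"n = {self.hill_n:.4g} +/- {self.n_stderr:.3g}, "
            f"amplitude = {self.amplitude:.4g}"
            f"{' (free)' if self.amplitude_free else ' (fixed)'}, "
            f"RSS = {self.rss:.4g} over {self.n_points} points"
        )


class HillModel:
    """Hill dose–response model for bound fraction versus free Ca2+."""

    def __init__(self, free_ca, bs_fract, min_points: int = 5):
        self.free_ca = np.asarray(free_ca, dtype=float)
        self.bs_fract = np.asarray(bs_fract, dtype=float)
        if self.free_ca.shape != self.bs_fract.shape:
            raise ParameterError("free_ca and bs_fract must have equal length")
        if len(self.free_ca) < min_points:
            raise ParameterError(f"at least {min_points} points are required")
        if np.any(self.free_ca <= 0):
            raise ParameterError("free_ca must be strictly positive")

    def _residuals(self, theta, fit_amplitude):
        lec, n = theta[0], theta[1]
        amp = theta[2] if fit_amplitude else 1.0
        return predict_hill(self.free_ca, 10.0 ** lec, n, amp) - self.bs_fract

    def fit(self, fit_amplitude: bool = False) -> HillFit:
        """Multi-start least-squares fit of (EC50, n[, amplitude])."""
        if self.bs_fract.max() < 1e-9:
            raise FitFailureError("no signal: all fractional responses are zero")
        seeds_ec = list(_EC50_SEEDS)
        half = 0.5 * self.bs_fract.max()
        idx = int(np.argmin(np.abs(self.bs_fract - half)))
        seeds_ec.insert(0, float(self.free_ca[idx]))

        lo = [_LOG_EC50_BOUNDS[0], _HILL_N_BOUNDS[0]]
        hi = [_LOG_EC50_BOUNDS[1], _HILL_N_BOUNDS[1]]
        if fit_amplitude:
            lo.append(1e-6)
            hi.append(1.0)

        best = None
        diagnostics = []
        for ec0 in seeds_ec:
            lec0 = float(np.clip(np.log10(ec0), *_LOG_EC50_BOUNDS))
            for n0 in _N_SEEDS:
                x0 = [lec0, n0]
                if fit_amplitude:
                    x0.append(min(1.0, max(1e-3, float(self.bs_fract.max()))))
                try:
                    sol = least_squares(
                        self._residuals, np.array(x0), args=(fit_amplitude,),
                        bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
                        max_nfev=2000,
                    )
                except Exception as exc:  # pragma: no cover
                    diagnostics.append(f"start {x0}: {exc}")
                    continue
                if not sol.success:
                    diagnostics.append(f"start {x0}: {sol.message}")
                    continue
                rss = float(2.0 * sol.cost)
                ec = 10.0 ** sol.x[0]
                if best is None or rss < best[0] - 1e-14 or (
                    abs(rss - best[0]) < 1e-14 and ec < best[1]
                ):
                    best = (rss, ec, sol)
        if best is None:
            raise FitFailureError("Hill fit did not converge from any start",
                                  diagnostics)
        rss, ec, sol = best
        n_par = len(sol.x)
        n_pts = len(self.free_ca)
        bse = np.full(n_par, np.nan)
        if n_pts > n_par:
            s2 = rss / (n_pts - n_par)
            try:
                cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
                bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                pass
        return HillFit(
            ec50=ec, hill_n=float(sol.x[1]),
            amplitude=float(sol.x[2]) if fit_amplitude else 1.0,
            ec50_stderr=float(ec * np.log(10.0) * bse[0]),
            n_stderr=float(bse[1]),
            rss=rss, n_points=n_pts, converged=True,
            amplitude_free=fit_amplitude,
        )


def fit_hill(free_ca, bs_fract, fit_amplitude: bool = False) -> HillFit:
    """Fit a Hill curve to bound fraction versus free Ca2+ (µM)."""
    return HillModel(free_ca, bs_fract).fit(fit_amplitude=fit_amplitude)


def fit_hill_mixture(free_ca, bs_fract) -> tuple[HillFit, HillFit, float]:
    """Two-component sum-of-Hills fit: w·H1 + (1−w)·H2.

    A labelled alternative to the segmented decomposition; it estimates both
    species jointly instead of reproducing the segmented procedure, and is
    never used by default.  Returns (species1, species2, weight1) with
    species 1 the lower-EC50 component.
    """
    ca = np.asarray(free_ca, dtype=float)
    y = np.asarray(bs_fract, dtype=float)
    if len(ca) < 7:
        raise ParameterError("at least 7 points are required for a mixture fit")

    def resid(theta):
        l1, n1, l2, n2, w = theta
        return (w * predict_hill(ca, 10.0 ** l1, n1)
                + (1.0 - w) * predict_hill(ca, 10.0 ** l2, n2) - y)

    lo = [-3, 0.3, -3, 0.3, 0.01]
    hi = [3, 6.0, 3, 6.0, 0.99]
    best = None
    for l1 in (-1.0, -0.5):
        for l2 in (0.3, 0.8):
            sol = least_squares(resid, np.array([l1, 1.5, l2, 2.0, 0.3]),
                                bounds=(lo, hi), xtol=1e-14, ftol=1e-14,
                                max_nfev=4000)
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
    if best is None:
        raise FitFailureError("mixture fit did not converge")
    l1, n1, l2, n2, w = best.x
    rss = float(2.0 * best.cost)
    if l1 > l2:  # order species by EC50
        l1, n1, l2, n2, w = l2, n2, l1, n1, 1.0 - w
    mk = lambda l, n, a: HillFit(10.0 ** l, float(n), float(a), np.nan, np.nan,
                                 rss, len(ca), True, amplitude_free=True)
    return mk(l1, n1, w), mk(l2, n2, 1.0 - w), float(w)


@dataclass
class CaSensitivityResult:
    """Ca2+ sensitivity of biosensor–CaM complex formation.

    ``species2_or_global`` is the Hill fit over the entire population; when the
    response is biphasic it tracks the more abundant low-sensitivity species,
    as in the segmented procedure this package follows.
    """

    species1: Optional[HillFit]
    species2_or_global: Optional[HillFit]
    biphasic: bool
    breakpoint: float
    free_ca: np.ndarray
    bs_fract: np.ndarray
    f_pvalue: float = np.nan
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Ca2+ sensitivity of biosensor-CaM interaction",
                 "=" * 46,
                 f"n points           : {len(self.free_ca)}",
                 f"biphasic           : {self.biphasic} "
                 f"(breakpoint {self.breakpoint:g} uM, F-test p = {self.f_pvalue:.3g})"]
        if self.species1 is not None:
            lines.append(f"species 1 (<= breakpoint): {self.species1.summary()}")
        if self.species2_or_global is not None:
            tag = "species 2 (global)" if self.biphasic else "global"
            lines.append(f"{tag:<25}: {self.species2_or_global.summary()}")
        if self.species2_or_global is None:
            lines.append("no fit attempted (no Ca2+ signal)")
        for w in self.warnings:
            lines.append(f"note: {w}")
        return "\n".join(lines)


def decompose_biphasic(free_ca, bs_fract, breakpoint: float = DEFAULT_BREAKPOINT,
                       alpha: float = 0.05) -> CaSensitivityResult:
    """Segmented Hill decomposition of a possibly biphasic Ca2+ response.

    Species 1 is fit (amplitude free) on points with free Ca2+ ≤ breakpoint;
    the global fit over all points stands for species 2 (or the single
    species).  The curve is declared biphasic when the species-1 fit converges
    with amplitude ≥ 0.05 and EC50 below the breakpoint, the global EC50 sits
    at or above the breakpoint, and a segmented model (independent low/high
    Hill fits) beats the single global fit by an F-ratio test at ``alpha``.
    """
    ca = np.asarray(free_ca, dtype=float)
    y = np.asarray(bs_fract, dtype=float)
    warn: list[str] = []

    pos = ca > 0
    if not np.all(pos):
        warn.append(f"{int((~pos).sum())} zero-Ca2+ point(s) excluded from fits")
    ca_f, y_f = ca[pos], y[pos]

    if len(ca_f) < 5 or y_f.max() < 1e-9:
        return CaSensitivityResult(
            species1=None, species2_or_global=None, biphasic=False,
            breakpoint=breakpoint, free_ca=ca, bs_fract=y,
            warnings=warn + ["no fit attempted (no Ca2+ signal)"],
        )

    glob = HillModel(ca_f, y_f).fit(fit_amplitude=False)

    low = ca_f <= breakpoint
    high = ~low
    species1 = None
    p_value = np.nan
    if low.sum() >= 4:
        try:
            species1 = HillModel(ca_f[low], y_f[low], min_points=4).fit(
                fit_amplitude=True)
        except FitFailureError as exc:
            warn.append(f"species-1 fit failed: {exc}")
    else:
        warn.append(
            f"only {int(low.sum())} point(s) below the {breakpoint:g} µM "
            "breakpoint; species-1 fit not attempted"
        )

    biphasic = False
    if species1 is not None and high.sum() >= 4:
        try:
            high_fit = HillModel(ca_f[high], y_f[high], min_points=4).fit(
                fit_amplitude=True)
        except FitFailureError:
            high_fit = None
        if high_fit is not None:
            rss_seg = species1.rss + high_fit.rss
            rss_glob = glob.rss
            n = len(ca_f)
            k_glob, k_seg = 2, 6
            df1, df2 = k_seg - k_glob, n - k_seg
            if df2 > 0:
                if rss_glob <= 1e-16 * n:
                    p_value = 1.0  # global fit already exact
                elif rss_seg <= 0:
                    p_value = 0.0
                else:
                    f_stat = ((rss_glob - rss_seg) / df1) / (rss_seg / df2)
                    p_value = float(f_dist.sf(max(f_stat, 0.0), df1, df2))
            biphasic = bool(
                species1.converged
                and species1.amplitude >= 0.05
                and species1.ec50 < breakpoint
                and glob.ec50 >= breakpoint
                and np.isfinite(p_value)
                and p_value < alpha
            )

    return CaSensitivityResult(
        species1=species1, species2_or_global=glob, biphasic=biphasic,
        breakpoint=breakpoint, free_ca=ca, bs_fract=y, f_pvalue=p_value,
        warnings=warn,
    )


def run_ca_assay(assay: CaAssaySeries, breakpoint: float = DEFAULT_BREAKPOINT,
                 alpha: float = 0.05) -> CaSensitivityResult:
    """Full Ca2+-sensitivity pipeline on one assay.

    Indicator intensities are dilution-corrected from the assay's volume
    schedule before use (the emission ratio needs no correction).  Indicator
    endpoints come from the calibration records: the nominally Ca2+-free first
    point and the Ca2+-saturating final addition (or the explicit
    ``indicator_f_min``/``indicator_f_max`` fields, which must already be
    dilution-corrected).  Biosensor ratio endpoints come from the same two
    states.  Indicator-saturated points (within 0.1% of F_max) serve only as
    endpoints and are excluded from the Hill fits.
    """
    added = np.cumsum([p.added_volume for p in assay.points])
    factor = (assay.initial_volume + added) / assay.initial_volume
    f_ind = assay.f_indicator * factor
    f_min = assay.indicator_f_min if assay.indicator_f_min is not None else float(f_ind[0])
    f_max = assay.indicator_f_max if assay.indicator_f_max is not None else float(f_ind.max())
    if f_max <= f_min:
        return CaSensitivityResult(
            species1=None, species2_or_global=None, biphasic=False,
            breakpoint=breakpoint, free_ca=np.zeros(len(assay)),
            bs_fract=np.zeros(len(assay)),
            warnings=["indicator shows no Ca2+ response; all free Ca2+ = 0, "
                      "no fit attempted"],
        )

    span = f_max - f_min
    saturated = (f_max - f_ind) < _SATURATION_FRACTION * span
    warn: list[str] = []
    if saturated.any():
        warn.append(
            f"{int(saturated.sum())} indicator-saturated point(s) used as "
            "calibration endpoints and excluded from fits "
            f"(indices {[int(i) for i in np.nonzero(saturated)[0]]})"
        )

    free_ca = np.zeros(len(assay))
    free_ca[~saturated] = free_calcium(f_ind[~saturated], f_min, f_max,
                                       assay.indicator_kd)
    free_ca[saturated] = np.inf

    # biosensor endpoints: the Ca2+-free start and saturating end coincide
    # with the observed extrema noiselessly; using the extrema keeps endpoint
    # noise from pushing fractions outside [0, 1]
    ratios = assay.ratios
    r_min = float(ratios.min())
    r_max = float(ratios.max())
    if r_max <= r_min:
        return CaSensitivityResult(
            species1=None, species2_or_global=None, biphasic=False,
            breakpoint=breakpoint, free_ca=free_ca, bs_fract=np.zeros(len(assay)),
            warnings=warn + ["flat biosensor ratio; no fit attempted"],
        )
    bs_fract = fractional_from_ratio(ratios, r_min, r_max)

    result = decompose_biphasic(free_ca[~saturated], bs_fract[~saturated],
                                breakpoint=breakpoint, alpha=alpha)
    result.free_ca = free_ca
    result.bs_fract = bs_fract
    result.warnings = warn + result.warnings
    return result
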