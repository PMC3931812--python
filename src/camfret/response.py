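"""Fractional FRET response, dynamic range, and dilution correction.

Binding of Ca2+-CaM to the biosensor linker disrupts FRET: donor emission
(475 nm) rises, acceptor emission (535 nm) falls.  The fractional response
places the observed signal between the unbound and maximally bound endpoints:

    BS_fract = (R - R_min) / (R_max - R_min)            (ratio channel)
    BS_fract = (F - F_min) / (F_max - F_min)            (donor channel)
    BS_fract = (F_max - F) / (F_max - F_min)            (acceptor channel)

where R = F475/F535.  Intensity channels must be dilution-corrected first;
the ratio is invariant under the common dilution factor and needs none.
"""

from __future__ import annotations

import warnings as _warnings

import numpy as np

from .errors import (
    DegenerateEndpointsError,
    OutOfRangeError,
    ScheduleError,
)
from .series import ResponseSeries, TitrationSeries

#: Fractional responses may overshoot [0, 1] by this much (noise at the
#: endpoints) before being treated as data errors rather than clamped.
CLAMP_TOLERANCE = 0.05


def clamp_fraction(f, tol: float = CLAMP_TOLERANCE, label: str = "BS_fract"):
    """Clamp fractions to [0, 1], warning on small excursions, erroring on large.

    Accepts scalars or arrays; returns the same shape.
    """
    arr = np.asarray(f, dtype=float)
    low, high = arr.min(), arr.max()
    if low < -tol or high > 1.0 + tol:
        raise OutOfRangeError(
            f"{label} outside [0, 1] by more than the clamp tolerance "
            f"{tol} (range [{low:.4g}, {high:.4g}])"
        )
    if low < 0 or high > 1:
        _warnings.warn(
            f"{label} clamped to [0, 1] (observed range [{low:.4g}, {high:.4g}])",
            stacklevel=2,
        )
    clipped = np.clip(arr, 0.0, 1.0)
    return float(clipped) if np.isscalar(f) or np.ndim(f) == 0 else clipped


def fractional_from_ratio(r, r_min: float, r_max: float, clamp: bool = True):
    """Fractional response from the F475/F535 emission ratio.

    Parameters
    ----------
    r : float or array
        Observed ratio(s).
    r_min, r_max : float
        Ratios in the unbound and maximally bound state.
    """
    if r_max == r_min:
        raise DegenerateEndpointsError("r_max == r_min: ratio endpoints are degenerate")
    f = (np.asarray(r, dtype=float) - r_min) / (r_max - r_min)
    if clamp:
        f = clamp_fraction(f)
    return float(f) if np.ndim(r) == 0 else f


def fractional_from_intensity(f, f_min: float, f_max: float, channel: str,
                              clamp: bool = True):
    """Fractional response from a single dilution-corrected intensity channel.

    The donor intensity rises on binding, the acceptor falls, so the acceptor
    normalization is inverted: ``(f_max - f) / (f_max - f_min)``.
    """
    if f_max <= f_min:
        raise DegenerateEndpointsError("f_max must exceed f_min")
    if channel == "donor":
        frac = (np.asarray(f, dtype=float) - f_min) / (f_max - f_min)
    elif channel == "acceptor":
        frac = (f_max - np.asarray(f, dtype=float)) / (f_max - f_min)
    else:
        raise ValueError(f"channel must be 'donor' or 'acceptor', got {channel!r}")
    if clamp:
        frac = clamp_fraction(frac)
    return float(frac) if np.ndim(f) == 0 else frac


def dynamic_range(r_min: float, r_max: float) -> float:
    """Fold difference R_max / R_min; proxies the conformational change."""
    if r_min <= 0:
        raise OutOfRangeError("r_min must be > 0 for a fold dynamic range")
    if r_max < r_min:
        raise OutOfRangeError("r_max must be >= r_min")
    return r_max / r_min


def apply_dilution_correction(series: TitrationSeries,
                              channel: str = "ratio") -> ResponseSeries:
    """Compute cumulative titrant totals and dilution-corrected responses.

    At point k with cumulative added volume W_k into starting volume V0:

    * titrant total   C_k = stock × W_k / (V0 + W_k)   (conservation of mass;
      supports per-step stock concentrations by summing moles),
    * intensities are multiplied by (V0 + W_k) / V0 before use in the
      intensity-channel normalizations,
    * the ratio channel passes through unchanged.

    ``channel`` selects which normalization downstream fits will use; the
    endpoints r_min/r_max (or intensity endpoints) recorded here are the
    *observed* first/last values and serve only to seed fits.
    """
    if channel not in ("ratio", "donor", "acceptor"):
        raise ValueError(f"unknown channel {channel!r}")
    v0 = series.initial_volume
    added = np.array([p.added_volume for p in series.points], dtype=float)
    if np.any(added < 0):
        raise ScheduleError("negative added volume in schedule")
    cum_vol = np.cumsum(added)
    stock = np.array([p.stock_concentration for p in series.points], dtype=float)
    # moles (µM·µL) added at each step, cumulated; supports varying stocks
    cum_moles = np.cumsum(added * stock)
    total_vol = v0 + cum_vol
    titrant_total = cum_moles / total_vol
    factor = total_vol / v0

    f_donor = np.array([p.f_donor for p in series.points]) * factor
    f_acceptor = np.array([p.f_acceptor for p in series.points]) * factor
    ratio = series.ratios

    warn: list[str] = []
    r_min_obs, r_max_obs = float(ratio[0]), float(ratio[-1])
    if r_max_obs < r_min_obs:
        warn.append("observed ratio decreases over the titration; endpoints swapped")
        r_min_obs, r_max_obs = r_max_obs, r_min_obs

    if channel == "ratio":
        # normalize the fraction trace by the observed extrema so endpoint
        # noise cannot push it outside [0, 1]; the first/last-point endpoints
        # recorded above only seed downstream fits
        lo, hi = float(ratio.min()), float(ratio.max())
        if hi > lo:
            bs = clamp_fraction((ratio - lo) / (hi - lo))
        else:
            bs = np.zeros_like(ratio)
            warn.append("flat ratio response; fractions set to 0")
    else:
        sig = f_donor if channel == "donor" else f_acceptor
        lo, hi = float(sig.min()), float(sig.max())
        if hi > lo:
            bs = fractional_from_intensity(sig, lo, hi, channel)
        else:
            bs = np.zeros_like(sig)
            warn.append("flat intensity response; fractions set to 0")

    return ResponseSeries(
        titrant_total=titrant_total,
        ratio=ratio,
        bs_fract=bs,
        channel_used=channel,
        r_min=r_min_obs,
        r_max=r_max_obs,
        f_donor=f_donor,
        f_acceptor=f_acceptor,
        warnings=warn,
    )
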