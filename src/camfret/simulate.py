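"""Synthetic titration generator.

Emulates the spectrofluorometer experiments the analysis consumes:

* CaM titrations at saturating Ca2+ — per-addition dilution of a concentrated
  CaM stock into the cuvette, bound fraction from the depletion (quadratic) or
  hyperbolic isotherm, donor/acceptor channels in either ``ideal_ratio`` or
  ``spectral`` mode, optional multiplicative Gaussian channel noise;
* Ca2+ titrations at saturating CaM — chelator-buffered free Ca2+ from a
  mass-balance solver, an indicator channel (X-Rhod5F-like, K_d 1.6 µM), and a
  mono- or biphasic (two-species) biosensor Hill response, ending in a
  Ca2+-saturating calibration spike;
* endpoint emission spectra built from Gaussian donor/acceptor peaks.

In ``ideal_ratio`` mode the acceptor channel is held constant and the donor
carries the whole response, making the emission ratio affine in bound
fraction; this is the mode in which ratio- and donor-normalized fractional
responses are exact.  ``spectral`` mode uses physically reciprocal channels
(donor rises, acceptor falls), so the ratio is a Möbius — not affine —
function of bound fraction.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConfigurationError, ScheduleError, SolverError
from .series import CaAssaySeries, TitrationPoint, TitrationSeries

# Default chelator/indicator Ca2+ dissociation constants (µM) at the assay's
# ionic conditions; conventions of this package, configurable per assay.
BAPTA_KD = 0.16
BR2BAPTA_KD = 1.6
CAM_SITE_KD = 10.0  # per-site, CaM modeled as 4 identical independent sites


@dataclass(frozen=True)
class BufferSpecies:
    """A Ca2+-binding species contributing 1:1 site buffering."""

    name: str
    total: float          # µM
    kd_ca: float          # µM per site
    n_sites: int = 1

    def __post_init__(self):
        if self.total < 0:
            raise ConfigurationError(f"{self.name}: total must be >= 0")
        if self.kd_ca <= 0:
            raise ConfigurationError(f"{self.name}: kd_ca must be > 0")
        if self.n_sites < 1:
            raise ConfigurationError(f"{self.name}: n_sites must be >= 1")


@dataclass(frozen=True)
class HillSpecies:
    """One complex species in a Ca2+ assay: Hill parameters and mixture weight."""

    ec50: float           # µM
    n: float
    weight: float = 1.0


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the assay design the analysis targets: 0.5 µM biosensor in
    a 2 mL cuvette at 22 °C, noiseless unless ``noise_sigma`` is set.
    """

    true_kd: Optional[float] = None          # µM, CaM titrations
    binding_model: str = "quadratic"         # generator isotherm
    hill_species: Optional[Sequence[HillSpecies]] = None  # Ca2+ assays
    bs_total: float = 0.5                    # µM
    r_min: float = 1.0
    r_max: float = 2.0
    mode: str = "ideal_ratio"                # or "spectral"
    noise_sigma: float = 0.0                 # relative, per channel per point
    seed: int = 0
    schedule: Optional[list[tuple[float, float]]] = None  # (µL, µM stock)
    initial_volume: float = 2000.0           # µL
    max_volume: float = 4000.0               # µL cuvette capacity
    n_points: int = 30
    span: tuple[float, float] = (0.01, 100.0)  # titrant grid, × true Kd
    base_intensity: float = 1.0e5            # a.u., acceptor at f = 0
    # spectral mode
    acceptor_drop: float = 0.3               # fractional acceptor loss at f = 1
    donor_center: float = 475.0
    acceptor_center: float = 535.0
    donor_width: float = 15.0                # nm, Gaussian sigma
    acceptor_width: float = 12.0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.mode not in ("ideal_ratio", "spectral"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.hill_species is not None:
            w = sum(s.weight for s in self.hill_species)
            if abs(w - 1.0) > 1e-9:
                raise ConfigurationError("hill species weights must sum to 1")
        if not 0 <= self.acceptor_drop < 1:
            raise ConfigurationError("acceptor_drop must be in [0, 1)")


# -- free Ca2+ speciation ---------------------------------------------------

def bound_calcium(x: float, buffers: Sequence[BufferSpecies]) -> float:
    """Ca2+ bound to all buffer sites at free Ca2+ ``x`` (µM)."""
    return sum(b.n_sites * b.total * x / (b.kd_ca + x) for b in buffers)


def solve_free_ca(ca_total: float, buffers: Sequence[BufferSpecies]) -> float:
    """Free Ca2+ from total Ca2+ and 1:1-site buffer speciation.

    Solves ``ca_total = x + Σ_j n_j·T_j·x/(K_j + x)`` for the unique x ≥ 0 by
    bracketed root-finding; the left side is strictly increasing in x.
    """
    if ca_total < 0:
        raise ConfigurationError("ca_total must be >= 0")
    if ca_total == 0 or not buffers:
        return float(ca_total)

    def balance(x):
        return x + bound_calcium(x, buffers) - ca_total

    hi = ca_total  # free Ca2+ can never exceed total
    if balance(hi) < 0:
        raise SolverError(
            f"mass balance not bracketed on [0, {hi}] (residual {balance(hi)})"
        )
    try:
        x = brentq(balance, 0.0, hi, xtol=1e-15, rtol=1e-14, maxiter=200)
    except Exception as exc:
        raise SolverError(f"free-Ca2+ root finding failed: {exc}") from exc
    resid = abs(balance(x)) / max(ca_total, 1.0)
    if resid > 1e-9:
        raise SolverError(f"conservation residual {resid:.2e} exceeds 1e-9")
    return float(x)


def total_from_free_ca(x: float, buffers: Sequence[BufferSpecies]) -> float:
    """Closed-form inverse of :func:`solve_free_ca` (used in schedule design)."""
    return x + bound_calcium(x, buffers)


# -- schedules ---------------------------------------------------------------

def design_schedule(targets: Sequence[float], initial_volume: float,
                    stock_factor: float = 20.0) -> list[tuple[float, float]]:
    """Per-step (added volume µL, stock µM) reaching given cumulative totals.

    The targets are dilution-corrected cumulative titrant totals; a single
    stock at ``stock_factor`` × the largest target keeps the added volume to a
    few percent of the starting volume.  Conservation of mass gives the
    cumulative added volume W_k = C_k·V0 / (S − C_k).
    """
    targets = np.asarray(targets, dtype=float)
    if np.any(np.diff(targets) <= 0) or targets[0] <= 0:
        raise ScheduleError("targets must be positive and strictly increasing")
    stock = stock_factor * targets[-1]
    cum_vol = targets * initial_volume / (stock - targets)
    volumes = np.diff(np.concatenate([[0.0], cum_vol]))
    return [(float(v), float(stock)) for v in volumes]


def _default_cam_schedule(config: GeneratorConfig) -> list[tuple[float, float]]:
    lo, hi = config.span
    targets = np.geomspace(lo * config.true_kd, hi * config.true_kd,
                           config.n_points)
    return design_schedule(targets, config.initial_volume)


def _cumulative_totals(schedule, initial_volume):
    vols = np.array([v for v, _ in schedule])
    stocks = np.array([s for _, s in schedule])
    if np.any(vols < 0):
        raise ScheduleError("negative added volume")
    cum_vol = np.cumsum(vols)
    totals = np.cumsum(vols * stocks) / (initial_volume + cum_vol)
    return cum_vol, totals


# -- emission channels -------------------------------------------------------

def _gauss_band(center: float, width: float, band: tuple[float, float]) -> float:
    """Integral of a unit-amplitude Gaussian peak over a wavelength band."""
    a, b = band
    z = lambda t: (t - center) / (width * math.sqrt(2.0))
    return width * math.sqrt(math.pi / 2.0) * (math.erf(z(b)) - math.erf(z(a)))


DONOR_BAND = (470.0, 480.0)
ACCEPTOR_BAND = (530.0, 540.0)


def _channel_endpoints(config: GeneratorConfig):
    """Endpoint (F475, F535) channel intensities for unbound and bound states."""
    base = config.base_intensity
    f535_0, f535_1 = base, base * (1.0 - config.acceptor_drop)
    f475_0, f475_1 = config.r_min * f535_0, config.r_max * f535_1
    return (f475_0, f535_0), (f475_1, f535_1)


def _spectral_amplitudes(config: GeneratorConfig):
    """Gaussian peak amplitudes reproducing the endpoint band intensities."""
    m = np.array([
        [_gauss_band(config.donor_center, config.donor_width, DONOR_BAND),
         _gauss_band(config.acceptor_center, config.acceptor_width, DONOR_BAND)],
        [_gauss_band(config.donor_center, config.donor_width, ACCEPTOR_BAND),
         _gauss_band(config.acceptor_center, config.acceptor_width, ACCEPTOR_BAND)],
    ])
    (f475_0, f535_0), (f475_1, f535_1) = _channel_endpoints(config)
    amp0 = np.linalg.solve(m, [f475_0, f535_0])
    amp1 = np.linalg.solve(m, [f475_1, f535_1])
    if np.any(amp0 < 0) or np.any(amp1 < 0):
        raise ConfigurationError(
            "endpoint spectra are not realizable with non-negative peaks; "
            "adjust r_min/r_max/acceptor_drop"
        )
    return amp0, amp1


def _channels_at_fraction(f, config: GeneratorConfig):
    """Ideal (undiluted) donor and acceptor channel intensities at fraction f."""
    f = np.asarray(f, dtype=float)
    if config.mode == "ideal_ratio":
        f535 = np.full_like(f, config.base_intensity)
        ratio = config.r_min + (config.r_max - config.r_min) * f
        return f535 * ratio, f535
    (f475_0, f535_0), (f475_1, f535_1) = _channel_endpoints(config)
    return f475_0 + (f475_1 - f475_0) * f, f535_0 + (f535_1 - f535_0) * f


def synthesize_spectrum(bound_fraction: float, config: GeneratorConfig):
    """Emission spectrum (450–600 nm, 1 nm grid) at a given bound fraction.

    The spectrum interpolates linearly between unbound and bound endpoint
    spectra, each the sum of Gaussian donor and acceptor peaks whose band
    integrals over 470–480 and 530–540 nm equal the configured channel
    intensities.
    """
    if not 0.0 <= bound_fraction <= 1.0:
        raise ConfigurationError("bound_fraction must lie in [0, 1]")
    amp0, amp1 = _spectral_amplitudes(config)
    wl = np.arange(450.0, 600.0 + 1e-9, 1.0)
    gd = np.exp(-0.5 * ((wl - config.donor_center) / config.donor_width) ** 2)
    ga = np.exp(-0.5 * ((wl - config.acceptor_center) / config.acceptor_width) ** 2)
    ad = amp0[0] + (amp1[0] - amp0[0]) * bound_fraction
    aa = amp0[1] + (amp1[1] - amp0[1]) * bound_fraction
    return wl, ad * gd + aa * ga


# -- generators --------------------------------------------------------------

def _apply_noise(rng, sigma, *channels):
    if sigma == 0:
        return channels
    return tuple(c * (1.0 + sigma * rng.standard_normal(np.shape(c)))
                 for c in channels)


def simulate_cam_titration(config: GeneratorConfig) -> TitrationSeries:
    """Simulate a CaM titration at saturating Ca2+.

    Bound fraction comes from the configured isotherm on dilution-corrected
    CaM totals; measured intensities carry the biosensor dilution factor
    V0/(V0+W) and, when ``noise_sigma`` > 0, i.i.d. multiplicative Gaussian
    noise per channel per point.  Deterministic given ``config.seed``.
    """
    if config.true_kd is None or config.true_kd <= 0:
        raise ConfigurationError("simulate_cam_titration requires true_kd > 0")
    schedule = config.schedule or _default_cam_schedule(config)
    cum_vol, totals = _cumulative_totals(schedule, config.initial_volume)
    if config.initial_volume + cum_vol[-1] > config.max_volume:
        raise ScheduleError(
            f"schedule exceeds cuvette capacity {config.max_volume} µL"
        )

    from .binding import predict_hyperbolic, predict_quadratic  # cycle guard

    if config.binding_model == "quadratic":
        frac = predict_quadratic(totals, config.bs_total, config.true_kd)
    elif config.binding_model == "hyperbolic":
        frac = predict_hyperbolic(totals, config.true_kd)
    else:
        raise ConfigurationError(f"unknown binding_model {config.binding_model!r}")

    # prepend the zero-CaM baseline
    frac = np.concatenate([[0.0], frac])
    dil = np.concatenate([[1.0],
                          config.initial_volume / (config.initial_volume + cum_vol)])
    volumes = np.concatenate([[0.0], [v for v, _ in schedule]])
    stocks = np.concatenate([[schedule[0][1]], [s for _, s in schedule]])

    f475, f535 = _channels_at_fraction(frac, config)
    f475, f535 = f475 * dil, f535 * dil
    rng = np.random.default_rng(config.seed)
    f475, f535 = _apply_noise(rng, config.noise_sigma, f475, f535)

    points = [
        TitrationPoint(step_index=i, added_volume=float(volumes[i]),
                       stock_concentration=float(stocks[i]),
                       f_donor=float(f475[i]), f_acceptor=float(f535[i]))
        for i in range(len(frac))
    ]
    return TitrationSeries(points=points, initial_volume=config.initial_volume,
                           biosensor_total=config.bs_total, titrant_name="CaM")


def default_ca_buffers(cam_total: float,
                       chelator_total: float = 250.0,
                       chelator_kd: float = BR2BAPTA_KD,
                       indicator_total: float = 2.0,
                       indicator_kd: float = 1.6,
                       cam_site_kd: float = CAM_SITE_KD) -> list[BufferSpecies]:
    """Default Ca2+-buffer mixture of the sensitivity assay.

    0.25 mM Br2BAPTA, 2 µM indicator, and CaM as four identical independent
    Ca2+ sites.  Pass ``chelator_total=0`` and ``cam_total=0`` for an
    unbuffered titration.
    """
    buffers = []
    if chelator_total > 0:
        buffers.append(BufferSpecies("Br2BAPTA", chelator_total, chelator_kd))
    if indicator_total > 0:
        buffers.append(BufferSpecies("indicator", indicator_total, indicator_kd))
    if cam_total > 0:
        buffers.append(BufferSpecies("CaM", cam_total, cam_site_kd, n_sites=4))
    return buffers


def simulate_ca_assay(config: GeneratorConfig,
                      buffers: Optional[Sequence[BufferSpecies]] = None,
                      indicator: Optional[BufferSpecies] = None,
                      indicator_f_min: float = 100.0,
                      indicator_f_max: float = 1000.0,
                      cam_total: float = 20.0,
                      free_ca_span: tuple[float, float] = (0.01, 100.0),
                      saturating_free_ca: float = 5000.0) -> CaAssaySeries:
    """Simulate a Ca2+ titration at saturating CaM with an indicator channel.

    Per addition: free Ca2+ from :func:`solve_free_ca` on the diluted totals →
    indicator fluorescence from its saturation curve → biosensor bound
    fraction as the weighted sum of the configured Hill species → channels per
    mode, all scaled by the dilution factor, plus seeded noise.  The schedule
    targets ``config.n_points`` log-spaced free-Ca2+ values spanning
    ``free_ca_span`` × the extreme species EC50s and ends with a saturating
    calibration spike.  Deterministic given ``config.seed``.
    """
    if not config.hill_species:
        raise ConfigurationError("simulate_ca_assay requires hill_species")
    if indicator is None:
        indicator = BufferSpecies("indicator", 2.0, 1.6)
    if buffers is None:
        buffers = default_ca_buffers(cam_total,
                                     indicator_total=indicator.total,
                                     indicator_kd=indicator.kd_ca)

    ec_lo = min(s.ec50 for s in config.hill_species)
    ec_hi = max(s.ec50 for s in config.hill_species)
    free_targets = np.geomspace(free_ca_span[0] * ec_lo,
                                free_ca_span[1] * ec_hi, config.n_points)
    free_targets = np.append(free_targets, saturating_free_ca)
    # totals needed at starting buffer concentrations (dilution handled below)
    ca_targets = np.array([total_from_free_ca(x, buffers) for x in free_targets])
    schedule = config.schedule or design_schedule(
        ca_targets, config.initial_volume, stock_factor=100.0)
    cum_vol, totals = _cumulative_totals(schedule, config.initial_volume)

    v0 = config.initial_volume
    dil = v0 / (v0 + cum_vol)
    rng = np.random.default_rng(config.seed)

    # baseline: nominally Ca2+-free
    free = [0.0]
    for k in range(len(schedule)):
        dbuf = [replace(b, total=b.total * dil[k]) for b in buffers]
        free.append(solve_free_ca(totals[k], dbuf))
    free = np.array(free)
    dil = np.concatenate([[1.0], dil])
    volumes = np.concatenate([[0.0], [v for v, _ in schedule]])
    stocks = np.concatenate([[schedule[0][1]], [s for _, s in schedule]])

    f_ind = indicator_f_min + (indicator_f_max - indicator_f_min) * (
        free / (indicator.kd_ca + free))
    frac = sum(s.weight * _hill(free, s.ec50, s.n) for s in config.hill_species)
    f475, f535 = _channels_at_fraction(frac, config)
    f475, f535, f_ind = f475 * dil, f535 * dil, f_ind * dil
    f475, f535, f_ind = _apply_noise(rng, config.noise_sigma, f475, f535, f_ind)

    points = [
        TitrationPoint(step_index=i, added_volume=float(volumes[i]),
                       stock_concentration=float(stocks[i]),
                       f_donor=float(f475[i]), f_acceptor=float(f535[i]),
                       f_indicator=float(f_ind[i]))
        for i in range(len(free))
    ]
    return CaAssaySeries(points=points, initial_volume=v0, cam_total=cam_total,
                         indicator_kd=indicator.kd_ca)


def _hill(x, ec50, n):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore"):
        t = (x / ec50) ** n
    return t / (1.0 + t)
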