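"""Containers for titration records.

A titration is an ordered list of additions of a concentrated titrant stock
into a cuvette of known starting volume while donor (475 nm), acceptor
(535 nm) and optionally Ca2+-indicator (600 nm) emission intensities are
recorded.  Volumes are microlitres, concentrations micromolar, intensities
arbitrary units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError


@dataclass(frozen=True)
class TitrationPoint:
    """One addition step of a titration.

    ``added_volume`` is the volume of titrant stock added at this step (0 for
    the baseline record), not the cumulative volume.
    """

    step_index: int
    added_volume: float          # µL
    stock_concentration: float   # µM
    f_donor: float               # a.u. at 475 nm
    f_acceptor: float            # a.u. at 535 nm
    f_indicator: Optional[float] = None  # a.u. at 600 nm

    def __post_init__(self):
        if self.added_volume < 0:
            raise ConfigurationError(
                f"step {self.step_index}: added_volume must be >= 0"
            )
        if self.f_donor <= 0 or self.f_acceptor <= 0:
            raise ConfigurationError(
                f"step {self.step_index}: channel intensities must be > 0"
            )

    @property
    def ratio(self) -> float:
        """Donor/acceptor emission ratio (F475/F535)."""
        return self.f_donor / self.f_acceptor


def _check_points(points: Sequence[TitrationPoint]) -> None:
    if not points:
        raise ConfigurationError("a titration needs at least one point")
    steps = [p.step_index for p in points]
    if any(b <= a for a, b in zip(steps, steps[1:])):
        raise ConfigurationError("step indices must be strictly increasing")
    if points[0].added_volume != 0:
        raise ConfigurationError("the baseline point (step 0) must have added_volume == 0")


@dataclass
class TitrationSeries:
    """A CaM (titrant) titration at saturating Ca2+.

    ``biosensor_total`` is the total biosensor concentration in the starting
    mix; it enters the ligand-depletion isotherm.
    """

    points: list[TitrationPoint]
    initial_volume: float        # µL
    biosensor_total: float       # µM
    titrant_name: str = "CaM"
    temperature: float = 22.0    # °C, metadata

    def __post_init__(self):
        _check_points(self.points)
        if self.initial_volume <= 0:
            raise ConfigurationError("initial_volume must be > 0")
        if self.biosensor_total <= 0:
            raise ConfigurationError("biosensor_total must be > 0")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    @property
    def cumulative_added(self) -> np.ndarray:
        """Cumulative added volume (µL) at each point."""
        return np.cumsum([p.added_volume for p in self.points])


@dataclass
class ResponseSeries:
    """Dilution-corrected titration response ready for isotherm fitting."""

    titrant_total: np.ndarray    # µM, cumulative dilution-corrected totals
    ratio: np.ndarray            # F475/F535 per point
    bs_fract: np.ndarray         # fraction bound per point, in [0, 1]
    channel_used: str            # one of {"ratio", "donor", "acceptor"}
    r_min: float
    r_max: float
    f_donor: Optional[np.ndarray] = None    # dilution-corrected intensities
    f_acceptor: Optional[np.ndarray] = None
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.titrant_total)


@dataclass
class CaAssaySeries:
    """A Ca2+ titration at saturating CaM with a parallel indicator channel.

    Indicator endpoints ``indicator_f_min``/``indicator_f_max`` come from
    calibration records: the nominally Ca2+-free start of the assay and a
    Ca2+-saturating addition at its end.  They are never guessed from data.
    """

    points: list[TitrationPoint]
    initial_volume: float        # µL
    cam_total: float             # µM, saturating, fixed
    indicator_kd: float = 1.6    # µM, X-Rhod5F in vitro Kd for Ca2+
    indicator_f_min: Optional[float] = None
    indicator_f_max: Optional[float] = None
    chelator: str = "Br2BAPTA 0.25 mM"
    temperature: float = 22.0

    def __post_init__(self):
        _check_points(self.points)
        if self.initial_volume <= 0:
            raise ConfigurationError("initial_volume must be > 0")
        if any(p.f_indicator is None for p in self.points):
            raise ConfigurationError(
                "CaAssaySeries requires an indicator (F600) reading at every point"
            )
        if (
            self.indicator_f_min is not None
            and self.indicator_f_max is not None
            and self.indicator_f_max <= self.indicator_f_min
        ):
            raise ConfigurationError("indicator_f_max must exceed indicator_f_min")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def ratios(self) -> np.ndarray:
        return np.array([p.ratio for p in self.points])

    @property
    def f_indicator(self) -> np.ndarray:
        return np.array([p.f_indicator for p in self.points])
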