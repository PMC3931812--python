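"""Reading and writing titration tables, spectra, and analysis reports.

Titration tables are delimited text (comma or tab) with a header row and
columns ``step, added_volume_uL, stock_conc_uM, F475, F535`` plus an optional
``F600`` indicator column.  A fully populated F600 column makes the file a
Ca2+ assay; a missing or blank column makes it a CaM titration.  Spectra are
two-column ``wavelength_nm, intensity_au`` files, one per titration step.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import BindingResult
from .calcium import CaSensitivityResult, HillFit
from .errors import ConfigurationError
from .series import CaAssaySeries, TitrationPoint, TitrationSeries

REQUIRED_COLUMNS = ("step", "added_volume_uL", "stock_conc_uM", "F475", "F535")


def read_titration_table(path, initial_volume: float,
                         biosensor_total: Optional[float] = None,
                         cam_total: Optional[float] = None,
                         dialect: Optional[str] = None,
                         **series_kwargs) -> Union[TitrationSeries, CaAssaySeries]:
    """Parse a titration table into a typed series.

    The presence of a fully populated ``F600`` column selects
    :class:`CaAssaySeries` (requires ``cam_total``); otherwise a
    :class:`TitrationSeries` is returned (requires ``biosensor_total``).
    ``dialect`` forces "comma" or "tab"; by default the delimiter is sniffed.
    """
    sep = {"comma": ",", "tab": "\t", None: None}.get(dialect, dialect)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ConfigurationError(f"{path}: missing required column {col!r}")

    def numeric(col):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ConfigurationError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, row {row}"
            )
        return vals

    step = numeric("step").astype(int)
    vol = numeric("added_volume_uL")
    stock = numeric("stock_conc_uM")
    f475 = numeric("F475")
    f535 = numeric("F535")
    f600 = numeric("F600") if "F600" in df.columns else None
    has_indicator = f600 is not None and not f600.isna().any() and len(df) > 0

    points = [
        TitrationPoint(
            step_index=int(step.iloc[i]), added_volume=float(vol.iloc[i]),
            stock_concentration=float(stock.iloc[i]),
            f_donor=float(f475.iloc[i]), f_acceptor=float(f535.iloc[i]),
            f_indicator=float(f600.iloc[i]) if has_indicator else None,
        )
        for i in range(len(df))
    ]
    if has_indicator:
        if cam_total is None:
            raise ConfigurationError(
                "table carries an F600 indicator column; cam_total is required"
            )
        return CaAssaySeries(points=points, initial_volume=initial_volume,
                             cam_total=cam_total, **series_kwargs)
    if biosensor_total is None:
        raise ConfigurationError(
            "CaM titration table requires biosensor_total"
        )
    return TitrationSeries(points=points, initial_volume=initial_volume,
                           biosensor_total=biosensor_total, **series_kwargs)


def write_titration_table(series: Union[TitrationSeries, CaAssaySeries],
                          path, dialect: str = "comma") -> None:
    """Write a series back to delimited text (inverse of the reader)."""
    sep = {"comma": ",", "tab": "\t"}[dialect]
    rows = {
        "step": [p.step_index for p in series.points],
        "added_volume_uL": [p.added_volume for p in series.points],
        "stock_conc_uM": [p.stock_concentration for p in series.points],
        "F475": [p.f_donor for p in series.points],
        "F535": [p.f_acceptor for p in series.points],
    }
    if any(p.f_indicator is not None for p in series.points):
        rows["F600"] = [p.f_indicator for p in series.points]
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_spectrum(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column wavelength/intensity spectrum file."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: spectrum needs two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_spectrum(wavelengths, intensities, path) -> None:
    pd.DataFrame({"wavelength_nm": wavelengths,
                  "intensity_au": intensities}).to_csv(path, index=False)


# -- structured reports ------------------------------------------------------

def _clean(obj):
    """Recursively convert numpy scalars/arrays to plain JSON-able types."""
    if isinstance(obj, dict):
        return {k: _clean(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_clean(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def _hill_dict(h: Optional[HillFit]):
    return None if h is None else _clean(asdict(h))


def binding_result_to_dict(r: BindingResult) -> dict:
    d = asdict(r)
    return _clean(d)


def ca_result_to_dict(r: CaSensitivityResult) -> dict:
    return _clean({
        "species1": _hill_dict(r.species1),
        "species2_or_global": _hill_dict(r.species2_or_global),
        "biphasic": r.biphasic,
        "breakpoint": r.breakpoint,
        "f_pvalue": r.f_pvalue,
        "free_ca": r.free_ca,
        "bs_fract": r.bs_fract,
        "warnings": list(r.warnings),
    })


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_clean(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class AnalysisReport:
    """Structured, serializable record of one pipeline run."""

    construct: str
    command: str
    results: dict
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return _clean({
            "construct": self.construct,
            "command": self.command,
            "results": self.results,
            "provenance": self.provenance,
            "warnings": self.warnings,
        })

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(construct=d["construct"], command=d["command"],
                   results=d["results"], provenance=d.get("provenance", {}),
                   warnings=list(d.get("warnings", [])))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "AnalysisReport":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def __eq__(self, other):
        return isinstance(other, AnalysisReport) and self.to_dict() == other.to_dict()


def make_provenance(inputs: list[str], config: dict, seed: Optional[int]) -> dict:
    return {
        "inputs": [str(p) for p in inputs],
        "config_hash": config_hash(config),
        "seed": seed,
        "package_version": __version__,
    }
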