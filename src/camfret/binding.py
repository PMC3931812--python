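"""Apparent-K_d estimation for biosensor–CaM titrations.

Two single-site isotherms are supported.  When total biosensor [BS] is
negligible next to K_d, bound fraction follows the hyperbola

    f([CaM]) = [CaM] / (K_d + [CaM]),

otherwise ligand depletion matters and the exact mass-action (quadratic) root
is used:

    f = ((K_d + [BS] + [CaM]) - sqrt((K_d + [BS] + [CaM])^2 - 4·[BS]·[CaM]))
        / (2·[BS]),

with [CaM] the *total* titrated concentration.  Fitting happens in measured
ratio space by default, with the endpoint ratios free parameters, because the
final titration point need not be saturating.

The entry points are :class:`BindingModel` (construct from arrays or a
:class:`~camfret.series.ResponseSeries`) whose :meth:`~BindingModel.fit`
returns a :class:`BindingResult`, and the convenience function
:func:`fit_binding`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .errors import FitFailureError, ParameterError
from .response import dynamic_range
from .series import ResponseSeries

#: Observed fold response below which a titration is declared non-binding.
NO_BINDING_DR = 1.02

#: Depletion regime: quadratic model is kept when fitted K_d < this × [BS].
DEPLETION_KD_FACTOR = 10.0

#: Multi-start K_d seeds (µM); the ~300-fold K_d span across constructs
#: defeats single-start optimizers.
KD_SEEDS = tuple(np.geomspace(0.01, 1000.0, 7))

_LOG_KD_BOUNDS = (-4.0, 4.0)  # log10 µM


def predict_hyperbolic(cam, kd: float):
    """Bound fraction under the non-depleting hyperbolic isotherm."""
    if kd <= 0:
        raise ParameterError("kd must be > 0")
    cam = np.asarray(cam, dtype=float)
    out = cam / (kd + cam)
    return float(out) if out.ndim == 0 else out


def predict_quadratic(cam_total, bs_total: float, kd: float):
    """Bound fraction under single-site mass action with ligand depletion.

    Returns the physical (smaller) root; reduces to the hyperbola when
    ``bs_total`` is negligible next to ``kd``.
    """
    if kd <= 0:
        raise ParameterError("kd must be > 0")
    if bs_total <= 0:
        raise ParameterError("bs_total must be > 0")
    cam_total = np.asarray(cam_total, dtype=float)
    s = kd + bs_total + cam_total
    disc = s * s - 4.0 * bs_total * cam_total
    # disc >= (kd + |bs - cam|)^2 > 0 analytically; clip rounding residue only
    disc = np.clip(disc, 0.0, None)
    out = (s - np.sqrt(disc)) / (2.0 * bs_total)
    return float(out) if out.ndim == 0 else out


def saturating_concentration(kd: float, bs_total: float = 0.0,
                             coverage: float = 0.95,
                             model: str = "hyperbolic") -> float:
    """Smallest total titrant concentration achieving ``coverage`` bound fraction.

    Hyperbolic: ``kd·c/(1-c)``.  Quadratic: add the titrant sequestered in the
    complex, ``kd·c/(1-c) + c·bs_total`` (exact inversion of mass action).
    """
    if not 0 < coverage < 1:
        raise ParameterError("coverage must lie in (0, 1)")
    if kd <= 0:
        raise ParameterError("kd must be > 0")
    free_needed = kd * coverage / (1.0 - coverage)
    if model == "hyperbolic":
        return free_needed
    if model == "quadratic":
        return free_needed + coverage * bs_total
    raise ParameterError(f"unknown model {model!r}")


def fold_difference(kd_a: float, kd_b: float) -> tuple[float, int]:
    """Affinity fold difference ``kd_a / kd_b`` and its nearest integer."""
    if kd_a <= 0 or kd_b <= 0:
        raise ParameterError("kd values must be > 0")
    ratio = kd_a / kd_b
    return ratio, int(round(ratio))


@dataclass
class BindingResult:
    """Result of a biosensor–CaM isotherm fit.

    ``kd_app`` is NaN for a no-binding (flat) titration, with
    ``binding_detected`` False.
    """

    kd_app: float                     # µM
    kd_stderr: float
    r_min_fit: float
    r_max_fit: float
    dynamic_range: float
    model: str                        # "hyperbolic" | "quadratic"
    response_model: str               # "fraction" | "affine_ratio" | "spectral_ratio"
    rss: float
    n_points: int
    converged: bool
    binding_detected: bool = True
    curvature: float = 0.0            # spectral_ratio denominator slope q
    bs_total: float = np.nan
    params: np.ndarray = field(default_factory=lambda: np.array([]))
    bse: np.ndarray = field(default_factory=lambda: np.array([]))
    warnings: list[str] = field(default_factory=list)

    def predict(self, cam_total, scale: str = "auto"):
        """Predicted response at total titrant concentrations.

        ``scale`` is "fraction", "ratio", or "auto" (whatever was fit).
        """
        if self.model == "quadratic":
            f = predict_quadratic(cam_total, self.bs_total, self.kd_app)
        else:
            f = predict_hyperbolic(cam_total, self.kd_app)
        if scale == "fraction" or (scale == "auto" and self.response_model == "fraction"):
            return f
        return _ratio_from_fraction(f, self.r_min_fit, self.r_max_fit,
                                    self.curvature, self.response_model)

    def summary(self) -> str:
        lines = [
            "Biosensor-CaM binding fit",
            "=" * 41,
            f"isotherm model     : {self.model}",
            f"response model     : {self.response_model}",
            f"n points           : {self.n_points}",
        ]
        if self.binding_detected:
            lines += [
                f"apparent Kd (uM)   : {self.kd_app:.6g} +/- {self.kd_stderr:.3g}",
                f"R_min / R_max      : {self.r_min_fit:.4f} / {self.r_max_fit:.4f}",
                f"dynamic range      : {self.dynamic_range:.4g}",
            ]
        else:
            lines += ["no binding detected (flat response)"]
        lines += [
            f"RSS                : {self.rss:.6g}",
            f"converged          : {self.converged}",
        ]
        for w in self.warnings:
            lines.append(f"note: {w}")
        return "\n".join(lines)


def _ratio_from_fraction(f, r_min, r_max, q, response_model):
    if response_model == "spectral_ratio":
        p = r_max * (1.0 - q) - r_min
        return (r_min + p * f) / (1.0 - q * f)
    return r_min + (r_max - r_min) * f


class BindingModel:
    """Isotherm model for a CaM titration, statsmodels style.

    Parameters
    ----------
    cam_total : array
        Dilution-corrected cumulative titrant totals (µM).
    response : array
        Measured response per point: the F475/F535 ratio for the ratio-space
        response models, or pre-normalized bound fractions for
        ``response_model="fraction"``.
    bs_total : float
        Total biosensor concentration (µM), used by the depletion isotherm.
    response_model : str
        "affine_ratio" (default; R affine in bound fraction with free
        endpoints), "spectral_ratio" (Möbius ratio of two affine emission
        channels, extra curvature parameter), or "fraction".
    """

    def __init__(self, cam_total, response, bs_total: float,
                 response_model: str = "affine_ratio"):
        self.cam_total = np.asarray(cam_total, dtype=float)
        self.response = np.asarray(response, dtype=float)
        if self.cam_total.shape != self.response.shape:
            raise ParameterError("cam_total and response must have equal length")
        if len(self.cam_total) < 4:
            raise ParameterError("at least 4 titration points are required")
        if bs_total <= 0:
            raise ParameterError("bs_total must be > 0")
        if response_model not in ("fraction", "affine_ratio", "spectral_ratio"):
            raise ParameterError(f"unknown response_model {response_model!r}")
        self.bs_total = bs_total
        self.response_model = response_model

    @classmethod
    def from_series(cls, response: ResponseSeries, bs_total: float,
                    response_model: str = "affine_ratio") -> "BindingModel":
        y = response.bs_fract if response_model == "fraction" else response.ratio
        return cls(response.titrant_total, y, bs_total, response_model)

    # -- internals ---------------------------------------------------------

    def _fraction(self, log10_kd: float, model: str):
        kd = 10.0 ** log10_kd
        if model == "quadratic":
            return predict_quadratic(self.cam_total, self.bs_total, kd)
        return predict_hyperbolic(self.cam_total, kd)

    def _residuals(self, theta, model: str):
        if self.response_model == "fraction":
            f = self._fraction(theta[0], model)
            return f - self.response
        if self.response_model == "affine_ratio":
            r_min, r_max, lkd = theta
            f = self._fraction(lkd, model)
            return r_min + (r_max - r_min) * f - self.response
        r_min, r_max, q, lkd = theta
        f = self._fraction(lkd, model)
        p = r_max * (1.0 - q) - r_min
        return (r_min + p * f) / (1.0 - q * f) - self.response

    def _starts(self):
        y0, y1 = float(self.response[0]), float(self.response[-1])
        seeds = list(KD_SEEDS)
        # data-driven seed: titrant concentration at half response
        half = 0.5 * (y0 + y1)
        idx = int(np.argmin(np.abs(self.response - half)))
        c_half = self.cam_total[idx]
        if c_half > 0:
            seeds.insert(0, float(c_half))
        for kd0 in seeds:
            lkd0 = float(np.clip(np.log10(kd0), *_LOG_KD_BOUNDS))
            if self.response_model == "fraction":
                yield np.array([lkd0])
            elif self.response_model == "affine_ratio":
                yield np.array([y0, y1, lkd0])
            else:
                yield np.array([y0, y1, 0.3, lkd0])

    def _bounds(self):
        lo_k, hi_k = _LOG_KD_BOUNDS
        if self.response_model == "fraction":
            return ([lo_k], [hi_k])
        if self.response_model == "affine_ratio":
            return ([1e-9, 1e-9, lo_k], [np.inf, np.inf, hi_k])
        return ([1e-9, 1e-9, 0.0, lo_k], [np.inf, np.inf, 0.95, hi_k])

    def _fit_one_model(self, model: str):
        best = None
        diagnostics = []
        for x0 in self._starts():
            try:
                sol = least_squares(self._residuals, x0, args=(model,),
                                    bounds=self._bounds(), xtol=1e-14,
                                    ftol=1e-14, gtol=1e-14, max_nfev=2000)
            except Exception as exc:  # pragma: no cover - optimizer edge
                diagnostics.append(f"start {x0}: {exc}")
                continue
            if not sol.success:
                diagnostics.append(f"start {x0}: {sol.message}")
                continue
            rss = float(2.0 * sol.cost)
            kd = 10.0 ** sol.x[-1]
            if best is None or rss < best[0] - 1e-12 or (
                abs(rss - best[0]) < 1e-12 and kd < best[1]
            ):
                best = (rss, kd, sol)
        if best is None:
            raise FitFailureError(
                f"no optimizer start converged for model={model}", diagnostics
            )
        return best

    # -- public ------------------------------------------------------------

    def fit(self, model: str = "auto") -> BindingResult:
        """Least-squares fit; ``model`` is "auto", "hyperbolic" or "quadratic".

        "auto" keeps the quadratic (depletion) fit when its K_d estimate falls
        below 10 × [BS], otherwise reports the hyperbolic fit, and records the
        choice.
        """
        notes: list[str] = []
        if self.response_model != "fraction":
            r = self.response
            lo, hi = float(r.min()), float(r.max())
            if lo <= 0 or hi / lo < NO_BINDING_DR:
                return BindingResult(
                    kd_app=np.nan, kd_stderr=np.nan, r_min_fit=lo, r_max_fit=hi,
                    dynamic_range=hi / lo if lo > 0 else np.nan,
                    model="none", response_model=self.response_model,
                    rss=float(np.sum((r - r.mean()) ** 2)),
                    n_points=len(r), converged=True, binding_detected=False,
                    bs_total=self.bs_total,
                    warnings=[f"flat response (fold {hi / lo:.4g} < {NO_BINDING_DR}); "
                              "no binding detected"],
                )

        if model == "auto":
            rss, kd, sol = self._fit_one_model("quadratic")
            if kd < DEPLETION_KD_FACTOR * self.bs_total:
                chosen = "quadratic"
                notes.append(
                    f"auto-selected quadratic model (Kd {kd:.3g} µM < "
                    f"{DEPLETION_KD_FACTOR:g} × [BS] {self.bs_total:g} µM)"
                )
            else:
                chosen = "hyperbolic"
                rss, kd, sol = self._fit_one_model("hyperbolic")
                notes.append(
                    f"auto-selected hyperbolic model (depletion negligible at "
                    f"Kd {kd:.3g} µM, [BS] {self.bs_total:g} µM)"
                )
        elif model in ("hyperbolic", "quadratic"):
            chosen = model
            rss, kd, sol = self._fit_one_model(model)
        else:
            raise ParameterError(f"unknown model {model!r}")

        return self._build_result(chosen, rss, kd, sol, notes)

    def _build_result(self, model, rss, kd, sol, notes):
        n, p = len(self.response), len(sol.x)
        bse = np.full(p, np.nan)
        if n > p:
            s2 = rss / (n - p)
            try:
                jtj = sol.jac.T @ sol.jac
                cov = np.linalg.inv(jtj) * s2
                bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            except np.linalg.LinAlgError:
                notes = notes + ["singular Jacobian; standard errors unavailable"]
        kd_stderr = kd * np.log(10.0) * bse[-1]

        if self.response_model == "fraction":
            r_min_f, r_max_f, q = 0.0, 1.0, 0.0
        elif self.response_model == "affine_ratio":
            r_min_f, r_max_f = float(sol.x[0]), float(sol.x[1])
            q = 0.0
        else:
            r_min_f, r_max_f, q = float(sol.x[0]), float(sol.x[1]), float(sol.x[2])
        if r_min_f > r_max_f:
            r_min_f, r_max_f = r_max_f, r_min_f
            notes = notes + ["fitted endpoints inverted; swapped"]
        dr = dynamic_range(r_min_f, r_max_f) if r_min_f > 0 else np.nan

        return BindingResult(
            kd_app=kd, kd_stderr=float(kd_stderr), r_min_fit=r_min_f,
            r_max_fit=r_max_f, dynamic_range=dr, model=model,
            response_model=self.response_model, rss=rss, n_points=n,
            converged=True, binding_detected=True, curvature=q,
            bs_total=self.bs_total, params=sol.x.copy(), bse=bse,
            warnings=notes,
        )


def fit_binding(response: ResponseSeries, bs_total: float,
                model: str = "auto",
                response_model: str = "affine_ratio") -> BindingResult:
    """Fit an apparent K_d to a dilution-corrected titration response."""
    return BindingModel.from_series(response, bs_total, response_model).fit(model)
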