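"""Concentration–intensity psychophysics for single odorants.

Perceived intensity of an odorant grows sigmoidally with the logarithm of its
gas-phase concentration.  The central model is the three-parameter Hill
equation

    I(C) = Imax * C**n / (C**n + EC50**n)

where ``Imax`` is the maximum perceivable intensity (gLMS units), ``EC50`` the
concentration at the curve's inflection point and ``n`` the slope of the
transition.  Three classical alternatives — Stevens' power law, Beidler's
function (the Hill curve with n fixed at 1) and Fechner's logarithmic law —
are fitted alongside it so their goodness of fit can be compared per odorant.

Fitting is performed in (log10 concentration, intensity) space with bounded
nonlinear least squares and a small multi-start, which keeps the optimiser
away from the divergent flat/saturated regimes the raw parametrisation allows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InsufficientDataError

__all__ = [
    "HillParams",
    "RatingPoint",
    "CurveFit",
    "FAMILIES",
    "hill_intensity",
    "family_intensity",
    "fit_curve",
    "compare_families",
]

#: Canonical family order, also the final tie-break in ranking.
FAMILIES: tuple[str, ...] = ("hill", "beidler", "stevens", "fechner")

_N_FREE = {"hill": 3, "beidler": 2, "stevens": 2, "fechner": 2}


@dataclass(frozen=True)
class HillParams:
    """Parameters of a fitted Hill concentration–intensity curve."""

    imax: float
    ec50: float
    n: float

    def __post_init__(self) -> None:
        for name in ("imax", "ec50", "n"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"HillParams.{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class RatingPoint:
    """One panel-mean intensity observation of one stimulus.

    ``concentration`` is on a linear gas-phase scale; units are treated as
    opaque but must be consistent within a dataset.  ``intensity`` is in gLMS
    units and nonnegative.
    """

    odorant_id: str
    concentration: float
    intensity: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"concentration must be finite and > 0, got {self.concentration!r}")
        if not (np.isfinite(self.intensity) and self.intensity >= 0):
            raise ValueError(f"intensity must be finite and >= 0, got {self.intensity!r}")


@dataclass(frozen=True)
class CurveFit:
    """Result of fitting one curve family to one odorant's ratings."""

    odorant_id: str
    family: str
    params: object  # HillParams for family="hill", a plain dict otherwise
    rmse: float
    n_points: int
    converged: bool

    @property
    def hill(self) -> HillParams:
        if self.family != "hill":
            raise AttributeError(f"fit family is {self.family!r}, not 'hill'")
        return self.params  # type: ignore[return-value]


def hill_intensity(params: HillParams, concentration):
    """Evaluate the Hill curve at one or many concentrations.

    Accepts a scalar or array; concentration 0 returns 0 (the curve's limit).
    Evaluation is carried out in log space to stay finite at extreme C/EC50
    ratios.
    """
    c = np.asarray(concentration, dtype=float)
    if not np.all(np.isfinite(c)) or np.any(c < 0):
        raise ValueError("concentration must be finite and >= 0")
    # I = Imax / (1 + (EC50/C)^n), stable as exp/log
    with np.errstate(divide="ignore"):
        log_ratio = np.log(params.ec50) - np.log(c)  # +inf at c == 0
    out = params.imax / (1.0 + np.exp(np.clip(params.n * log_ratio, -700, 700)))
    out = np.where(c == 0, 0.0, out)
    return float(out) if np.isscalar(concentration) or out.ndim == 0 else out


def _beidler(params: Mapping[str, float], c):
    return hill_intensity(HillParams(params["imax"], params["k"], 1.0), c)


def _stevens(params: Mapping[str, float], c):
    c = np.asarray(c, dtype=float)
    out = params["k"] * np.power(c, params["exponent"], where=c > 0, out=np.zeros_like(c))
    return float(out) if out.ndim == 0 else out


def _fechner(params: Mapping[str, float], c):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        out = params["k"] * np.log(np.where(c > 0, c, np.nan) / params["c0"])
    out = np.where((c <= params["c0"]) | ~np.isfinite(out), 0.0, out)
    return float(out) if out.ndim == 0 else out


def family_intensity(family: str, params, concentration):
    """Evaluate any supported curve family at ``concentration``.

    ``fechner`` is clamped to 0 at and below its threshold concentration C0.
    """
    if family == "hill":
        p = params if isinstance(params, HillParams) else HillParams(**params)
        return hill_intensity(p, concentration)
    if family == "beidler":
        return _beidler(params, concentration)
    if family == "stevens":
        return _stevens(params, concentration)
    if family == "fechner":
        return _fechner(params, concentration)
    raise ValueError(f"unknown curve family {family!r}")


# ---------------------------------------------------------------------------
# fitting


def _check_points(points: Sequence[RatingPoint], family: str) -> None:
    if family not in _N_FREE:
        raise ValueError(f"unknown curve family {family!r}")
    if len({p.odorant_id for p in points}) > 1:
        raise ValueError("fit_curve expects ratings of a single odorant")
    if len(points) < _N_FREE[family] or len({p.concentration for p in points}) < 2:
        raise InsufficientDataError(
            f"{family} needs >= {_N_FREE[family]} points at >= 2 distinct concentrations, "
            f"got {len(points)}"
        )


def _predict_theta(family: str, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Model prediction from the internal (bounded) parameter vector.

    x is log10 concentration.  Internal parametrisations use log10 for the
    concentration-scale parameters so the bounds are symmetric in decades.
    """
    if family == "hill":
        imax, log_ec50, n = theta
        return imax / (1.0 + np.exp(np.clip(n * np.log(10.0) * (log_ec50 - x), -700, 700)))
    if family == "beidler":
        imax, log_k = theta
        return imax / (1.0 + np.exp(np.clip(np.log(10.0) * (log_k - x), -700, 700)))
    if family == "stevens":
        log_k, b = theta
        return 10.0 ** np.clip(log_k + b * x, -300, 300)
    if family == "fechner":
        k, x0 = theta
        return k * np.log(10.0) * np.maximum(x - x0, 0.0)
    raise ValueError(family)


def _bounds_and_start(family: str, x: np.ndarray, y: np.ndarray):
    ymax = float(np.max(y))
    imax_hi = max(2.0 * ymax, 1e-6)
    lo_x, hi_x = float(np.min(x)), float(np.max(x))
    if family in ("hill", "beidler"):
        # ec50 searched within [min C / 10^3, max C * 10^3]
        half = ymax / 2.0
        x_half = float(x[np.argmin(np.abs(y - half))])
        start = [max(ymax, 1e-8), x_half] + ([1.0] if family == "hill" else [])
        lo = [1e-9, lo_x - 3.0] + ([0.1] if family == "hill" else [])
        hi = [imax_hi, hi_x + 3.0] + ([10.0] if family == "hill" else [])
        return (np.array(lo), np.array(hi)), np.array(start)
    if family == "stevens":
        pos = y > 0
        if pos.sum() >= 2 and len(np.unique(x[pos])) >= 2:
            b, logk = np.polyfit(x[pos], np.log10(y[pos]), 1)
        else:
            b, logk = 1.0, (np.log10(ymax) - hi_x if ymax > 0 else 0.0)
        lo = np.array([-30.0, 0.01])
        hi = np.array([30.0, 10.0])
        start = np.clip(np.array([logk, b]), lo + 1e-9, hi - 1e-9)
        return (lo, hi), start
    if family == "fechner":
        slope = (y[-1] - y[0]) / (x[-1] - x[0] + 1e-12)
        k0 = max(abs(slope) / np.log(10.0), 1e-6)
        start = np.array([k0, lo_x - 1.0])
        lo = np.array([1e-9, lo_x - 10.0])
        hi = np.array([1e9, hi_x + 10.0])
        return (lo, hi), np.clip(start, lo + 1e-12, hi - 1e-12)
    raise ValueError(family)


def _theta_to_params(family: str, theta: np.ndarray):
    if family == "hill":
        return HillParams(imax=float(theta[0]), ec50=float(10.0 ** theta[1]), n=float(theta[2]))
    if family == "beidler":
        return {"imax": float(theta[0]), "k": float(10.0 ** theta[1])}
    if family == "stevens":
        return {"k": float(10.0 ** theta[0]), "exponent": float(theta[1])}
    if family == "fechner":
        return {"k": float(theta[0]), "c0": float(10.0 ** theta[1])}
    raise ValueError(family)


def fit_curve(
    points: Sequence[RatingPoint],
    family: str = "hill",
    *,
    n_restarts: int = 5,
    seed: int = 0,
) -> CurveFit:
    """Least-squares fit of one curve family to one odorant's ratings.

    The fit minimises squared intensity residuals against log10 concentration.
    Multi-start (``n_restarts`` jittered initialisations, deterministic under
    ``seed``) guards against the multimodality of sigmoid fits.  Optimiser
    failure is reported via ``converged=False`` with best-effort parameters,
    never as an exception.
    """
    _check_points(points, family)
    pts = sorted(points, key=lambda p: p.concentration)
    x = np.log10(np.array([p.concentration for p in pts]))
    y = np.array([p.intensity for p in pts])
    (lo, hi), start = _bounds_and_start(family, x, y)

    rng = np.random.default_rng(seed)
    starts = [start]
    for _ in range(max(n_restarts - 1, 0)):
        jitter = start + rng.normal(scale=0.25 * (hi - lo).clip(max=4.0), size=start.shape)
        starts.append(np.clip(jitter, lo + 1e-12, hi - 1e-12))

    best_theta, best_cost, converged = start, np.inf, False
    for s in starts:
        try:
            res = least_squares(
                lambda th: _predict_theta(family, th, x) - y,
                s, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if res.cost < best_cost:
            best_theta, best_cost, converged = res.x, res.cost, bool(res.success)

    resid = _predict_theta(family, best_theta, x) - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    return CurveFit(
        odorant_id=pts[0].odorant_id,
        family=family,
        params=_theta_to_params(family, best_theta),
        rmse=rmse,
        n_points=len(pts),
        converged=converged and math.isfinite(rmse),
    )


def compare_families(
    points: Sequence[RatingPoint],
    families: Sequence[str] = FAMILIES,
    *,
    rmse_tol: float = 1e-6,
    seed: int = 0,
) -> list[CurveFit]:
    """Fit every family and rank ascending by RMSE.

    RMSE ties (within ``rmse_tol``) are broken by fewer free parameters, then
    by the fixed family order, so a nested pair such as hill/beidler ranks the
    simpler family first when the extra parameter buys nothing.
    """
    fits = [fit_curve(points, fam, seed=seed) for fam in families]
    fits.sort(key=lambda f: f.rmse)
    # regroup near-ties and apply the secondary keys inside each group
    ranked: list[CurveFit] = []
    i = 0
    while i < len(fits):
        j = i + 1
        while j < len(fits) and fits[j].rmse - fits[i].rmse <= rmse_tol:
            j += 1
        group = sorted(fits[i:j], key=lambda f: (_N_FREE[f.family], FAMILIES.index(f.family)))
        ranked.extend(group)
        i = j
    return ranked
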