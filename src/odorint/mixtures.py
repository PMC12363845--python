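"""Analytic models of odor-mixture intensity.

Seven models predict the perceived intensity of a mixture from the
stand-alone intensities (and, for the biophysical pair, the fitted Hill
curves) of its components:

========  ==================================================================
ADD       linear addition, sum of component intensities
SC        strongest component, the max
EUC       Euclidean addition, sqrt of the sum of squares
VEC       Euclidean addition plus pairwise cosine interaction terms
U         VEC generalised to all k-subsets (geometric-mean interaction term)
CB        competitive binding: components compete for one receptor pool
PRI       primacy coding: LogSumExp of component intensities evaluated at a
          fraction (default 20%) of each ambient concentration
========  ==================================================================

With the published universal cosine of −0.3, VEC's radicand goes negative for
large mixtures ("imaginary intensity"); such predictions are reported with
``valid=False`` rather than raised, so batch evaluation never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import MissingParameterError, UnsupportedSizeError
from .psychophysics import HillParams, hill_intensity

__all__ = [
    "ComponentState",
    "MixtureSpec",
    "MixtureModelConfig",
    "MixturePrediction",
    "MODELS",
    "predict_add",
    "predict_sc",
    "predict_euc",
    "predict_vec",
    "predict_u",
    "predict_cb",
    "predict_pri",
    "predict_all",
]

#: Fixed model order used by predict_all and the long-format output tables.
MODELS: tuple[str, ...] = ("ADD", "SC", "EUC", "VEC", "U", "CB", "PRI")

#: Largest mixture the U model will enumerate (2^n subset terms).
MAX_U_COMPONENTS = 12


@dataclass(frozen=True)
class ComponentState:
    """One mixture component.

    ``intensity_alone`` is the perceived intensity of the component presented
    by itself at ``concentration`` (the ambient, in-mixture concentration).
    ``hill`` is required by the CB and PRI models only.
    """

    odorant_id: str
    concentration: float = 0.0
    intensity_alone: float = 0.0
    hill: HillParams | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.concentration) and self.concentration >= 0):
            raise ValueError(f"concentration must be finite and >= 0, got {self.concentration!r}")
        if not (np.isfinite(self.intensity_alone) and self.intensity_alone >= 0):
            raise ValueError(
                f"intensity_alone must be finite and >= 0, got {self.intensity_alone!r}"
            )


@dataclass(frozen=True)
class MixtureSpec:
    """An ordered, duplicate-free list of components."""

    mixture_id: str
    components: tuple[ComponentState, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValueError("mixture needs at least one component")
        ids = [c.odorant_id for c in self.components]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate component ids in mixture {self.mixture_id!r}")

    def without(self, odorant_id: str) -> "MixtureSpec":
        """The (n-1)-component sub-mixture lacking ``odorant_id``."""
        kept = tuple(c for c in self.components if c.odorant_id != odorant_id)
        if len(kept) == len(self.components):
            raise KeyError(f"{odorant_id!r} not in mixture {self.mixture_id!r}")
        return replace(self, mixture_id=f"{self.mixture_id}-{odorant_id}", components=kept)

    def intensities(self) -> np.ndarray:
        return np.array([c.intensity_alone for c in self.components], dtype=float)


@dataclass(frozen=True)
class MixtureModelConfig:
    """Shared model constants.

    cos_alpha      pairwise/subset interaction cosine (universal value −0.3)
    fmax           CB global maximum intensity scale (published value 1)
    alpha_fraction PRI's early-sniff concentration fraction (0.2 = 20%)
    """

    cos_alpha: float = -0.3
    fmax: float = 1.0
    alpha_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not -1.0 <= self.cos_alpha <= 1.0:
            raise ValueError("cos_alpha must lie in [-1, 1]")
        if self.fmax <= 0:
            raise ValueError("fmax must be > 0")
        if not 0.0 < self.alpha_fraction <= 1.0:
            raise ValueError("alpha_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class MixturePrediction:
    mixture_id: str
    model: str
    value: float
    valid: bool = True
    reason: str = ""


def _pred(mix: MixtureSpec, model: str, value: float) -> MixturePrediction:
    return MixturePrediction(mix.mixture_id, model, float(value), True)


def _invalid(mix: MixtureSpec, model: str, reason: str) -> MixturePrediction:
    return MixturePrediction(mix.mixture_id, model, float("nan"), False, reason)


def predict_add(mix: MixtureSpec) -> MixturePrediction:
    """Linear addition: Imix = sum of component intensities."""
    return _pred(mix, "ADD", mix.intensities().sum())


def predict_sc(mix: MixtureSpec) -> MixturePrediction:
    """Strongest component: Imix = max component intensity."""
    return _pred(mix, "SC", mix.intensities().max())


def predict_euc(mix: MixtureSpec) -> MixturePrediction:
    """Euclidean addition: Imix = sqrt(sum of squared intensities)."""
    return _pred(mix, "EUC", np.sqrt(np.sum(mix.intensities() ** 2)))


def predict_vec(mix: MixtureSpec, cfg: MixtureModelConfig = MixtureModelConfig()) -> MixturePrediction:
    """Vector model: EUC plus pairwise 2*Ii*Ij*cos_alpha interaction terms.

    A negative radicand (undefined, "imaginary" intensity) is reported as
    ``valid=False``.
    """
    ivec = mix.intensities()
    pair_sum = (ivec.sum() ** 2 - np.sum(ivec**2)) / 2.0  # sum_{i<j} Ii*Ij
    radicand = np.sum(ivec**2) + 2.0 * cfg.cos_alpha * pair_sum
    if radicand < 0:
        return _invalid(mix, "VEC", f"negative radicand {radicand:.6g}")
    return _pred(mix, "VEC", np.sqrt(radicand))


def predict_u(mix: MixtureSpec, cfg: MixtureModelConfig = MixtureModelConfig()) -> MixturePrediction:
    """U model: interaction terms over every k-subset, k = 2..n.

    Each subset of k components contributes 2*cos_alpha*(prod Ii)**(1/k) — a
    geometric-mean-like term — inside the square root.  Enumeration is
    exhaustive, so mixtures beyond MAX_U_COMPONENTS are refused.
    """
    ivec = mix.intensities()
    n = len(ivec)
    if n > MAX_U_COMPONENTS:
        raise UnsupportedSizeError(
            f"U model enumerates all subsets; {n} components > {MAX_U_COMPONENTS}"
        )
    radicand = float(np.sum(ivec**2))
    if cfg.cos_alpha != 0.0:
        for k in range(2, n + 1):
            for subset in combinations(ivec, k):
                radicand += 2.0 * cfg.cos_alpha * float(np.prod(subset)) ** (1.0 / k)
    if radicand < 0:
        return _invalid(mix, "U", f"negative radicand {radicand:.6g}")
    return _pred(mix, "U", np.sqrt(radicand))


def _require_hill(mix: MixtureSpec, model: str) -> None:
    missing = [c.odorant_id for c in mix.components if c.hill is None]
    if missing:
        raise MissingParameterError(f"{model} needs Hill params; missing for {missing}")


def predict_cb(mix: MixtureSpec, cfg: MixtureModelConfig = MixtureModelConfig()) -> MixturePrediction:
    """Competitive binding: components compete for a single receptor pool.

    Imix = Fmax * sum(ai * Ci/EC50i) / (1 + sum(Ci/EC50i)) with ai the
    component's fitted Imax (baseline intensity taken as 0).
    """
    _require_hill(mix, "CB")
    ratio = np.array([c.concentration / c.hill.ec50 for c in mix.components])
    a = np.array([c.hill.imax for c in mix.components])
    return _pred(mix, "CB", cfg.fmax * float(np.sum(a * ratio)) / (1.0 + float(np.sum(ratio))))


def predict_pri(mix: MixtureSpec, cfg: MixtureModelConfig = MixtureModelConfig()) -> MixturePrediction:
    """Primacy coding: LogSumExp of component intensities at 20% concentration.

    Imix = ln(sum_i exp(Ii(alpha * Ci))).  Zero-concentration components are
    pruned first — an absent component cannot contribute, and exp(0)=1 terms
    would otherwise inflate the sum.
    """
    _require_hill(mix, "PRI")
    active = [c for c in mix.components if c.concentration > 0]
    if not active:
        raise ValueError(f"mixture {mix.mixture_id!r} has no component with concentration > 0")
    early = np.array(
        [hill_intensity(c.hill, cfg.alpha_fraction * c.concentration) for c in active]
    )
    return _pred(mix, "PRI", logsumexp(early))


_MODEL_FNS = {
    "ADD": lambda mix, cfg: predict_add(mix),
    "SC": lambda mix, cfg: predict_sc(mix),
    "EUC": lambda mix, cfg: predict_euc(mix),
    "VEC": predict_vec,
    "U": predict_u,
    "CB": predict_cb,
    "PRI": predict_pri,
}


def predict_all(
    mix: MixtureSpec,
    cfg: MixtureModelConfig = MixtureModelConfig(),
    models: Sequence[str] = MODELS,
) -> list[MixturePrediction]:
    """Evaluate every requested model, capturing per-model failures.

    Always returns one prediction per model in the fixed MODELS order;
    precondition failures (missing Hill params, oversize U enumeration)
    surface as ``valid=False`` records, never as exceptions.
    """
    unknown = set(models) - set(MODELS)
    if unknown:
        raise ValueError(f"unknown model name(s) {sorted(unknown)}; valid: {list(MODELS)}")
    out = []
    for name in MODELS:
        if name not in models:
            continue
        try:
            out.append(_MODEL_FNS[name](mix, cfg))
        except (MissingParameterError, UnsupportedSizeError, ValueError) as exc:
            out.append(_invalid(mix, name, str(exc)))
    return out
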