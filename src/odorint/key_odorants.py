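"""Identifying perceptually dominant components of complex aromas.

Classical aroma screening ranks compounds by odor activity value
(OAV = concentration / detection threshold) and confirms candidates with
omission tests — comparing the full mixture to the mixture lacking one
component.  Because intensity is a nonlinear function of concentration, OAV
can badly misrank components.  This module replaces the heuristic with
model-based scores:

* a *simulated omission score* Imix − Imix−i under any pluggable mixture
  predictor (analytic model or trained network), and
* the *single-molecule approximation*: the predicted stand-alone intensity of
  each component at its in-mixture concentration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mixtures import MixtureSpec
from .psychophysics import hill_intensity

__all__ = [
    "GCRecord",
    "OmissionScore",
    "oav",
    "simulate_omission",
    "single_molecule_scores",
    "rank_key_odorants",
]


@dataclass(frozen=True)
class GCRecord:
    """One GC-quantified compound: concentration and detection threshold."""

    compound_id: str
    concentration: float
    detection_threshold: float
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.concentration) and self.concentration > 0):
            raise ValueError(f"concentration must be finite and > 0, got {self.concentration!r}")
        if not (np.isfinite(self.detection_threshold) and self.detection_threshold > 0):
            raise ValueError(
                f"detection_threshold must be finite and > 0, got {self.detection_threshold!r}"
            )


@dataclass(frozen=True)
class OmissionScore:
    """Predicted intensity drop when one component is removed."""

    mixture_id: str
    omitted_id: str
    full_intensity: float
    reduced_intensity: float
    error: str = ""

    @property
    def score(self) -> float:
        return self.full_intensity - self.reduced_intensity


def oav(record: GCRecord) -> float:
    """Odor activity value: concentration over detection threshold."""
    return record.concentration / record.detection_threshold


def simulate_omission(
    mix: MixtureSpec,
    predictor: Callable[[MixtureSpec], float],
) -> list[OmissionScore]:
    """Score every component by the predicted drop from omitting it.

    ``predictor`` maps any sub-mixture to an intensity — an analytic model
    from :mod:`odorint.mixtures` or a trained network via its mixture input
    encoding.  The full-mixture intensity is computed once; a predictor
    failure on one sub-mixture is recorded on that component's entry and
    does not stop the scan.
    """
    if len(mix.components) < 2:
        raise ValueError("omission needs a mixture of >= 2 components")
    full = float(predictor(mix))
    out = []
    for comp in mix.components:
        try:
            reduced = float(predictor(mix.without(comp.odorant_id)))
            out.append(OmissionScore(mix.mixture_id, comp.odorant_id, full, reduced))
        except Exception as exc:  # per-component failure, others still scored
            out.append(
                OmissionScore(mix.mixture_id, comp.odorant_id, full, float("nan"), str(exc))
            )
    return out


def single_molecule_scores(
    mix: MixtureSpec,
    predictor: Callable[[str, float], float] | None = None,
) -> list[tuple[str, float]]:
    """Stand-alone intensity of each component at its in-mixture concentration.

    The default predictor evaluates each component's Hill curve; any callable
    ``(odorant_id, concentration) -> intensity`` (e.g. the single-molecule
    network) can be substituted.  Under a purely additive mixture model this
    ranking coincides with the simulated omission ranking.
    """
    if len(mix.components) == 0:
        raise ValueError("empty mixture")
    out = []
    for comp in mix.components:
        if predictor is not None:
            val = float(predictor(comp.odorant_id, comp.concentration))
        elif comp.hill is not None:
            val = float(hill_intensity(comp.hill, comp.concentration))
        else:
            val = float(comp.intensity_alone)
        out.append((comp.odorant_id, val))
    return out


def rank_key_odorants(
    scores: Sequence[OmissionScore] | Sequence[tuple[str, float]],
    top_k: int | None = None,
    threshold: float | None = None,
    gc_records: Sequence[GCRecord] | None = None,
) -> pd.DataFrame:
    """Rank components descending by score; ties broken by compound id.

    Returns a table with columns (compound_id, score, rank) plus, when GC
    records are supplied, an ``oav`` column for side-by-side comparison with
    the classical heuristic.  ``top_k`` or ``threshold`` restrict the report.
    """
    if len(scores) == 0:
        raise ValueError("no scores to rank")
    if isinstance(scores[0], OmissionScore):
        rows = [(s.omitted_id, s.score) for s in scores]
    else:
        rows = [(cid, float(v)) for cid, v in scores]
    df = pd.DataFrame(rows, columns=["compound_id", "score"])
    df = df.sort_values(["score", "compound_id"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    if gc_records is not None:
        oav_map = {r.compound_id: oav(r) for r in gc_records}
        df["oav"] = df["compound_id"].map(oav_map)
    if threshold is not None:
        df = df[df["score"] >= threshold]
    if top_k is not None:
        df = df.head(top_k)
    return df.reset_index(drop=True)
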