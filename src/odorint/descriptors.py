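"""Physicochemical descriptor preprocessing and feature selection.

Descriptor values (e.g. a Dragon-style catalogue plus experimental transport
properties) arrive as an input table; nothing here computes them from
structure.  The pipeline is:

1. drop uninformative columns (no variance, mostly zeros, any missing value),
2. log10-transform strictly positive columns,
3. keep, per Hill parameter (Imax, log10 EC50, n), the k descriptors most
   correlated with it across molecules, plus a forced set of transport
   features (MW, MLOGP, vapor pressure, boiling point) and the geometric
   alpha-area.

A fixed 10-feature simplified set (five transport features plus the five
descriptors most correlated with the Hill parameters in the reference
dataset) is exposed for the interpretable reduced model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, MissingColumnError
from .geometry import MoleculeGeometry, compute_alpha_area  # noqa: F401  (re-export)
from .psychophysics import CurveFit

__all__ = [
    "DescriptorTable",
    "SelectionReport",
    "FORCED_TRANSPORT_FEATURES",
    "SIMPLIFIED_FEATURES",
    "filter_low_information",
    "log_transform_positive",
    "select_by_hill_correlation",
    "simplified_feature_set",
    "compute_alpha_area",
]

#: Transport-related columns always retained by selection when present.
FORCED_TRANSPORT_FEATURES: tuple[str, ...] = ("MW", "MLOGP", "VP", "BP")

#: Geometric column treated like a forced feature.
ALPHA_AREA_FEATURE = "alpha_area"

#: The fixed 10-column interpretable feature set, in output order.
SIMPLIFIED_FEATURES: tuple[str, ...] = (
    "MW", "MLOGP", "VP", "BP", "alpha_area",
    "CATS2D_03_LL", "SpMax8_Bh.p.", "MPC07", "MATS7i", "H2s",
)

HILL_PARAM_NAMES: tuple[str, ...] = ("imax", "log10_ec50", "hill_n")


@dataclass(frozen=True)
class DescriptorTable:
    """Molecule x descriptor matrix with per-column provenance.

    ``values`` is indexed by molecule id; ``provenance`` maps each column to
    one of {"computed", "experimental", "geometric"}; ``log_transformed``
    records which columns have already been log10-transformed so the
    transform is never applied twice.
    """

    values: pd.DataFrame
    provenance: Mapping[str, str] = field(default_factory=dict)
    log_transformed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "log_transformed", frozenset(self.log_transformed))
        prov = dict(self.provenance)
        for col in self.values.columns:
            prov.setdefault(col, "computed")
        object.__setattr__(self, "provenance", prov)

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class SelectionReport:
    """Outcome of correlation-based descriptor selection."""

    retained_names: tuple[str, ...]
    per_name_reason: Mapping[str, str]
    correlation_values: pd.DataFrame  # retained descriptors x Hill params


def filter_low_information(
    table: DescriptorTable,
    *,
    sd_threshold: float = 1e-8,
    zero_fraction: float = 0.5,
) -> DescriptorTable:
    """Drop columns with no variance, mostly-zero entries, or missing values.

    A column survives when its standard deviation is >= ``sd_threshold``,
    strictly fewer than ``zero_fraction`` of its entries are zero, and it has
    no missing values.  Row order is preserved.
    """
    df = table.values
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise EmptyResultError("descriptor table is empty")
    keep = []
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            continue
        if np.std(vals) < sd_threshold:
            continue
        if np.mean(vals == 0.0) > zero_fraction:
            continue
        keep.append(col)
    if not keep:
        raise EmptyResultError("filtering removed every descriptor column")
    return replace(
        table,
        values=df[keep].copy(),
        provenance={c: table.provenance[c] for c in keep},
        log_transformed=table.log_transformed & set(keep),
    )


def log_transform_positive(table: DescriptorTable) -> DescriptorTable:
    """log10-transform every strictly positive column, once.

    Columns containing any value <= 0 pass through unchanged.  Re-applying
    the transform to an already transformed column is refused via the
    ``log_transformed`` record.
    """
    already = set(table.log_transformed) & set(table.values.columns)
    if already:
        raise ValueError(
            f"columns already log-transformed: {sorted(already)[:5]}... — refusing to reapply"
        )
    df = table.values.copy()
    transformed = set()
    for col in df.columns:
        vals = df[col].to_numpy(dtype=float)
        if np.all(vals > 0):
            df[col] = np.log10(vals)
            transformed.add(col)
    return replace(table, values=df, log_transformed=frozenset(transformed))


def _hill_param_frame(fits: Sequence[CurveFit]) -> pd.DataFrame:
    rows = {}
    for f in fits:
        if f.family != "hill":
            raise ValueError(f"selection needs hill-family fits, got {f.family!r}")
        p = f.hill
        rows[f.odorant_id] = (p.imax, np.log10(p.ec50), p.n)
    return pd.DataFrame.from_dict(rows, orient="index", columns=HILL_PARAM_NAMES)


def select_by_hill_correlation(
    table: DescriptorTable,
    fits: Sequence[CurveFit],
    k_per_param: int = 40,
) -> SelectionReport:
    """Select the k descriptors most correlated with each Hill parameter.

    Pearson correlation of every column against Imax, log10(EC50) and the
    Hill slope; the three top-k lists are unioned and the forced transport
    features plus alpha-area appended when present.  Ties are broken by
    descriptor name order, so the report is deterministic.
    """
    if k_per_param < 1:
        raise ValueError("k_per_param must be >= 1")
    params = _hill_param_frame(fits)
    if set(params.index) != set(table.values.index):
        raise ValueError("molecules in the descriptor table and the fits do not match")
    params = params.loc[table.values.index]

    x = table.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    xs = xc.std(axis=0)
    corrs = {}
    for pname in HILL_PARAM_NAMES:
        y = params[pname].to_numpy()
        yc = y - y.mean()
        ys = yc.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc * yc[:, None]).mean(axis=0) / (xs * ys)
        corrs[pname] = pd.Series(np.nan_to_num(r), index=table.values.columns)
    corr_df = pd.DataFrame(corrs)

    reason_priority = {"imax": "correlated_imax", "log10_ec50": "correlated_ec50",
                       "hill_n": "correlated_n"}
    reasons: dict[str, str] = {}
    retained: list[str] = []
    for pname in HILL_PARAM_NAMES:
        ranked = sorted(
            table.values.columns, key=lambda c: (-abs(corr_df.loc[c, pname]), c)
        )[:k_per_param]
        for name in ranked:
            if name not in reasons:
                reasons[name] = reason_priority[pname]
                retained.append(name)
    for name in FORCED_TRANSPORT_FEATURES:
        if name in table.values.columns:
            reasons[name] = "forced_transport"
            if name not in retained:
                retained.append(name)
    if ALPHA_AREA_FEATURE in table.values.columns:
        reasons[ALPHA_AREA_FEATURE] = "forced_geometric"
        if ALPHA_AREA_FEATURE not in retained:
            retained.append(ALPHA_AREA_FEATURE)

    return SelectionReport(
        retained_names=tuple(retained),
        per_name_reason={n: reasons[n] for n in retained},
        correlation_values=corr_df.loc[retained],
    )


def simplified_feature_set(table: DescriptorTable) -> DescriptorTable:
    """Project onto the fixed 10-feature interpretable set, in fixed order."""
    missing = [c for c in SIMPLIFIED_FEATURES if c not in table.values.columns]
    if missing:
        raise MissingColumnError(f"simplified feature set needs column(s) {missing}")
    cols = list(SIMPLIFIED_FEATURES)
    return replace(
        table,
        values=table.values[cols].copy(),
        provenance={c: table.provenance[c] for c in cols},
        log_transformed=table.log_transformed & set(cols),
    )
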