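"""Readers and writers for the package's delimited-text schemas.

All tables are UTF-8 CSV with a header row.  Concentration columns are
explicit about scale: a ratings file carries either ``concentration``
(linear) or ``log10_concentration``, never both.  Every writer here has a
reader that parses its output losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .key_odorants import GCRecord
from .mixtures import ComponentState, MixturePrediction, MixtureSpec
from .psychophysics import CurveFit, HillParams, RatingPoint
from .synthetic import GroundTruth

__all__ = [
    "read_ratings", "write_ratings",
    "read_curve_fits", "write_curve_fits",
    "read_mixtures", "write_mixtures",
    "write_predictions", "read_predictions",
    "read_descriptor_table", "write_descriptor_table",
    "read_gc_table", "write_gc_table",
    "write_ground_truth",
]

_FLOAT_FMT = "%.17g"


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    return df


def _require(df: pd.DataFrame, path, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


# --------------------------------------------------------------------- ratings


def read_ratings(path) -> list[RatingPoint]:
    df = _read_csv(path)
    _require(df, path, ["odorant_id", "intensity"])
    has_lin = "concentration" in df.columns
    has_log = "log10_concentration" in df.columns
    if has_lin == has_log:
        raise ValueError(
            f"{path}: exactly one of 'concentration' or 'log10_concentration' is required"
        )
    conc = df["concentration"] if has_lin else 10.0 ** df["log10_concentration"]
    reps = df["replicate"] if "replicate" in df.columns else pd.Series(0, index=df.index)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                RatingPoint(str(row["odorant_id"]), float(conc[i]), float(row["intensity"]),
                            int(reps[i]))
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_ratings(points: Sequence[RatingPoint], path) -> None:
    pd.DataFrame(
        [(p.odorant_id, p.concentration, p.intensity, p.replicate) for p in points],
        columns=["odorant_id", "concentration", "intensity", "replicate"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ------------------------------------------------------------------ curve fits

_FIT_COLS = ["odorant_id", "family", "imax", "ec50", "hill_n", "extra_params",
             "rmse", "n_points", "converged"]


def write_curve_fits(fits: Sequence[CurveFit], path) -> None:
    rows = []
    for f in fits:
        imax = ec50 = hill_n = np.nan
        extra = ""
        if f.family == "hill":
            imax, ec50, hill_n = f.hill.imax, f.hill.ec50, f.hill.n
        elif f.family == "beidler":
            imax, ec50 = f.params["imax"], f.params["k"]
        else:
            extra = json.dumps(f.params, sort_keys=True)
        rows.append((f.odorant_id, f.family, imax, ec50, hill_n, extra,
                     f.rmse, f.n_points, f.converged))
    pd.DataFrame(rows, columns=_FIT_COLS).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_curve_fits(path) -> list[CurveFit]:
    df = _read_csv(path)
    _require(df, path, _FIT_COLS[:2] + _FIT_COLS[6:])
    out = []
    for _, row in df.iterrows():
        fam = row["family"]
        if fam == "hill":
            params = HillParams(float(row["imax"]), float(row["ec50"]), float(row["hill_n"]))
        elif fam == "beidler":
            params = {"imax": float(row["imax"]), "k": float(row["ec50"])}
        else:
            params = json.loads(row["extra_params"])
        out.append(CurveFit(str(row["odorant_id"]), fam, params, float(row["rmse"]),
                            int(row["n_points"]), bool(row["converged"])))
    return out


# -------------------------------------------------------------------- mixtures


def write_mixtures(mixtures: Sequence[MixtureSpec], path) -> None:
    rows = [
        (m.mixture_id, c.odorant_id, c.concentration, c.intensity_alone)
        for m in mixtures
        for c in m.components
    ]
    pd.DataFrame(
        rows, columns=["mixture_id", "odorant_id", "concentration", "intensity_alone"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_mixtures(path, curves: Sequence[CurveFit] | None = None) -> list[MixtureSpec]:
    """Read a mixture table, optionally joining Hill params from fitted curves."""
    df = _read_csv(path)
    _require(df, path, ["mixture_id", "odorant_id", "concentration", "intensity_alone"])
    hill_by_id = {c.odorant_id: c.hill for c in curves or [] if c.family == "hill"}
    out = []
    for mid, grp in df.groupby("mixture_id", sort=False):
        comps = tuple(
            ComponentState(
                str(r["odorant_id"]), float(r["concentration"]), float(r["intensity_alone"]),
                hill=hill_by_id.get(str(r["odorant_id"])),
            )
            for _, r in grp.iterrows()
        )
        out.append(MixtureSpec(str(mid), comps))
    return out


# ----------------------------------------------------------------- predictions


def write_predictions(preds: Sequence[MixturePrediction], path) -> None:
    pd.DataFrame(
        [(p.mixture_id, p.model, p.value, p.valid, p.reason) for p in preds],
        columns=["mixture_id", "model", "value", "valid", "reason"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_predictions(path) -> list[MixturePrediction]:
    df = _read_csv(path)
    _require(df, path, ["mixture_id", "model", "value", "valid"])
    return [
        MixturePrediction(str(r["mixture_id"]), str(r["model"]), float(r["value"]),
                          bool(r["valid"]),
                          "" if pd.isna(r.get("reason", "")) else str(r.get("reason", "")))
        for _, r in df.iterrows()
    ]


# ----------------------------------------------------------------- descriptors


def write_descriptor_table(table: DescriptorTable, path) -> None:
    """CSV of values plus a JSON sidecar with provenance and transform log."""
    path = Path(path)
    df = table.values.copy()
    df.insert(0, "molecule_id", df.index)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "provenance": dict(table.provenance),
        "log_transformed": sorted(table.log_transformed),
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_descriptor_table(path) -> DescriptorTable:
    path = Path(path)
    df = _read_csv(path)
    _require(df, path, ["molecule_id"])
    df = df.set_index("molecule_id")
    df.index = df.index.astype(str)
    df.index.name = None
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    prov, logt = {}, frozenset()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        prov = meta.get("provenance", {})
        logt = frozenset(meta.get("log_transformed", []))
    return DescriptorTable(df, prov, logt)


# ------------------------------------------------------------------- GC tables


def read_gc_table(path) -> list[GCRecord]:
    df = _read_csv(path)
    _require(df, path, ["compound_id", "concentration", "threshold"])
    feat_cols = [c for c in df.columns if c not in ("compound_id", "concentration", "threshold")]
    out = []
    for _, r in df.iterrows():
        feats = r[feat_cols].to_numpy(dtype=float) if feat_cols else None
        out.append(GCRecord(str(r["compound_id"]), float(r["concentration"]),
                            float(r["threshold"]), feats))
    return out


def write_gc_table(records: Sequence[GCRecord], path, feature_names: Sequence[str] = ()) -> None:
    rows = []
    for rec in records:
        row = [rec.compound_id, rec.concentration, rec.detection_threshold]
        if feature_names:
            row += list(np.asarray(rec.features, dtype=float))
        rows.append(row)
    cols = ["compound_id", "concentration", "threshold"] + list(feature_names)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- ground truth


def write_ground_truth(truth: GroundTruth, out_dir) -> dict[str, Path]:
    """Write a complete synthetic dataset in the package's input schemas.

    Emits ratings, descriptors, mixtures, true Hill parameters and the
    mixture truth sidecar; returns the path of each file written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ratings": out_dir / "ratings.csv",
        "descriptors": out_dir / "descriptors.csv",
        "mixtures": out_dir / "mixtures.csv",
        "hill_params": out_dir / "true_hill_params.csv",
        "mixture_truth": out_dir / "mixture_truth.csv",
    }
    write_ratings(truth.ratings, paths["ratings"])
    write_descriptor_table(truth.molecules, paths["descriptors"])
    write_mixtures(truth.mixtures, paths["mixtures"])
    pd.DataFrame(
        [(m, p.imax, p.ec50, p.n) for m, p in truth.hill_params.items()],
        columns=["odorant_id", "imax", "ec50", "hill_n"],
    ).to_csv(paths["hill_params"], index=False, float_format=_FLOAT_FMT)
    truth.mixture_truth.to_csv(paths["mixture_truth"], index=False, float_format=_FLOAT_FMT)
    return paths
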