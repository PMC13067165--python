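"""File formats, configuration and reports.

Study data travel as long (tidy) CSV with columns ``sample_id``,
``replicate_id``, ``time_h`` and exactly one value stream per file:
``swelling`` (g/g), ``mass_g`` (+ ``dry_mass_g`` per replicate), or
``density_g_per_mL``.  The time column is named with its unit to prevent
silent unit errors.  Reports are written as a machine-readable JSON
document (stable key order, full precision) plus a human CSV summary
with 4-significant-figure display rounding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MassSeries, DensitySeries, SwellingCurve, swelling_degree_from_mass
from .estimators import FitResult
from .mechanism import MechanismCall
from .stats import GroupComparison
from .synthetic import StudyFixture

__all__ = [
    "StudyTable",
    "RunConfig",
    "read_study",
    "write_report",
    "write_study",
    "write_profile",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1"

_VALUE_COLUMNS = ("swelling", "mass_g", "density_g_per_mL")


@dataclass(frozen=True)
class StudyTable:
    """Validated long-format study data.

    ``kind`` is one of ``swelling``/``mass``/``density`` according to the
    value column present.
    """

    frame: pd.DataFrame
    kind: str

    def curves(self) -> list[SwellingCurve]:
        if self.kind == "density":
            raise ValueError("density tables carry no swelling curves")
        out = []
        for (sample, rep), g in self.frame.groupby(
            ["sample_id", "replicate_id"], sort=True
        ):
            t = g["time_h"].to_numpy(dtype=float)
            if self.kind == "mass":
                w0 = float(g["dry_mass_g"].iloc[0])
                series = MassSeries(str(sample), str(rep), t, g["mass_g"].to_numpy(float), w0)
                out.append(swelling_degree_from_mass(series))
            else:
                out.append(SwellingCurve(str(sample), str(rep), t, g["swelling"].to_numpy(float)))
        return out

    def density_series(self) -> list[DensitySeries]:
        if self.kind != "density":
            raise ValueError(f"table kind is {self.kind!r}, not density")
        out = []
        for (sample, rep), g in self.frame.groupby(
            ["sample_id", "replicate_id"], sort=True
        ):
            out.append(
                DensitySeries(
                    str(sample), str(rep),
                    g["time_h"].to_numpy(float),
                    g["density_g_per_mL"].to_numpy(float),
                )
            )
        return out


def read_study(path) -> StudyTable:
    """Read and canonicalize a study CSV; errors name the offending row.

    Rows are sorted by (sample, replicate, time); duplicate times within
    a replicate and mixed value columns are rejected.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    present = [c for c in _VALUE_COLUMNS if c in df.columns]
    if len(present) != 1:
        raise ValueError(
            f"{path}: need exactly one of {_VALUE_COLUMNS} as value column, "
            f"found {present or 'none'}"
        )
    value_col = present[0]
    required = ["sample_id", "replicate_id", "time_h", value_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    kind = {"swelling": "swelling", "mass_g": "mass", "density_g_per_mL": "density"}[value_col]
    if kind == "mass" and "dry_mass_g" not in df.columns:
        raise ValueError(f"{path}: mass_g data requires a dry_mass_g column")
    if df[required].isna().any().any():
        bad = int(df[required].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value in row {bad}")
    df = df.sort_values(["sample_id", "replicate_id", "time_h"], kind="mergesort")
    df = df.reset_index(drop=True)
    dup = df.duplicated(subset=["sample_id", "replicate_id", "time_h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicated time {row['time_h']} for sample "
            f"{row['sample_id']!r} replicate {row['replicate_id']!r}"
        )
    if kind == "mass":
        nuniq = df.groupby(["sample_id", "replicate_id"])["dry_mass_g"].nunique()
        bad = nuniq[nuniq > 1]
        if len(bad):
            raise ValueError(
                f"{path}: dry_mass_g must be constant within a replicate; "
                f"violated by {bad.index[0]}"
            )
    return StudyTable(df, kind)


def write_study(curves: Sequence[SwellingCurve] | StudyFixture, path) -> None:
    """Write swelling curves as the long CSV dialect :func:`read_study` reads."""
    if isinstance(curves, StudyFixture):
        curves = curves.curves
    rows = []
    for c in curves:
        for t, s in zip(c.times, c.S):
            rows.append(
                {"sample_id": c.sample_id, "replicate_id": c.replicate_id,
                 "time_h": t, "swelling": s}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass(frozen=True)
class RunConfig:
    """Options for a fitting run; loadable from YAML or JSON."""

    models: tuple[str, ...] = ("swelling_eq", "power_law")
    window_fraction: float = 0.60
    threshold_lower: float = 0.1
    threshold_upper: float = 100.0
    reference_time: str | float = "window_midpoint"
    tail_fraction: float = 0.2
    alpha: float = 0.05
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.window_fraction <= 1:
            raise ValueError("window_fraction must be in (0, 1]")
        if not self.threshold_lower < self.threshold_upper:
            raise ValueError("threshold_lower must be < threshold_upper")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _round_sig(x: float, sig: int = 4) -> float:
    if x == 0 or not np.isfinite(x):
        return float(x)
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False, trim="k"
    ))


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(
    fits: Sequence[FitResult],
    mechanism_calls: Mapping[str, MechanismCall] | None = None,
    comparisons: Sequence[GroupComparison] | None = None,
    out_dir="report",
) -> dict[str, Path]:
    """Write report.json (machine) and summary.csv (per-sample table).

    The JSON document is byte-stable for identical inputs: keys are
    sorted and floats serialized at full precision.  The CSV summary
    mirrors the conventional results-table layout — per sample the
    power-law exponent n +/- sd with its exponent-range label, the
    swelling-equation k +/- sd, the a*/b* ratio +/- sd, the mean R^2,
    the ratio-scale mechanism call, and Tukey letters where available.
    """
    if not fits:
        raise ValueError("need at least one fit to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mechanism_calls = mechanism_calls or {}
    comparisons = comparisons or []
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "fits": [f.to_dict() for f in fits],
        "mechanism_calls": {k: v.to_dict() for k, v in sorted(mechanism_calls.items())},
        "comparisons": [c.to_dict() for c in comparisons],
    }
    json_path = out / "report.json"
    json_path.write_text(json.dumps(doc, sort_keys=True, indent=1, default=_json_default) + "\n")

    letters = {}
    for comp in comparisons:
        for g, lt in comp.letters.items():
            letters.setdefault(g, {})[comp.parameter] = lt

    rows = []
    samples = sorted({f.sample_id or "" for f in fits})
    for sample in samples:
        sf = [f for f in fits if (f.sample_id or "") == sample]
        row: dict[str, Any] = {"sample_id": sample}
        for model, prefix in (("power_law", "n"), ("swelling_eq", None)):
            mf = [f for f in sf if f.model_id == model]
            if not mf:
                continue
            if model == "power_law":
                vals = [f.params.n for f in mf]
                row["n_mean"] = _round_sig(float(np.mean(vals)))
                row["n_sd"] = _round_sig(float(np.std(vals, ddof=1))) if len(vals) > 1 else float("nan")
                from .mechanism import classify_from_exponent

                row["exponent_mechanism"] = classify_from_exponent(float(np.mean(vals))).label
                row["power_law_r2"] = _round_sig(float(np.mean([f.r2 for f in mf])))
            else:
                ks = [f.params.k for f in mf]
                ratios = [f.params.ratio for f in mf if f.params.b_star != 0]
                row["k_mean"] = _round_sig(float(np.mean(ks)))
                row["k_sd"] = _round_sig(float(np.std(ks, ddof=1))) if len(ks) > 1 else float("nan")
                if ratios:
                    row["ratio_mean"] = _round_sig(float(np.mean(ratios)))
                    row["ratio_sd"] = _round_sig(float(np.std(ratios, ddof=1))) if len(ratios) > 1 else float("nan")
                row["swelling_eq_r2"] = _round_sig(float(np.mean([f.r2 for f in mf])))
                row["overshoot"] = any(f.params.a_star < 0 for f in mf)
        call = mechanism_calls.get(sample)
        if call is not None:
            row["mechanism_call"] = call.hard_label
            row["dominance"] = call.dominance_label
        for pname, lt in sorted(letters.get(sample, {}).items()):
            row[f"letters_{pname}"] = lt
        rows.append(row)
    csv_path = out / "summary.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return {"json": json_path, "csv": csv_path}


def write_profile(profile, path) -> None:
    """CF/CR profile as CSV: time_h, CF, CR, valid."""
    pd.DataFrame(
        {"time_h": profile.times, "CF": profile.CF, "CR": profile.CR,
         "valid": profile.valid}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report schema (versioned, checked in tests and on demand)

def validate_report(doc: Mapping[str, Any]) -> None:
    """Structural check of a report document; raises ValueError on breach."""
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError("unknown or missing schema_version")
    if not isinstance(doc.get("fits"), list) or not doc["fits"]:
        raise ValueError("fits must be a non-empty list")
    fit_keys = {
        "model_id", "params", "stderr", "r2", "r2_adj", "rss", "n_points",
        "window", "converged", "n_starts_used", "sample_id", "replicate_id",
    }
    for f in doc["fits"]:
        missing = fit_keys - set(f)
        if missing:
            raise ValueError(f"fit record missing keys {sorted(missing)}")
        if not isinstance(f["params"], dict):
            raise ValueError("fit params must be a mapping")
        if len(f["window"]) != 2:
            raise ValueError("fit window must be a (t_min, t_max) pair")
    if not isinstance(doc.get("mechanism_calls"), dict):
        raise ValueError("mechanism_calls must be a mapping")
    for call in doc["mechanism_calls"].values():
        for key in ("ratio", "hard_label", "dominance_label", "reference_time",
                    "overshoot_regime", "ratio_defined"):
            if key not in call:
                raise ValueError(f"mechanism call missing {key!r}")
    if not isinstance(doc.get("comparisons"), list):
        raise ValueError("comparisons must be a list")
    for comp in doc["comparisons"]:
        for key in ("parameter", "alpha", "groups", "anova_p"):
            if key not in comp:
                raise ValueError(f"comparison missing {key!r}")
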