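"""Tabular I/O, run configuration and report writing.

File conventions
----------------
* Times are hours everywhere except inside well-counter series, whose
  columns are explicitly named in minutes.
* Biodistribution CSV: comment lines ``# key=value`` carry dataset metadata,
  then columns ``organ,time_h,mean_pia_g,sd_pia_g,n``.
* Well-counter CSV: metadata lines for efficiency and mass, then columns
  ``t_start_min,interval_min,counts``.
* TIA CSV: ``organ,tia_pia_h_g,method,tail_fraction,nuclide``.
* Dose report: a CSV in conventional organ order (blood first, tumor last)
  with optional per-component columns, plus a prescription JSON.  Output is
  deterministic for fixed input (fixed float formatting, sorted keys).

Validation errors name the offending row so a malformed animal-study sheet
is diagnosable without opening the code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .pk import TimeActivityCurve

__all__ = [
    "BiodistributionDataset",
    "RunConfig",
    "ValidationError",
    "read_biodistribution_csv",
    "write_biodistribution_csv",
    "read_well_counter_csv",
    "write_well_counter_csv",
    "write_tia_csv",
    "read_tia_csv",
    "write_dose_report",
]

#: Conventional report ordering of the study's tissues.
ORGAN_ORDER = (
    "blood", "heart", "lungs", "liver", "spleen", "kidneys", "stomach",
    "intestine", "bone", "thymus", "muscle", "BAT", "red marrow", "tumor",
)

_FLOAT_FMT = "%.17g"


class ValidationError(ValueError):
    """Input file failed schema or invariant checks."""


@dataclass(frozen=True)
class BiodistributionDataset:
    """A full biodistribution study: one time-activity curve per organ."""

    agent_label: str
    protein_dose_mg_kg: float
    administered_activity_kbq: float
    curves: tuple[TimeActivityCurve, ...]

    def __post_init__(self) -> None:
        labels = [c.organ_label for c in self.curves]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValidationError(f"duplicate organ labels: {dupes}")

    @property
    def organs(self) -> tuple[str, ...]:
        return tuple(c.organ_label for c in self.curves)

    def curve(self, organ: str) -> TimeActivityCurve:
        for c in self.curves:
            if c.organ_label == organ:
                return c
        raise KeyError(f"no curve for organ {organ!r}")


# ---------------------------------------------------------------------------
# biodistribution CSV

def _read_metadata(path: Path) -> dict[str, str]:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def write_biodistribution_csv(ds: BiodistributionDataset, path) -> None:
    path = Path(path)
    rows = []
    for c in ds.curves:
        sd = c.sd_conc if c.sd_conc is not None else np.zeros(len(c))
        n = c.n_animals if c.n_animals is not None else np.ones(len(c), dtype=int)
        for i in range(len(c)):
            rows.append((c.organ_label, c.times_h[i], c.mean_conc[i], sd[i], int(n[i])))
    df = pd.DataFrame(rows, columns=["organ", "time_h", "mean_pia_g", "sd_pia_g", "n"])
    with open(path, "w") as fh:
        fh.write(f"# agent={ds.agent_label}\n")
        fh.write(f"# protein_dose_mg_kg={ds.protein_dose_mg_kg!r}\n")
        fh.write(f"# administered_activity_kbq={ds.administered_activity_kbq!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_biodistribution_csv(path) -> BiodistributionDataset:
    """Read and validate a biodistribution CSV (see module notes for schema)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["organ", "time_h", "mean_pia_g", "sd_pia_g", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    neg = df.index[df["mean_pia_g"] < 0]
    if len(neg):
        raise ValidationError(
            f"{path.name}: negative mean_pia_g at data row {int(neg[0]) + 1}"
        )
    dup = df.duplicated(subset=["organ", "time_h"])
    if dup.any():
        row = int(df.index[dup][0]) + 1
        raise ValidationError(f"{path.name}: duplicate (organ, time) at data row {row}")
    curves = []
    for organ, grp in df.groupby("organ", sort=False):
        grp = grp.sort_values("time_h")
        curves.append(
            TimeActivityCurve(
                organ_label=str(organ),
                times_h=grp["time_h"].to_numpy(float),
                mean_conc=grp["mean_pia_g"].to_numpy(float),
                sd_conc=grp["sd_pia_g"].to_numpy(float),
                n_animals=grp["n"].to_numpy(int),
            )
        )
    return BiodistributionDataset(
        agent_label=meta.get("agent", "unknown"),
        protein_dose_mg_kg=float(meta.get("protein_dose_mg_kg", "nan")),
        administered_activity_kbq=float(meta.get("administered_activity_kbq", "nan")),
        curves=tuple(curves),
    )


# ---------------------------------------------------------------------------
# well-counter CSV

def write_well_counter_csv(series, path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "t_start_min": series.interval_start_min,
            "interval_min": np.full(len(series.counts), series.interval_min),
            "counts": series.counts,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# efficiency={series.efficiency!r}\n")
        fh.write(f"# mass_g={series.mass_g!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_well_counter_csv(path):
    from .synthetic import WellCounterSeries  # deferred: synthetic imports io

    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["t_start_min", "interval_min", "counts"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    intervals = df["interval_min"].unique()
    if len(intervals) != 1:
        raise ValidationError(f"{path.name}: interval_min must be constant")
    return WellCounterSeries(
        interval_start_min=df["t_start_min"].to_numpy(float),
        interval_min=float(intervals[0]),
        counts=df["counts"].to_numpy(np.int64),
        efficiency=float(meta.get("efficiency", "1.0")),
        mass_g=float(meta.get("mass_g", "1.0")),
    )


# ---------------------------------------------------------------------------
# TIA and dose report

def write_tia_csv(results, path) -> None:
    df = pd.DataFrame(
        [
            {
                "organ": r.organ_label,
                "tia_pia_h_g": r.tia,
                "method": r.method,
                "tail_fraction": r.tail_fraction,
                "nuclide": r.radionuclide_label,
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_tia_csv(path):
    from .tia import TIAResult

    df = pd.read_csv(path)
    required = ["organ", "tia_pia_h_g", "method", "tail_fraction", "nuclide"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{Path(path).name}: missing columns {missing}")
    return [
        TIAResult(
            organ_label=str(r["organ"]),
            tia=float(r["tia_pia_h_g"]),
            method=str(r["method"]),
            tail_fraction=float(r["tail_fraction"]),
            radionuclide_label=str(r["nuclide"]),
        )
        for _, r in df.iterrows()
    ]


def _organ_sort_key(label: str):
    try:
        return (0, ORGAN_ORDER.index(label))
    except ValueError:
        return (1, label)


def write_dose_report(coeffs, prescription, csv_path, json_path=None) -> None:
    """Write the dose-coefficient table (CSV) and prescription (JSON).

    Organs appear in the conventional order (unknown organs appended
    alphabetically); component breakdowns become extra columns summing to
    the total.  Byte output is deterministic for fixed input.
    """
    coeffs = sorted(coeffs, key=lambda c: _organ_sort_key(c.organ_label))
    comp_keys = sorted({k for c in coeffs if c.components for k in c.components})
    rows = []
    for c in coeffs:
        row = {"organ": c.organ_label, "mean_absorbed_dose_mgy_per_kbq": c.mgy_per_kbq}
        for k in comp_keys:
            row[f"component_{k}"] = (c.components or {}).get(k, math.nan)
        rows.append(row)
    cols = ["organ", "mean_absorbed_dose_mgy_per_kbq"] + [f"component_{k}" for k in comp_keys]
    pd.DataFrame(rows, columns=cols).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    if prescription is not None and json_path is not None:
        payload = {
            "limiting_organ": prescription.limiting_organ,
            "limit_gy": prescription.limit_gy,
            "administered_kbq": prescription.administered_kbq,
            "organ_doses_gy": dict(sorted(prescription.organ_doses_gy.items())),
        }
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration

class RunConfig(BaseModel):
    """Validated pipeline configuration (YAML-loadable; unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    noise_cv: float = 0.15
    schedule_h: list[float] = [1.0, 6.0, 24.0, 72.0, 144.0]
    n_per_time: int = 5
    nuclide: str = "Ac-225"
    tia_method: str = "auto"  # fit | hybrid | auto
    organ_dose_limits_gy: dict[str, float] = {"liver": 28.0, "kidneys": 18.0}
    marrow_from_blood_factor: float = 0.36

    @field_validator("noise_cv")
    @classmethod
    def _cv_nonneg(cls, v):
        if v < 0:
            raise ValueError("noise_cv must be non-negative")
        return v

    @field_validator("schedule_h")
    @classmethod
    def _schedule_increasing(cls, v):
        if len(v) == 0 or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule_h must be non-empty and strictly increasing")
        return v

    @field_validator("tia_method")
    @classmethod
    def _method_known(cls, v):
        if v not in ("fit", "hybrid", "auto"):
            raise ValueError("tia_method must be fit, hybrid or auto")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
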