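"""EHR feature encoding: one-hot statics and carried-forward temporal fields.

The EHR vector for a subject concatenates

* static demographics/comorbidities, with categorical fields one-hot
  encoded against a fixed schema vocabulary,
* medication-category counts over the hospital stay, and
* time-stamped labs/vitals carried forward (last observation at or before
  each tumbling-window end, "SubWin n" columns) with a per-window missing
  indicator.

The column dictionary is a configurable schema (YAML-serialisable); the
default schema shipped with the synthetic generator has 542 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StaticField:
    name: str
    kind: str  # "numeric" | "categorical" | "flag"
    levels: tuple = ()

    def n_columns(self) -> int:
        return len(self.levels) if self.kind == "categorical" else 1


@dataclass(frozen=True)
class EhrSchema:
    """Ordered feature dictionary defining the EHR vector layout."""

    static: tuple[StaticField, ...]
    temporal: tuple[str, ...]
    med_categories: tuple[str, ...] = ()
    n_windows: int = 5
    temporal_defaults: dict = field(default_factory=dict)
    strict: bool = False

    @property
    def n_columns(self) -> int:
        n = sum(f.n_columns() for f in self.static)
        n += len(self.med_categories)
        n += len(self.temporal) * self.n_windows * 2  # value + missing flag
        return n

    def column_names(self) -> list[str]:
        names: list[str] = []
        for f in self.static:
            if f.kind == "categorical":
                names.extend(f"{f.name}={lvl}" for lvl in f.levels)
            else:
                names.append(f.name)
        names.extend(f"MedCount.{c}" for c in self.med_categories)
        for t in self.temporal:
            for w in range(1, self.n_windows + 1):
                names.append(f"{t}.SubWin {w}")
                names.append(f"{t}.SubWin {w}.missing")
        return names

    def to_dict(self) -> dict:
        return {
            "static": [{"name": f.name, "kind": f.kind, "levels": list(f.levels)}
                       for f in self.static],
            "temporal": list(self.temporal),
            "med_categories": list(self.med_categories),
            "n_windows": self.n_windows,
            "temporal_defaults": dict(self.temporal_defaults),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EhrSchema":
        return cls(
            static=tuple(StaticField(s["name"], s["kind"], tuple(s.get("levels", ())))
                         for s in d["static"]),
            temporal=tuple(d["temporal"]),
            med_categories=tuple(d.get("med_categories", ())),
            n_windows=int(d.get("n_windows", 5)),
            temporal_defaults=dict(d.get("temporal_defaults", {})),
        )


@dataclass
class EhrRecord:
    """Raw EHR data of one subject.

    ``static``: mapping field name -> value.  ``temporal``: DataFrame with
    columns (timestamp, feature, value), timestamps in the same clock as
    the waveforms.  ``med_counts``: mapping category -> administration count.
    """

    subject_id: str
    static: dict
    temporal: pd.DataFrame
    med_counts: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.temporal):
            if not self.temporal["timestamp"].is_monotonic_increasing:
                self.temporal = self.temporal.sort_values("timestamp", kind="stable")


def encode_static(record: EhrRecord, schema: EhrSchema) -> tuple[np.ndarray, list[str]]:
    """Encode static fields (plus medication counts) against the schema.

    Unseen categorical values yield an all-zero one-hot group (with a
    warning) unless the schema is strict, in which case they are a
    :class:`DataError`.
    """
    values: list[float] = []
    names: list[str] = []
    for f in schema.static:
        v = record.static.get(f.name)
        if f.kind == "categorical":
            onehot = np.zeros(len(f.levels))
            if v is not None:
                if v in f.levels:
                    onehot[f.levels.index(v)] = 1.0
                elif schema.strict:
                    raise DataError(f"value {v!r} not in vocabulary of {f.name!r}")
                else:
                    log.warning("unseen category %r for field %r (zero group emitted)", v, f.name)
            values.extend(onehot)
            names.extend(f"{f.name}={lvl}" for lvl in f.levels)
        else:
            values.append(float(v) if v is not None else 0.0)
            names.append(f.name)
    for c in schema.med_categories:
        values.append(float(record.med_counts.get(c, 0)))
        names.append(f"MedCount.{c}")
    return np.asarray(values), names


def carry_forward_temporal(record: EhrRecord, window_end_times: np.ndarray,
                           schema: EhrSchema) -> tuple[np.ndarray, list[str]]:
    """Last-observation-carried-forward encoding of temporal fields.

    For each temporal feature and tumbling window, the value is the most
    recent entry at or before the window end.  Windows with no prior
    observation get the schema default (NaN when none is configured, to be
    imputed downstream) and a missing indicator of 1.  Future entries can
    never influence a window.
    """
    ends = np.asarray(window_end_times, dtype=float)
    if np.any(np.diff(ends) < 0):
        raise DataError("window_end_times must be sorted")
    values: list[float] = []
    names: list[str] = []
    temporal = record.temporal
    for feat in schema.temporal:
        sub = temporal[temporal["feature"] == feat] if len(temporal) else temporal
        ts = sub["timestamp"].to_numpy(dtype=float) if len(sub) else np.empty(0)
        vs = sub["value"].to_numpy(dtype=float) if len(sub) else np.empty(0)
        default = schema.temporal_defaults.get(feat, np.nan)
        for w, end in enumerate(ends, start=1):
            pos = np.searchsorted(ts, end, side="right") - 1
            if pos >= 0:
                values.extend([vs[pos], 0.0])
            else:
                values.extend([default, 1.0])
            names.append(f"{feat}.SubWin {w}")
            names.append(f"{feat}.SubWin {w}.missing")
    return np.asarray(values), names


def encode_ehr(record: EhrRecord, window_end_times: np.ndarray,
               schema: EhrSchema) -> tuple[np.ndarray, list[str]]:
    """Full fixed-length EHR vector: statics + med counts + carried-forward."""
    sv, sn = encode_static(record, schema)
    tv, tn = carry_forward_temporal(record, window_end_times, schema)
    return np.concatenate([sv, tv]), sn + tn


# ---------------------------------------------------------------------------
# CSV ingestion (static.csv: one row per subject; temporal.csv: long format)


def read_ehr_csv(static_csv, temporal_csv, med_categories=()) -> dict[str, EhrRecord]:
    static = pd.read_csv(static_csv)
    temporal = pd.read_csv(temporal_csv)
    required = {"subject_id", "timestamp", "feature", "value"}
    if not required.issubset(temporal.columns):
        raise DataError(f"temporal.csv must have columns {sorted(required)}")
    out: dict[str, EhrRecord] = {}
    tgroups = dict(tuple(temporal.groupby("subject_id")))
    for _, row in static.iterrows():
        sid = str(row["subject_id"])
        svals = row.drop("subject_id").to_dict()
        med = {c: svals.pop(f"MedCount.{c}") for c in med_categories if f"MedCount.{c}" in svals}
        t = tgroups.get(row["subject_id"],
                        pd.DataFrame(columns=["timestamp", "feature", "value"]))
        out[sid] = EhrRecord(subject_id=sid, static=svals,
                             temporal=t[["timestamp", "feature", "value"]], med_counts=med)
    return out
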