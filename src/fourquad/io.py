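"""CSV input/output and the JSON report document.

Two CSV layouts are supported for a reference/test pair:

* long (canonical): columns ``subject_id, time, method, value`` with method
  values ``reference`` and ``test`` (or any two/three observer names for
  multi-observer files);
* wide: ``subject_id`` followed by ``reference_t1..reference_t{T+1}`` and
  ``test_t1..test_t{T+1}``.

The reader auto-detects the layout from the header.  Subjects with missing
entries are rejected with a clear error: the concordance model has no
missing-data mechanism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import MeasurementSeries
from .errors import ConfigurationError

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_methods_long",
    "write_methods_long",
    "file_digest",
    "ReportDocument",
]


def file_digest(path) -> str:
    """Hex SHA-256 of a file's bytes, for report provenance."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _series_from_frames(
    wide: dict[str, pd.DataFrame], reference: str, test: str
) -> MeasurementSeries:
    ref = wide[reference]
    tst = wide[test].reindex(index=ref.index, columns=ref.columns)
    if ref.isna().any().any() or tst.isna().any().any():
        raise ConfigurationError(
            "missing values detected; remove incomplete subjects before loading"
        )
    return MeasurementSeries(
        subject_ids=list(ref.index),
        times=list(ref.columns),
        reference_values=ref.to_numpy(dtype=float),
        test_values=tst.to_numpy(dtype=float),
    )


def read_methods_long(path) -> dict[str, pd.DataFrame]:
    """Read a long CSV into one subject-by-time frame per method name."""
    df = pd.read_csv(path)
    required = {"subject_id", "time", "method", "value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"long layout requires columns {sorted(required)}; got {list(df.columns)}"
        )
    out: dict[str, pd.DataFrame] = {}
    for method, sub in df.groupby("method", sort=False):
        wide = sub.pivot_table(
            index="subject_id", columns="time", values="value", sort=False
        )
        # keep first-appearance subject order, time order as sorted labels
        order = sub["subject_id"].drop_duplicates()
        out[str(method)] = wide.reindex(index=order, columns=sorted(wide.columns))
    return out


def read_series_csv(
    path, *, reference: str = "reference", test: str = "test"
) -> MeasurementSeries:
    """Read a reference/test pair from CSV, auto-detecting the layout."""
    head = pd.read_csv(path, nrows=0)
    cols = set(head.columns)
    if {"subject_id", "time", "method", "value"}.issubset(cols):
        frames = read_methods_long(path)
        for name in (reference, test):
            if name not in frames:
                raise ConfigurationError(
                    f"method '{name}' not found in file (has {sorted(frames)})"
                )
        return _series_from_frames(frames, reference, test)
    if "subject_id" in cols:
        df = pd.read_csv(path).set_index("subject_id")
        ref_cols = [c for c in df.columns if c.startswith("reference_t")]
        tst_cols = [c for c in df.columns if c.startswith("test_t")]
        if not ref_cols or len(ref_cols) != len(tst_cols):
            raise ConfigurationError(
                "wide layout requires matching reference_t*/test_t* columns"
            )
        key = lambda c: int(c.rsplit("_t", 1)[1])
        ref_cols = sorted(ref_cols, key=key)
        tst_cols = sorted(tst_cols, key=key)
        if df[ref_cols + tst_cols].isna().any().any():
            raise ConfigurationError(
                "missing values detected; remove incomplete subjects before loading"
            )
        return MeasurementSeries(
            subject_ids=list(df.index),
            times=[key(c) for c in ref_cols],
            reference_values=df[ref_cols].to_numpy(dtype=float),
            test_values=df[tst_cols].to_numpy(dtype=float),
        )
    raise ConfigurationError(
        "unrecognized CSV header: expected the long layout "
        "(subject_id,time,method,value) or the wide layout "
        "(subject_id,reference_t*,test_t*)"
    )


def write_series_csv(series: MeasurementSeries, path, *, layout: str = "long"):
    """Write a reference/test pair to CSV in the long or wide layout."""
    if layout == "long":
        rows = []
        for name, values in (
            ("reference", series.reference_values),
            ("test", series.test_values),
        ):
            for i, sid in enumerate(series.subject_ids):
                for j, t in enumerate(series.times):
                    rows.append((sid, t, name, values[i, j]))
        pd.DataFrame(rows, columns=["subject_id", "time", "method", "value"]).to_csv(
            path, index=False
        )
    elif layout == "wide":
        data = {"subject_id": list(series.subject_ids)}
        for j, _ in enumerate(series.times):
            data[f"reference_t{j + 1}"] = series.reference_values[:, j]
        for j, _ in enumerate(series.times):
            data[f"test_t{j + 1}"] = series.test_values[:, j]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ConfigurationError("layout must be 'long' or 'wide'")


def write_methods_long(methods: dict[str, MeasurementSeries], path):
    """Write several single-observer series to one long CSV."""
    rows = []
    for name, series in methods.items():
        for i, sid in enumerate(series.subject_ids):
            for j, t in enumerate(series.times):
                rows.append((sid, t, name, series.reference_values[i, j]))
    pd.DataFrame(rows, columns=["subject_id", "time", "method", "value"]).to_csv(
        path, index=False
    )


@dataclass
class ReportDocument:
    """JSON-serializable analysis report.

    Carries enough provenance (tool version, input digest, configuration
    echo, seeds) that every number in it can be regenerated.
    """

    config: dict
    results: dict
    warnings: list = field(default_factory=list)
    input_digest: str | None = None
    version: str = __version__

    def to_json(self, indent: int = 2) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")

        return json.dumps(dataclasses.asdict(self), indent=indent, default=default)

    def write(self, path):
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "ReportDocument":
        payload = json.loads(text)
        return cls(**payload)

    @classmethod
    def read(cls, path) -> "ReportDocument":
        return cls.from_json(Path(path).read_text())
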