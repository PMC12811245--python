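"""Tabular I/O for the pipeline: ROI time series, phenotypes, results, and the DMN partition.

File conventions
----------------
* ROI time series: tab-delimited text, header row of ROI labels, T rows of
  floats (one row per volume).
* Phenotypes: RFC-4180 CSV with one row per subject; missing values are
  empty cells.
* Result tables: JSON (scalar summaries) or CSV (tidy tables).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DmnPartition",
    "RoiTimeSeries",
    "SubjectRecord",
    "default_partition",
    "load_partition",
    "read_timeseries",
    "write_timeseries",
    "read_phenotypes",
    "write_phenotypes",
    "write_results",
]

SUBCOMPONENTS = ("mPFC", "PCC", "LPC", "RPC")
#: ROI counts of the default DMN partition (33 regions total).
DEFAULT_PARTITION_SIZES = {"mPFC": 12, "PCC": 11, "LPC": 6, "RPC": 4}


@dataclass(frozen=True)
class DmnPartition:
    """Assignment of ROI columns to the four DMN subcomponents.

    The default partition has 33 ROIs: 12 medial prefrontal (mPFC),
    11 posterior cingulate (PCC), 6 left parietal (LPC) and 4 right
    parietal (RPC). Custom partitions may have any sizes but must be
    total (every ROI assigned) and disjoint (exactly one subcomponent
    per ROI) — guaranteed here by the mapping representation.
    """

    roi_labels: tuple[str, ...]
    subcomponent: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("duplicate ROI labels in partition")
        for label in self.roi_labels:
            comp = self.subcomponent.get(label)
            if comp is None:
                raise ValueError(f"ROI {label!r} has no subcomponent assignment")
            if comp not in SUBCOMPONENTS:
                raise ValueError(
                    f"ROI {label!r} assigned to unknown subcomponent {comp!r}; "
                    f"expected one of {SUBCOMPONENTS}"
                )
        extra = set(self.subcomponent) - set(self.roi_labels)
        if extra:
            raise ValueError(f"subcomponent map contains unknown ROIs: {sorted(extra)}")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    def members(self, component: str) -> list[str]:
        """ROI labels of one subcomponent, in column order."""
        if component not in SUBCOMPONENTS:
            raise ValueError(f"unknown subcomponent {component!r}")
        return [r for r in self.roi_labels if self.subcomponent[r] == component]

    def indices(self, component: str) -> np.ndarray:
        """Column indices of one subcomponent."""
        members = set(self.members(component))
        return np.array([i for i, r in enumerate(self.roi_labels) if r in members])

    def sizes(self) -> dict[str, int]:
        return {c: len(self.members(c)) for c in SUBCOMPONENTS}


def load_partition(path: str | Path, *, enforce_default_sizes: bool = False) -> DmnPartition:
    """Load a partition from a two-column TSV (roi_label, subcomponent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"roi_label", "subcomponent"}
    if not required.issubset(df.columns):
        raise ValueError(f"partition file must have columns {sorted(required)}")
    part = DmnPartition(
        roi_labels=tuple(df["roi_label"]),
        subcomponent=dict(zip(df["roi_label"], df["subcomponent"])),
    )
    if enforce_default_sizes and part.sizes() != DEFAULT_PARTITION_SIZES:
        raise ValueError(
            f"default partition must have sizes {DEFAULT_PARTITION_SIZES}, got {part.sizes()}"
        )
    return part


def default_partition() -> DmnPartition:
    """The packaged 33-ROI DMN partition (12 mPFC, 11 PCC, 6 LPC, 4 RPC)."""
    with resources.as_file(resources.files("dmnec.data") / "dmn_partition.tsv") as p:
        return load_partition(p, enforce_default_sizes=True)


@dataclass
class RoiTimeSeries:
    """One subject's T×N matrix of ROI signals.

    ``diff_order_applied`` records, per ROI, how many times the series was
    differenced by the stationarity screen (0 for raw data).
    """

    values: np.ndarray
    roi_labels: tuple[str, ...]
    diff_order_applied: np.ndarray | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time-series values must be a T×N matrix")
        t, n = self.values.shape
        if n != len(self.roi_labels):
            raise ValueError(
                f"{n} columns but {len(self.roi_labels)} ROI labels"
            )
        if t < 50:
            raise ValueError(f"need at least 50 timepoints, got {t}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at row {bad[0]}, column {bad[1]}")
        self.roi_labels = tuple(self.roi_labels)
        if self.diff_order_applied is None:
            self.diff_order_applied = np.zeros(n, dtype=int)
        else:
            self.diff_order_applied = np.asarray(self.diff_order_applied, dtype=int)
            if self.diff_order_applied.shape != (n,):
                raise ValueError("diff_order_applied must have one entry per ROI")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    def check_labels(self, partition: DmnPartition) -> None:
        if self.roi_labels != partition.roi_labels:
            raise ValueError(
                "ROI labels do not match partition: "
                f"{self.roi_labels[:3]}... vs {partition.roi_labels[:3]}..."
            )


_DIAGNOSES = {"MDD", "NC"}
_EPISODES = {"FEDN", "recurrent", "unknown"}
_ARMS = {"medication", "rTMS", "none"}


@dataclass
class SubjectRecord:
    """One phenotype row.

    Missing values are ``None`` (written as empty CSV cells). HAMD-17 scores
    and illness duration must be nonnegative when present.
    """

    subject_id: str
    site: str
    diagnosis: str = "MDD"
    episode: str = "unknown"
    medication_on: bool | None = None
    illness_duration_months: float | None = None
    age: float | None = None
    sex: int | None = None
    education: float | None = None
    motion: float | None = None
    hamd_pre: float | None = None
    hamd_post: float | None = None
    treatment_arm: str = "none"
    mean_ec_mpfc_pcc: float | None = None

    def __post_init__(self) -> None:
        if not self.site:
            raise ValueError(f"subject {self.subject_id!r}: site must be nonempty")
        if self.diagnosis not in _DIAGNOSES:
            raise ValueError(f"subject {self.subject_id!r}: diagnosis {self.diagnosis!r}")
        if self.episode not in _EPISODES:
            raise ValueError(f"subject {self.subject_id!r}: episode {self.episode!r}")
        if self.treatment_arm not in _ARMS:
            raise ValueError(f"subject {self.subject_id!r}: treatment_arm {self.treatment_arm!r}")
        for name in ("hamd_pre", "hamd_post", "illness_duration_months"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"subject {self.subject_id!r}: {name} must be ≥ 0, got {v}")

    def to_row(self) -> dict:
        d = asdict(self)
        if self.medication_on is not None:
            d["medication_on"] = int(self.medication_on)
        return d


_PHENO_COLUMNS = [
    "subject_id", "site", "diagnosis", "episode", "medication_on",
    "illness_duration_months", "age", "sex", "education", "motion",
    "hamd_pre", "hamd_post", "treatment_arm", "mean_ec_mpfc_pcc",
]


def read_timeseries(path: str | Path, subject_id: str | None = None) -> RoiTimeSeries:
    """Read a tab-delimited T×N time-series file with an ROI-label header.

    Raises with the offending row/column named on ragged rows or
    non-numeric cells.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        rows = []
        for i, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}: ragged row {i} ({len(row)} cells, expected {len(header)})"
                )
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                bad = next(j for j, c in enumerate(row) if not _is_float(c))
                raise ValueError(
                    f"{path}: non-numeric cell at row {i}, column {header[bad]!r}"
                ) from None
    return RoiTimeSeries(np.array(rows), tuple(header),
                         subject_id=subject_id or path.stem)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write a time series as TSV; round-trips through :func:`read_timeseries`
    losslessly (repr-precision floats)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(ts.roi_labels)
        for row in ts.values:
            w.writerow([repr(float(v)) for v in row])


def read_phenotypes(path: str | Path) -> list[SubjectRecord]:
    """Read a phenotype CSV into validated records.

    Duplicate subject ids and malformed values raise with the row named.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id(s): {sorted(set(dup))}")
    records = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in _PHENO_COLUMNS:
            if col not in df.columns:
                continue
            v = row[col]
            if isinstance(v, float) and math.isnan(v):
                v = None
            kwargs[col] = v
        if kwargs.get("medication_on") is not None:
            kwargs["medication_on"] = bool(int(kwargs["medication_on"]))
        if kwargs.get("sex") is not None:
            kwargs["sex"] = int(kwargs["sex"])
        try:
            records.append(SubjectRecord(**kwargs))
        except (ValueError, TypeError) as e:
            raise ValueError(f"phenotype row {i + 2}: {e}") from e
    return records


def write_phenotypes(records: Sequence[SubjectRecord], path: str | Path) -> None:
    pd.DataFrame([r.to_row() for r in records], columns=_PHENO_COLUMNS).to_csv(
        path, index=False
    )


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Phenotype records as a DataFrame (missing → NaN)."""
    return pd.DataFrame([r.to_row() for r in records], columns=_PHENO_COLUMNS)


def write_results(tables: Mapping[str, object], path: str | Path) -> None:
    """Write a mapping of named result tables/scalars to JSON.

    DataFrames are stored as records; numpy scalars/arrays are converted.
    """
    def _convert(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {k: _convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_convert(v) for v in obj]
        return obj

    with open(path, "w") as fh:
        json.dump(_convert(dict(tables)), fh, indent=2, allow_nan=True)
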