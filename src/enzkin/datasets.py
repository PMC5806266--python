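"""Tabular containers and the delimited-text dialects they serialize to.

All containers are thin, validated wrappers around :class:`pandas.DataFrame`.
The on-disk dialect is comma-separated with a header row and dot decimals;
ground-truth parameters from the simulators travel in a ``key = value``
sidecar file next to the data.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .exceptions import EmptyInputError, SchemaError

RATE_COLUMNS = [
    "substrate_name", "substrate_conc_mM", "pH", "temperature_C",
    "enzyme_conc_nM", "replicate", "velocity",
]

PROFILE_COLUMNS = ["x_name", "x", "replicate", "value"]

RESIDUAL_COLUMNS = ["preincubation_temp_C", "residual_activity"]


def _require_columns(frame: pd.DataFrame, columns, what: str):
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


@dataclass
class RateDataset:
    """Replicated initial-velocity observations with assay conditions.

    Columns: substrate_name (text), substrate_conc_mM, pH, temperature_C,
    enzyme_conc_nM (active enzyme), replicate (int), velocity (M s^-1).
    """

    frame: pd.DataFrame
    ground_truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        _require_columns(self.frame, RATE_COLUMNS, "RateDataset")
        f = self.frame
        bad = f.index[f["substrate_conc_mM"] < 0]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise SchemaError(
                f"RateDataset: negative substrate_conc_mM at data line(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        bad = f.index[f["enzyme_conc_nM"] <= 0]
        if len(bad):
            raise SchemaError(
                f"RateDataset: non-positive enzyme_conc_nM at data line(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        import numpy as np
        if len(f) and not np.isfinite(f["velocity"].to_numpy(float)).all():
            raise SchemaError("RateDataset: non-finite velocity values")

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, RateDataset) and self.frame.equals(other.frame)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, columns=RATE_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "RateDataset":
        frame = _read_table(path, RATE_COLUMNS, "RateDataset")
        return cls(frame)


@dataclass
class ProfileDataset:
    """A kinetic parameter profiled against one condition (pH or temperature).

    ``x_name`` is 'pH' or 'temperature_C'; ``value`` carries kcat/Km or kcat
    observations (one row per replicate per grid point).
    """

    frame: pd.DataFrame
    parameter_kind: str = "kcatKm"  # kcatKm | kcat
    pH: Optional[float] = None      # assay pH for temperature profiles
    ground_truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        _require_columns(self.frame, PROFILE_COLUMNS, "ProfileDataset")

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return (
            isinstance(other, ProfileDataset)
            and self.frame.equals(other.frame)
            and self.parameter_kind == other.parameter_kind
        )

    @property
    def x(self):
        return self.frame["x"].to_numpy(float)

    @property
    def values(self):
        return self.frame["value"].to_numpy(float)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, columns=PROFILE_COLUMNS)

    @classmethod
    def from_csv(cls, path, parameter_kind="kcatKm", pH=None) -> "ProfileDataset":
        frame = _read_table(path, PROFILE_COLUMNS, "ProfileDataset")
        return cls(frame, parameter_kind=parameter_kind, pH=pH)


@dataclass
class ResidualActivityTable:
    """Residual activity after 30-min preincubation, assayed at 40 degC.

    ``residual_activity`` is a fraction of the unheated maximum; values up to
    1.05 are tolerated to allow small noise overshoot.
    """

    frame: pd.DataFrame
    ground_truth: Optional[dict] = field(default=None, compare=False)

    def __post_init__(self):
        _require_columns(self.frame, RESIDUAL_COLUMNS, "ResidualActivityTable")
        r = self.frame["residual_activity"]
        if len(self.frame) and ((r < 0) | (r > 1.05)).any():
            raise SchemaError(
                "ResidualActivityTable: residual_activity outside [0, 1.05]"
            )

    def __len__(self):
        return len(self.frame)

    def __eq__(self, other):
        return isinstance(other, ResidualActivityTable) and self.frame.equals(other.frame)

    def to_csv(self, path):
        self.frame.to_csv(path, index=False, columns=RESIDUAL_COLUMNS)

    @classmethod
    def from_csv(cls, path) -> "ResidualActivityTable":
        frame = _read_table(path, RESIDUAL_COLUMNS, "ResidualActivityTable")
        return cls(frame)


def _read_table(path, columns, what) -> pd.DataFrame:
    """Read one of the delimited-text dialects with schema validation.

    Malformed numeric cells are rejected with their 1-based file line number.
    A header-only file yields an empty frame with a warning, not an error.
    """
    try:
        frame = pd.read_csv(path, dtype={c: str for c in columns})
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{what}: file {path!r} has no header row")
    _require_columns(frame, columns, what)
    if len(frame) == 0:
        warnings.warn(f"{what}: {path!r} contains a header but no data rows")
        return pd.DataFrame(columns=columns)
    numeric = [c for c in columns if c not in ("substrate_name", "x_name")]
    out = frame.copy()
    for col in numeric:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[converted.isna() & frame[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{what}: non-numeric value in column {col!r} at data line(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        if converted.isna().any():
            bad = frame.index[converted.isna()]
            raise SchemaError(
                f"{what}: missing value in column {col!r} at data line(s) "
                f"{[int(i) + 2 for i in bad]}"
            )
        out[col] = converted
    if "replicate" in out.columns:
        out["replicate"] = out["replicate"].astype(int)
    return out[columns]


def write_ground_truth(truth: dict, path):
    """Serialize a ground-truth parameter dict as ``key = value`` lines."""
    with open(path, "w") as fh:
        for key in sorted(truth):
            fh.write(f"{key} = {truth[key]!r}\n")


def read_ground_truth(path) -> dict:
    import ast

    truth = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            truth[key.strip()] = ast.literal_eval(value.strip())
    return truth


def dataset_checksum(dataset) -> str:
    """Stable content hash of a dataset's serialized form."""
    import hashlib

    buf = io.StringIO()
    dataset.frame.to_csv(buf, index=False)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
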