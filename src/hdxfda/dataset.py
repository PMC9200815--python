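"""Data model for centroided HDX-MS measurements.

Hydrogen-deuterium exchange mass spectrometry (HDX-MS) reports, for each
peptide, an isotope envelope at a series of exposure times to heavy water.
The envelope is routinely summarised by its intensity-weighted centroid; the
quantity modelled downstream is the neutral centroid mass

    M(t) = mean(m/z) * z - z

where ``z`` is the precursor charge.  This module holds the in-memory
containers (:class:`IsotopeSpectrum`, :class:`Measurement`,
:class:`HDXDataset`), the centroid arithmetic, and readers/writers for the
canonical long CSV layout and a vendor-style "state data" CSV dialect.

All exposure times are stored internally in seconds.  Missing observations
are kept explicitly (value = NaN) and dropped at fit time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical long-format columns, in deterministic order.
LONG_COLUMNS = [
    "analyte_sequence",
    "start",
    "end",
    "charge",
    "condition",
    "replicate",
    "exposure_s",
    "value",
    "value_kind",
]


class EmptySpectrumError(ValueError):
    """Raised when a spectrum carries no signal (all intensities zero)."""


class DatasetValidationError(ValueError):
    """Raised when a table of measurements violates the dataset contract."""


@dataclass(frozen=True)
class IsotopeSpectrum:
    """An isotope envelope: m/z values, intensities and precursor charge.

    Invariants: equal-length arrays, strictly increasing m/z, at least one
    strictly positive intensity, integer charge >= 1.
    """

    mz: np.ndarray
    intensity: np.ndarray
    charge: int

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.size != inten.size:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if mz.size == 0:
            raise ValueError("spectrum must contain at least one peak")
        if np.any(np.diff(mz) <= 0):
            raise ValueError("mz values must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        if not (isinstance(self.charge, (int, np.integer)) and self.charge >= 1):
            raise ValueError("charge must be a positive integer")


def compute_centroid_mass(spectrum: IsotopeSpectrum) -> float:
    """Neutral centroid mass of an isotope envelope.

    Computes the intensity-weighted mean m/z and converts it to a neutral
    mass scale: ``centroid = (sum(mz * I) / sum(I)) * z - z``.  Scaling all
    intensities by a positive constant leaves the result unchanged.

    Raises
    ------
    EmptySpectrumError
        If every intensity is zero.
    """
    total = float(np.sum(spectrum.intensity))
    if total <= 0.0:
        raise EmptySpectrumError("empty spectrum: all intensities are zero")
    mean_mz = float(np.dot(spectrum.mz, spectrum.intensity)) / total
    z = spectrum.charge
    return mean_mz * z - z


@dataclass(frozen=True)
class Measurement:
    """A single centroided observation y_icr(t).

    ``analyte_id`` identifies a (sequence, start, end, charge) tuple; charge
    states are treated as separate analytes because their envelopes are
    centroided independently.
    """

    sequence: str
    start: int
    end: int
    charge: int
    condition: str
    replicate: str
    exposure_s: float
    value: float
    value_kind: str = "centroid_mass"

    @property
    def analyte_id(self) -> str:
        return make_analyte_id(self.sequence, self.start, self.end, self.charge)

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.value)


def make_analyte_id(sequence: str, start: int, end: int, charge: int) -> str:
    return f"{sequence}[{start}-{end}]_{charge}"


class HDXDataset:
    """A validated collection of HDX-MS measurements in long format.

    Parameters
    ----------
    table : pandas.DataFrame
        Long-format table with the columns in :data:`LONG_COLUMNS`
        (``value_kind`` optional, default ``"centroid_mass"``).  NaN values
        encode explicit missing observations.

    Attributes
    ----------
    table : pandas.DataFrame
        The validated long table, with an ``analyte_id`` column appended.
    conditions : list of str
        Ordered condition labels (first-appearance order).
    times : numpy.ndarray
        Sorted unique exposure times in seconds.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = _validate_long_table(table)
        self.conditions: list[str] = list(
            pd.unique(self.table["condition"].astype(str))
        )
        self.times: np.ndarray = np.sort(self.table["exposure_s"].unique())

    # -- basic introspection -------------------------------------------------

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def analyte_ids(self) -> list[str]:
        return list(pd.unique(self.table["analyte_id"]))

    @property
    def n_analytes(self) -> int:
        return len(self.analyte_ids)

    def analyte_table(self, analyte_id: str, drop_missing: bool = True) -> pd.DataFrame:
        """Rows for one analyte, optionally without missing observations."""
        sub = self.table[self.table["analyte_id"] == analyte_id]
        if drop_missing:
            sub = sub[np.isfinite(sub["value"].to_numpy(dtype=float))]
        return sub

    def annotations(self) -> pd.DataFrame:
        """One row per analyte: sequence, residue span and charge."""
        cols = ["analyte_id", "analyte_sequence", "start", "end", "charge"]
        return (
            self.table[cols]
            .drop_duplicates("analyte_id")
            .reset_index(drop=True)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"HDXDataset(n_analytes={self.n_analytes}, "
            f"conditions={self.conditions}, m={len(self.times)})"
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HDXDataset):
            return NotImplemented
        a = self.table.sort_values(LONG_COLUMNS[:7]).reset_index(drop=True)
        b = other.table.sort_values(LONG_COLUMNS[:7]).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            x, y = a[col], b[col]
            if x.dtype.kind == "f":
                ok = np.all((x.to_numpy() == y.to_numpy()) | (x.isna() & y.isna()))
            else:
                ok = x.equals(y)
            if not ok:
                return False
        return True


def _validate_long_table(table: pd.DataFrame) -> pd.DataFrame:
    df = table.copy()
    if "value_kind" not in df.columns:
        df["value_kind"] = "centroid_mass"
    missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing_cols:
        raise DatasetValidationError(f"missing required columns: {missing_cols}")
    df = df[LONG_COLUMNS].copy()
    for col, dtype in [("start", int), ("end", int), ("charge", int)]:
        df[col] = df[col].astype(dtype)
    df["exposure_s"] = df["exposure_s"].astype(float)
    df["value"] = df["value"].astype(float)
    df["condition"] = df["condition"].astype(str)
    df["replicate"] = df["replicate"].astype(str)
    df["analyte_sequence"] = df["analyte_sequence"].astype(str)

    if len(df) == 0:
        raise DatasetValidationError("dataset contains no measurements")
    if (df["exposure_s"] < 0).any():
        bad = df.loc[df["exposure_s"] < 0, "exposure_s"].unique()
        raise DatasetValidationError(f"negative exposure times: {bad}")
    if (df["start"] > df["end"]).any():
        raise DatasetValidationError("analyte start residue exceeds end residue")
    if df["condition"].nunique() < 1:
        raise DatasetValidationError("dataset must declare at least one condition")

    df["analyte_id"] = [
        make_analyte_id(s, a, b, z)
        for s, a, b, z in zip(df["analyte_sequence"], df["start"], df["end"], df["charge"])
    ]
    key_cols = ["analyte_id", "condition", "replicate", "exposure_s"]
    dup_mask = df.duplicated(key_cols, keep=False)
    if dup_mask.any():
        dups = df.loc[dup_mask, key_cols].drop_duplicates().to_dict("records")
        raise DatasetValidationError(
            f"duplicated (analyte, condition, replicate, time) rows: {dups}"
        )
    return df.reset_index(drop=True)


# -- readers / writers -------------------------------------------------------


def read_long_csv(path, column_map: Mapping[str, str] | None = None) -> HDXDataset:
    """Read the canonical long CSV into an :class:`HDXDataset`.

    ``column_map`` maps canonical names to the file's column names, e.g.
    ``{"condition": "State"}``.  Rows whose value field is empty become
    explicit missing observations.  Non-numeric exposure entries raise an
    error naming the offending line.
    """
    raw = pd.read_csv(path)
    if column_map:
        raw = raw.rename(columns={v: k for k, v in column_map.items()})
    missing = [c for c in LONG_COLUMNS[:8] if c not in raw.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    exposure = pd.to_numeric(raw["exposure_s"], errors="coerce")
    bad = exposure.isna() & raw["exposure_s"].notna()
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in raw.index[bad]]
        raise DatasetValidationError(f"non-numeric exposure values at lines {lines}")
    raw["exposure_s"] = exposure
    raw["value"] = pd.to_numeric(raw["value"], errors="coerce")
    return HDXDataset(raw)


def write_long_csv(dataset: HDXDataset, path) -> None:
    """Write a dataset back to the canonical long CSV (round-trip exact)."""
    dataset.table[LONG_COLUMNS].to_csv(path, index=False)


_STATE_REQUIRED = ["Sequence", "Start", "End", "State", "Exposure"]


def read_state_csv(path, exposure_unit: str = "min") -> HDXDataset:
    """Read a vendor-style state-data CSV export.

    Expected columns: ``Protein, Sequence, Start, End, State, Exposure,
    Charge`` and either ``Center`` (centroid m/z; converted to neutral mass
    via the charge) or ``Uptake`` (deuterium uptake in Da).  The ``State``
    column maps to the condition label.  Vendor exports commonly give
    exposure in minutes; ``exposure_unit`` ("min" or "s") selects the
    conversion to the internal seconds scale.

    A ``Replicate`` column is honoured if present; otherwise replicate
    numbers are assigned by order of appearance within each
    (analyte, state, exposure) cell.
    """
    raw = pd.read_csv(path)
    missing = [c for c in _STATE_REQUIRED if c not in raw.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    if "Center" not in raw.columns and "Uptake" not in raw.columns:
        raise DatasetValidationError(
            "state data must contain a 'Center' or an 'Uptake' column"
        )
    known = set(
        _STATE_REQUIRED
        + ["Protein", "Charge", "Center", "Uptake", "Replicate", "MaxUptake"]
    )
    extra = [c for c in raw.columns if c not in known]
    if extra:
        logger.warning("ignoring unrecognised state-data columns: %s", extra)

    if exposure_unit not in ("min", "s"):
        raise ValueError("exposure_unit must be 'min' or 's'")
    scale = 60.0 if exposure_unit == "min" else 1.0

    charge = raw["Charge"] if "Charge" in raw.columns else pd.Series(1, index=raw.index)
    charge = pd.to_numeric(charge, errors="coerce").fillna(1).astype(int)
    if "Center" in raw.columns:
        value = pd.to_numeric(raw["Center"], errors="coerce") * charge - charge
        kind = "centroid_mass"
    else:
        value = pd.to_numeric(raw["Uptake"], errors="coerce")
        kind = "uptake"

    df = pd.DataFrame(
        {
            "analyte_sequence": raw["Sequence"].astype(str),
            "start": raw["Start"].astype(int),
            "end": raw["End"].astype(int),
            "charge": charge,
            "condition": raw["State"].astype(str),
            "exposure_s": pd.to_numeric(raw["Exposure"], errors="raise") * scale,
            "value": value,
            "value_kind": kind,
        }
    )
    if "Replicate" in raw.columns:
        df["replicate"] = raw["Replicate"].astype(str)
    else:
        key = [df["analyte_sequence"], df["start"], df["end"], df["charge"],
               df["condition"], df["exposure_s"]]
        df["replicate"] = (
            df.groupby([k.to_numpy() for k in key]).cumcount() + 1
        ).astype(str)
    return HDXDataset(df)


def to_uptake(dataset: HDXDataset, reference_mass: Mapping[str, float]) -> HDXDataset:
    """Optional per-analyte uptake transform: value - undeuterated mass.

    ``reference_mass`` maps analyte_id to its undeuterated (reference)
    centroid mass.  Off by default in every pipeline; the kinetic model's
    offset parameter ``d`` absorbs the undeuterated mass instead.
    """
    df = dataset.table.copy()
    ref = df["analyte_id"].map(reference_mass)
    if ref.isna().any():
        bad = sorted(df.loc[ref.isna(), "analyte_id"].unique())
        raise DatasetValidationError(f"no reference mass for analytes: {bad}")
    df["value"] = df["value"] - ref
    df["value_kind"] = "uptake"
    return HDXDataset(df.drop(columns=["analyte_id"]))


def write_results_csv(results: pd.DataFrame, path) -> None:
    """Write a test-result or effect table with a deterministic column order."""
    preferred = [
        "analyte_id", "rss0", "rss1", "d1", "d2", "s2", "s2_moderated",
        "F", "F_moderated", "p_value", "p_adjusted", "status",
        "effect", "t_star", "estimate", "confL", "confU", "level",
    ]
    cols = [c for c in preferred if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, index=False)


def read_results_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
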