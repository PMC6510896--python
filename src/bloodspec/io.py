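"""Reading, writing, validating and reshaping ATR-FTIR spectral datasets.

A :class:`SpectralDataset` couples a shared wavenumber axis (cm^-1, stored
ascending), an ``(n_spectra, n_wavenumbers)`` absorbance matrix and one
:class:`SampleMeta` record per row.  Two on-disk layouts are supported:

* ``wide_table`` — one CSV, metadata columns first (fixed order), then one
  column per wavenumber;
* ``per_spectrum_files`` — a directory of two-column (wavenumber,
  absorbance) text files plus a ``manifest.csv`` mapping filenames to
  metadata.

Files written with a descending axis (the usual spectroscopic display
convention) are flipped to ascending on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    AxisError,
    DuplicateRecordError,
    FormatError,
    RegionError,
)

GROUPS = ("HC", "CVID")
SUBGROUPS = ("none_assigned", "complication_free", "complications")
BIOFLUIDS = ("serum", "plasma")

#: metadata columns, in the canonical on-disk order
META_COLUMNS = ("subject_id", "group", "subgroup", "biofluid", "spot", "replicate")

#: named wavenumber regions (closed intervals, cm^-1)
REGIONS = {"fingerprint": (900.0, 1800.0), "high": (2800.0, 3700.0)}

_AXIS_RTOL = 1e-6


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one acquired spectrum.

    ``spot`` (1..2) and ``replicate`` (1..10) index the acquisition point;
    the sentinel ``spot = replicate = 0`` marks a subject-averaged spectrum.
    """

    subject_id: str
    group: str
    subgroup: str = "none_assigned"
    biofluid: str = "serum"
    spot: int = 1
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise FormatError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.subgroup not in SUBGROUPS:
            raise FormatError(
                f"unknown subgroup {self.subgroup!r}; expected one of {SUBGROUPS}"
            )
        if self.biofluid not in BIOFLUIDS:
            raise FormatError(
                f"unknown biofluid {self.biofluid!r}; expected one of {BIOFLUIDS}"
            )
        if self.subgroup != "none_assigned" and self.group != "CVID":
            raise FormatError(
                f"subgroup {self.subgroup!r} is only valid for CVID subjects"
            )

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.biofluid, self.spot, self.replicate)


@dataclass
class Spectrum:
    """One spectrum: ascending wavenumber axis + absorbance values."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.shape != self.absorbance.shape:
            raise FormatError("wavenumbers and absorbance must have equal length")
        validate_axis(self.wavenumbers)
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance contains non-finite values")


def validate_axis(axis: np.ndarray) -> None:
    """Check the axis is strictly increasing with uniform spacing."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1:
        raise AxisError("axis must be one-dimensional")
    if axis.size >= 2:
        d = np.diff(axis)
        if np.any(d <= 0):
            raise AxisError("wavenumber axis must be strictly increasing")
        step = d.mean()
        if np.max(np.abs(d - step)) > _AXIS_RTOL * abs(step):
            raise AxisError(
                "wavenumber axis spacing is non-uniform beyond relative "
                f"tolerance {_AXIS_RTOL}"
            )


@dataclass
class SpectralDataset:
    """A set of spectra sharing one wavenumber axis."""

    axis: np.ndarray
    matrix: np.ndarray
    records: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            self.matrix = self.matrix.reshape(len(self.records), self.axis.size)
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        validate_axis(self.axis)
        if self.matrix.shape[1] != self.axis.size:
            raise FormatError(
                f"matrix has {self.matrix.shape[1]} columns but axis has "
                f"{self.axis.size} points"
            )
        if self.matrix.shape[0] != len(self.records):
            raise FormatError(
                f"matrix has {self.matrix.shape[0]} rows but there are "
                f"{len(self.records)} records"
            )
        if self.matrix.size and not np.all(np.isfinite(self.matrix)):
            raise FormatError("absorbance matrix contains non-finite values")
        seen: set[tuple] = set()
        for rec in self.records:
            if rec.key in seen:
                raise DuplicateRecordError(f"duplicate record {rec.key}")
            seen.add(rec.key)

    # ------------------------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.axis, self.matrix[i], self.records[i])

    def __iter__(self):
        return (self.spectrum(i) for i in range(self.n_spectra))

    def subjects(self) -> list[str]:
        """Subject ids in first-appearance order."""
        out: list[str] = []
        for rec in self.records:
            if rec.subject_id not in out:
                out.append(rec.subject_id)
        return out

    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])

    def subset(self, mask: np.ndarray) -> "SpectralDataset":
        """Select rows by boolean mask or integer index array (order kept)."""
        arr = np.asarray(mask)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return SpectralDataset(
            self.axis.copy(),
            self.matrix[idx].copy(),
            [self.records[i] for i in idx],
        )

    def with_matrix(self, matrix: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.axis.copy(), np.asarray(matrix, float), list(self.records))


# ----------------------------------------------------------------------
# on-disk formats
# ----------------------------------------------------------------------

def _format_wavenumber(w: float) -> str:
    s = f"{w:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def _records_from_frame(df: pd.DataFrame) -> list[SampleMeta]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleMeta(
                subject_id=str(row.subject_id),
                group=str(row.group),
                subgroup=str(row.subgroup),
                biofluid=str(row.biofluid),
                spot=int(row.spot),
                replicate=int(row.replicate),
            )
        )
    return records


def _read_wide(path: Path) -> SpectralDataset:
    # round_trip parsing: bit-exact read-back of repr-formatted absorbances
    df = pd.read_csv(path, float_precision="round_trip")
    for col in META_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing metadata column {col!r} in {path}")
    wn_cols = [c for c in df.columns if c not in META_COLUMNS]
    try:
        axis = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"unparseable wavenumber column in {path}: {exc}") from exc
    matrix = df[wn_cols].to_numpy(dtype=float) if wn_cols else np.zeros((len(df), 0))
    if axis.size >= 2 and axis[0] > axis[-1]:
        axis = axis[::-1].copy()
        matrix = matrix[:, ::-1].copy()
    records = _records_from_frame(df[list(META_COLUMNS)])
    return SpectralDataset(axis, matrix, records)


def _write_wide(ds: SpectralDataset, path: Path) -> None:
    meta = pd.DataFrame(
        [(r.subject_id, r.group, r.subgroup, r.biofluid, r.spot, r.replicate) for r in ds.records],
        columns=list(META_COLUMNS),
    )
    data = pd.DataFrame(ds.matrix, columns=[_format_wavenumber(w) for w in ds.axis])
    pd.concat([meta, data], axis=1).to_csv(path, index=False)


def _sniff_two_column(fn: Path) -> np.ndarray:
    with open(fn) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    arr = np.loadtxt(fn, delimiter=delim, ndmin=2)
    if arr.shape[1] != 2:
        raise FormatError(f"{fn} is not a two-column (wavenumber, absorbance) file")
    return arr


def _read_per_spectrum(path: Path) -> SpectralDataset:
    manifest = path / "manifest.csv"
    if not manifest.exists():
        raise FormatError(f"missing manifest.csv in {path}")
    mdf = pd.read_csv(manifest)
    if "filename" not in mdf.columns:
        raise FormatError("manifest must have a 'filename' column")
    for col in META_COLUMNS:
        if col not in mdf.columns:
            raise FormatError(f"missing metadata column {col!r} in manifest")
    axis = None
    rows = []
    for fn in mdf["filename"]:
        arr = _sniff_two_column(path / str(fn))
        if arr.shape[0] >= 2 and arr[0, 0] > arr[-1, 0]:
            arr = arr[::-1]
        if axis is None:
            axis = arr[:, 0].copy()
        elif arr.shape[0] != axis.size or not np.allclose(arr[:, 0], axis, rtol=1e-9, atol=0):
            raise AxisError(f"{fn} axis differs from the shared dataset axis")
        rows.append(arr[:, 1])
    if axis is None:
        raise FormatError("manifest lists no spectra")
    records = _records_from_frame(mdf[list(META_COLUMNS)])
    return SpectralDataset(axis, np.vstack(rows), records)


def _write_per_spectrum(ds: SpectralDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    filenames = []
    for i in range(ds.n_spectra):
        fn = f"spectrum_{i:05d}.txt"
        np.savetxt(path / fn, np.column_stack([ds.axis, ds.matrix[i]]), fmt="%.17g")
        filenames.append(fn)
    meta = pd.DataFrame(
        [
            (fn, r.subject_id, r.group, r.subgroup, r.biofluid, r.spot, r.replicate)
            for fn, r in zip(filenames, ds.records)
        ],
        columns=["filename", *META_COLUMNS],
    )
    meta.to_csv(path / "manifest.csv", index=False)


def read_dataset(path: str | os.PathLike, format: str = "wide_table") -> SpectralDataset:
    """Read a :class:`SpectralDataset` from disk.

    Parameters
    ----------
    path
        CSV file (``wide_table``) or directory (``per_spectrum_files``).
    format
        ``"wide_table"`` or ``"per_spectrum_files"``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    if format == "wide_table":
        return _read_wide(p)
    if format == "per_spectrum_files":
        return _read_per_spectrum(p)
    raise FormatError(f"unknown dataset format {format!r}")


def write_dataset(ds: SpectralDataset, path: str | os.PathLike, format: str = "wide_table") -> None:
    """Write a dataset; ``read_dataset`` round-trips the result exactly."""
    p = Path(path)
    if format == "wide_table":
        _write_wide(ds, p)
    elif format == "per_spectrum_files":
        _write_per_spectrum(ds, p)
    else:
        raise FormatError(f"unknown dataset format {format!r}")


# ----------------------------------------------------------------------
# reshaping
# ----------------------------------------------------------------------

def average_replicates(ds: SpectralDataset) -> SpectralDataset:
    """Average all replicate spectra of each (subject, biofluid).

    Returns one spectrum per subject per biofluid — the arithmetic mean over
    that subject's replicates at each wavenumber.  Output records carry the
    ``spot = replicate = 0`` sentinel, so the operation is idempotent.
    """
    order: list[tuple] = []
    groups: dict[tuple, list[int]] = {}
    for i, rec in enumerate(ds.records):
        k = (rec.subject_id, rec.biofluid)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)
    rows = []
    records = []
    for k in order:
        idx = groups[k]
        first = ds.records[idx[0]]
        for i in idx[1:]:
            r = ds.records[i]
            if (r.group, r.subgroup) != (first.group, first.subgroup):
                raise FormatError(
                    f"inconsistent group/subgroup for subject {first.subject_id!r}"
                )
        rows.append(ds.matrix[idx].mean(axis=0))
        records.append(replace(first, spot=0, replicate=0))
    matrix = np.vstack(rows) if rows else np.zeros((0, ds.axis.size))
    return SpectralDataset(ds.axis.copy(), matrix, records)


def select_region(
    ds: SpectralDataset,
    region: str | tuple[float, float] | Sequence[float],
) -> SpectralDataset:
    """Restrict the dataset to a closed wavenumber interval.

    ``region`` is ``"fingerprint"`` (900–1800 cm^-1), ``"high"``
    (2800–3700 cm^-1) or an explicit ``(low, high)`` pair; both endpoints
    are included.
    """
    if isinstance(region, str):
        try:
            lo, hi = REGIONS[region]
        except KeyError:
            raise RegionError(f"unknown region {region!r}") from None
    else:
        lo, hi = float(region[0]), float(region[1])
        if lo > hi:
            lo, hi = hi, lo
    step = np.diff(ds.axis).mean() if ds.axis.size >= 2 else 1.0
    tol = 1e-9 * abs(step)
    mask = (ds.axis >= lo - tol) & (ds.axis <= hi + tol)
    if not mask.any():
        raise RegionError(f"region [{lo}, {hi}] does not intersect the axis")
    return SpectralDataset(ds.axis[mask].copy(), ds.matrix[:, mask].copy(), list(ds.records))


def concat_datasets(parts: Iterable[SpectralDataset]) -> SpectralDataset:
    """Stack datasets that share one axis into a single dataset."""
    parts = list(parts)
    if not parts:
        raise FormatError("no datasets to concatenate")
    axis = parts[0].axis
    for p in parts[1:]:
        if p.axis.size != axis.size or not np.allclose(p.axis, axis, rtol=1e-9, atol=0):
            raise AxisError("datasets do not share one wavenumber axis")
    matrix = np.vstack([p.matrix for p in parts])
    records = [r for p in parts for r in p.records]
    return SpectralDataset(axis.copy(), matrix, records)
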