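"""Spectra and metadata I/O.

A :class:`SpectraSet` holds an intensity matrix (rows = individual SORS
measurements) aligned to a shared wavenumber axis (Raman shift, cm^-1),
plus one metadata record per row.  On disk the pair is two CSV files:

* spectra table — wide format, header ``measurement_id`` followed by the
  wavenumbers, one measurement per row;
* metadata table — columns ``measurement_id, sample_id, honey_type, role,
  adulterant, level_pct, replicate, spatial_offset_mm``.

Values are serialised with full ``repr`` precision so a write/read
round-trip is numerically exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROLES = ("honey", "syrup", "sugar_standard", "blank")
ADULTERANTS = ("none", "rice", "sugar_beet", "sugar_cane")

META_COLUMNS = (
    "measurement_id",
    "sample_id",
    "honey_type",
    "role",
    "adulterant",
    "level_pct",
    "replicate",
    "spatial_offset_mm",
)


class SpectraFormatError(ValueError):
    """Malformed spectra/metadata file or inconsistent container."""


class AxisError(SpectraFormatError):
    """Wavenumber axis violates its invariants."""


class KeyedJoinError(SpectraFormatError):
    """Measurement ids of spectra and metadata do not match 1:1."""


def validate_axis(values: np.ndarray) -> np.ndarray:
    """Validate a wavenumber axis: finite, strictly increasing, >= 2 points."""
    axis = np.asarray(values, dtype=float)
    if axis.ndim != 1 or axis.size < 2:
        raise AxisError(f"axis must be 1-D with at least 2 points, got shape {axis.shape}")
    if not np.all(np.isfinite(axis)):
        raise AxisError("axis contains non-finite values")
    if not np.all(np.diff(axis) > 0):
        raise AxisError("axis must be strictly increasing")
    return axis


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate the per-measurement metadata table."""
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise SpectraFormatError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    bad_role = set(meta["role"]) - set(ROLES)
    if bad_role:
        raise SpectraFormatError(f"unknown roles: {sorted(bad_role)}")
    bad_adu = set(meta["adulterant"]) - set(ADULTERANTS)
    if bad_adu:
        raise SpectraFormatError(f"unknown adulterants: {sorted(bad_adu)}")
    levels = meta["level_pct"].to_numpy(dtype=float)
    if np.any((levels < 0) | (levels > 100)):
        raise SpectraFormatError("level_pct outside [0, 100]")
    honeys = meta["role"] == "honey"
    pure = meta["adulterant"] == "none"
    mismatch = honeys & (pure != (levels == 0))
    if mismatch.any():
        ids = meta.loc[mismatch, "measurement_id"].tolist()
        raise SpectraFormatError(
            f"honey rows must have adulterant == none iff level_pct == 0; violated by {ids}"
        )
    dup = meta.duplicated(subset=["sample_id", "replicate"])
    if dup.any():
        ids = meta.loc[dup, "measurement_id"].tolist()
        raise SpectraFormatError(f"duplicate replicate index within sample_id for {ids}")
    return meta


@dataclass
class SpectraSet:
    """Aligned intensity matrix + wavenumber axis + per-row metadata."""

    axis: np.ndarray
    intensities: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.axis = validate_axis(self.axis)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise SpectraFormatError("intensities must be a 2-D matrix")
        if self.intensities.shape[1] != self.axis.size:
            raise SpectraFormatError(
                f"intensity columns ({self.intensities.shape[1]}) != axis length ({self.axis.size})"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise SpectraFormatError("intensities contain non-finite values")
        self.meta = validate_meta(self.meta).reset_index(drop=True)
        if len(self.meta) != self.intensities.shape[0]:
            raise SpectraFormatError(
                f"meta rows ({len(self.meta)}) != intensity rows ({self.intensities.shape[0]})"
            )

    @property
    def n_measurements(self) -> int:
        return self.intensities.shape[0]

    def copy(self) -> "SpectraSet":
        return SpectraSet(self.axis.copy(), self.intensities.copy(), self.meta.copy())

    def select(self, mask: Sequence[bool]) -> "SpectraSet":
        """Row subset by boolean mask, keeping axis untouched."""
        mask = np.asarray(mask, dtype=bool)
        return SpectraSet(self.axis, self.intensities[mask], self.meta.loc[mask])


def read_spectra_table(spectra_path, meta_path) -> SpectraSet:
    """Read a spectra/metadata CSV pair into a validated :class:`SpectraSet`.

    The spectra header must be ``measurement_id`` followed by numeric
    wavenumbers.  A descending axis is accepted and reversed (with its
    columns) under a logged notice; ids must match the metadata 1:1.
    """
    spectra = pd.read_csv(spectra_path, float_precision="round_trip")
    if spectra.columns[0] != "measurement_id":
        raise SpectraFormatError(
            f"first spectra column must be 'measurement_id', got {spectra.columns[0]!r}"
        )
    try:
        axis = np.array([float(c) for c in spectra.columns[1:]])
    except ValueError as exc:
        raise SpectraFormatError(f"non-numeric wavenumber header: {exc}") from exc
    intensities = spectra.iloc[:, 1:].to_numpy(dtype=float)
    if axis.size >= 2 and np.all(np.diff(axis) < 0):
        logger.info("descending wavenumber axis in %s; reversing", spectra_path)
        axis = axis[::-1].copy()
        intensities = intensities[:, ::-1].copy()

    meta = pd.read_csv(meta_path)
    ids = spectra["measurement_id"].astype(str)
    meta_ids = meta["measurement_id"].astype(str)
    if ids.duplicated().any() or meta_ids.duplicated().any():
        raise KeyedJoinError("duplicate measurement_id")
    if set(ids) != set(meta_ids):
        only_spec = sorted(set(ids) - set(meta_ids))
        only_meta = sorted(set(meta_ids) - set(ids))
        raise KeyedJoinError(
            f"ids do not match 1:1 (spectra-only: {only_spec[:5]}, meta-only: {only_meta[:5]})"
        )
    meta = meta.set_index(meta_ids.values).loc[ids.values].reset_index(drop=True)
    meta["measurement_id"] = meta["measurement_id"].astype(str)
    return SpectraSet(axis, intensities, meta)


def write_spectra_table(sset: SpectraSet, spectra_path, meta_path) -> None:
    """Write the CSV pair that :func:`read_spectra_table` accepts (lossless)."""
    spectra_path, meta_path = Path(spectra_path), Path(meta_path)
    cols = [repr(float(v)) for v in sset.axis]
    df = pd.DataFrame(sset.intensities, columns=cols)
    df.insert(0, "measurement_id", sset.meta["measurement_id"].values)
    df.to_csv(spectra_path, index=False)
    sset.meta.to_csv(meta_path, index=False)
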