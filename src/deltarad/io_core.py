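"""Volume and table I/O, run configuration, and seeded random-state plumbing.

Volumes (PET in SUV, CT in HU, binary lesion masks) are NIfTI files read with
nibabel; analysis happens in voxel space using the header voxel spacing.
Feature and outcome tables are plain CSV with the subject identifier as the
index column; missing values serialize as empty fields, never as sentinel
numbers.
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("deltarad")

TIMEPOINTS = ("baseline", "eot")


class GridMismatchError(ValueError):
    """PET, CT and mask volumes do not share a voxel grid."""


class EmptyROIError(ValueError):
    """The lesion mask contains no foreground voxel."""


class DuplicateFeatureError(ValueError):
    """A feature table contains a duplicated column name."""


@dataclass
class ScanPair:
    """One co-registered PET/CT/mask triplet for one subject at one time point."""

    subject_id: str
    timepoint: str
    pet: np.ndarray
    ct: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    scanner_id: str = ""

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}")
        if not (self.pet.shape == self.ct.shape == self.mask.shape):
            raise GridMismatchError(
                f"shape mismatch for subject {self.subject_id}: "
                f"pet {self.pet.shape}, ct {self.ct.shape}, mask {self.mask.shape}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive voxel spacing {self.spacing}")
        self.mask = (np.asarray(self.mask) > 0).astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def require_roi(self) -> None:
        if self.n_foreground == 0:
            raise EmptyROIError(f"empty mask for subject {self.subject_id} ({self.timepoint})")


@dataclass
class OutcomeRecord:
    """Binary progression label, time-to-progression and censoring status.

    ``event = 1`` means ``ttp_months`` is the observed progression time;
    ``event = 0`` means it is the censoring time.
    """

    subject_id: str
    progression: int
    ttp_months: float
    event: int
    scanner_id: str = ""
    deauville: int | None = None

    def __post_init__(self) -> None:
        if self.progression not in (0, 1):
            raise ValueError("progression must be 0 or 1")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.ttp_months < 0:
            raise ValueError("ttp_months must be >= 0")
        if self.deauville is not None and not 1 <= int(self.deauville) <= 5:
            raise ValueError("deauville must be in 1..5")


@dataclass
class RunConfig:
    """Flat run configuration; every stochastic stage derives its stream from ``seed``."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    discretization: dict = field(default_factory=dict)
    cv: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    smote_mode: str = "within_fold"
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: raw[k] for k in ("seed", "paths", "discretization", "cv", "models", "smote_mode") if k in raw}
        stages = {k: v for k, v in raw.items() if k not in known}
        return cls(stages=stages, **known)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage generator: the stage name is hashed into the stream."""
    digest = hashlib.sha256(stage.encode()).digest()
    salt = int.from_bytes(digest[:4], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


# ---------------------------------------------------------------------------
# NIfTI volumes


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(data: np.ndarray, spacing: Sequence[float], path: str | Path) -> None:
    affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))


def read_scan_pair(
    pet_path: str | Path,
    ct_path: str | Path,
    mask_path: str | Path,
    metadata: Mapping[str, str],
) -> ScanPair:
    """Load one PET/CT/mask triplet and validate grids; the mask is binarized."""
    pet, spacing = read_volume(pet_path)
    ct, ct_spacing = read_volume(ct_path)
    mask, _ = read_volume(mask_path)
    if pet.shape != ct.shape:
        raise GridMismatchError(f"CT grid {ct.shape} does not match PET grid {pet.shape}: {ct_path}")
    if pet.shape != mask.shape:
        raise GridMismatchError(f"mask grid {mask.shape} does not match PET grid {pet.shape}: {mask_path}")
    if not np.allclose(spacing, ct_spacing, rtol=1e-4):
        logger.warning("CT spacing %s differs from PET spacing %s; using PET spacing", ct_spacing, spacing)
    pair = ScanPair(
        subject_id=str(metadata.get("subject_id", "")),
        timepoint=str(metadata.get("timepoint", "baseline")),
        pet=pet,
        ct=ct,
        mask=mask,
        spacing=spacing,
        scanner_id=str(metadata.get("scanner_id", "")),
    )
    pair.require_roi()
    return pair


# ---------------------------------------------------------------------------
# Feature tables

#: float format preserving doubles exactly on CSV round-trip
_FLOAT_FMT = "%.17g"


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a subject x feature table as CSV; NaN cells become empty fields."""
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise DuplicateFeatureError(f"duplicate feature name(s): {dupes}")
    table.to_csv(path, float_format=_FLOAT_FMT, index_label="subject_id", na_rep="")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, index_col=0, float_precision="round_trip")
    table.index = table.index.astype(str)
    table.index.name = None  # the label is re-added on write
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise DuplicateFeatureError(f"duplicate feature name(s) in {path}: {dupes}")
    return table


def write_outcomes(records: Sequence[OutcomeRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "progression": r.progression,
                "ttp_months": r.ttp_months,
                "event": r.event,
                "scanner_id": r.scanner_id,
                "deauville": r.deauville,
            }
        )
    pd.DataFrame(rows).set_index("subject_id").to_csv(path, float_format=_FLOAT_FMT, na_rep="")


def read_outcomes(path: str | Path) -> list[OutcomeRecord]:
    df = pd.read_csv(path, index_col=0)
    out = []
    for sid, row in df.iterrows():
        dv = row.get("deauville")
        out.append(
            OutcomeRecord(
                subject_id=str(sid),
                progression=int(row["progression"]),
                ttp_months=float(row["ttp_months"]),
                event=int(row["event"]),
                scanner_id=str(row.get("scanner_id", "")),
                deauville=None if dv is None or (isinstance(dv, float) and np.isnan(dv)) else int(dv),
            )
        )
    return out


def table_checksum(table: pd.DataFrame) -> str:
    """SHA-256 of the canonical CSV serialization; used for provenance logging."""
    buf = io.StringIO()
    table.to_csv(buf, float_format=_FLOAT_FMT, na_rep="")
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()
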