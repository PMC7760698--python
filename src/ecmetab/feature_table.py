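"""Feature-table data model and CSV I/O.

The central object is :class:`FeatureTable`: a features x samples matrix of
non-negative peak areas with per-feature metadata (neutral mass, retention
time, analytical mode) and per-sample metadata (role, dose, experiment,
injection order, protocol). Every pipeline stage consumes and returns one.

Missing values are explicit: an empty CSV cell becomes NaN and stays NaN —
a zero peak area and an absent measurement are different things for the CV
and outlier rules, so missing values are never imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MODES",
    "ROLES",
    "Feature",
    "SampleInfo",
    "FeatureTable",
    "FormatError",
    "read_feature_table",
    "write_feature_table",
    "subset",
]

#: Analytical modes: chromatography (HILIC/RPLC) x ESI polarity.
MODES = ("HILIC+", "HILIC-", "RPLC+", "RPLC-")
ROLES = ("biological", "blank", "qc")

FEATURE_COLUMNS = ["feature_id", "neutral_mass", "rt", "mode"]
SAMPLE_COLUMNS = ["sample_id", "role", "dose_uM", "experiment_id",
                  "injection_order", "protocol"]


class FormatError(ValueError):
    """Raised when an input file violates the expected CSV layout."""


@dataclass(frozen=True)
class Feature:
    """One LC-MS feature: a unique (mass, RT) ion species in one mode."""

    feature_id: str
    neutral_mass: float  # Da, monoisotopic as reported by peak picking
    rt: float            # minutes
    mode: str            # one of MODES
    annotation: str | None = None
    msi_level: int | None = None

    def __post_init__(self) -> None:
        if not self.neutral_mass > 0:
            raise ValueError(f"{self.feature_id}: neutral_mass must be > 0")
        if self.rt < 0:
            raise ValueError(f"{self.feature_id}: rt must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"{self.feature_id}: unknown mode {self.mode!r}")
        if self.msi_level is not None and self.msi_level not in (1, 2, 3, 4):
            raise ValueError(f"{self.feature_id}: msi_level must be 1-4")


@dataclass(frozen=True)
class SampleInfo:
    """Acquisition metadata for one injected sample."""

    sample_id: str
    role: str                       # biological | blank | qc
    dose_uM: float | None = None    # only meaningful for biological samples
    experiment_id: str | None = None
    injection_order: int | None = None
    protocol: str | None = None     # sample-preparation protocol label

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.role == "blank" and self.dose_uM is not None:
            raise ValueError(f"{self.sample_id}: blank samples carry no dose")
        if self.dose_uM is not None and self.dose_uM < 0:
            raise ValueError(f"{self.sample_id}: dose must be >= 0")
        if self.injection_order is not None and self.injection_order < 1:
            raise ValueError(f"{self.sample_id}: injection_order must be >= 1")


class FeatureTable:
    """Peak-area matrix (features x samples) plus metadata.

    Parameters
    ----------
    features : DataFrame
        Indexed by ``feature_id`` with columns ``neutral_mass``, ``rt``,
        ``mode`` and optionally ``annotation``, ``msi_level``.
    samples : DataFrame
        Indexed by ``sample_id`` with columns ``role``, ``dose_uM``,
        ``experiment_id``, ``injection_order``, ``protocol``.
    abundance : DataFrame
        Shape (n_features, n_samples); NaN marks a missing value, present
        values must be >= 0.
    """

    def __init__(self, features: pd.DataFrame, samples: pd.DataFrame,
                 abundance: pd.DataFrame, validate: bool = True):
        self.features = features
        self.samples = samples
        self.abundance = abundance
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, features: Iterable[Feature],
                     samples: Iterable[SampleInfo],
                     abundance: np.ndarray | pd.DataFrame) -> "FeatureTable":
        feats = list(features)
        samps = list(samples)
        fdf = pd.DataFrame(
            {
                "neutral_mass": [f.neutral_mass for f in feats],
                "rt": [f.rt for f in feats],
                "mode": [f.mode for f in feats],
                "annotation": [f.annotation for f in feats],
                "msi_level": [f.msi_level for f in feats],
            },
            index=pd.Index([f.feature_id for f in feats], name="feature_id"),
        )
        sdf = pd.DataFrame(
            {
                "role": [s.role for s in samps],
                "dose_uM": [s.dose_uM for s in samps],
                "experiment_id": [s.experiment_id for s in samps],
                "injection_order": [s.injection_order for s in samps],
                "protocol": [s.protocol for s in samps],
            },
            index=pd.Index([s.sample_id for s in samps], name="sample_id"),
        )
        ab = pd.DataFrame(np.asarray(abundance, dtype=float),
                          index=fdf.index, columns=sdf.index)
        return cls(fdf, sdf, ab)

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        if self.features.index.has_duplicates:
            raise FormatError("duplicated feature_id")
        if self.samples.index.has_duplicates:
            raise FormatError("duplicated sample_id")
        if self.abundance.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"abundance shape {self.abundance.shape} does not match "
                f"({len(self.features)}, {len(self.samples)})")
        if not self.abundance.index.equals(self.features.index):
            raise ValueError("abundance rows misaligned with features")
        if not self.abundance.columns.equals(self.samples.index):
            raise ValueError("abundance columns misaligned with samples")
        vals = self.abundance.to_numpy(dtype=float)
        if np.any(vals[~np.isnan(vals)] < 0):
            raise ValueError("negative abundance values")
        bad_mode = set(self.features["mode"]) - set(MODES)
        if bad_mode:
            raise ValueError(f"unknown mode(s): {sorted(bad_mode)}")
        bad_role = set(self.samples["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"unknown role(s): {sorted(bad_role)}")

    # -- convenience ------------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_features, self.n_samples)

    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def sample_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["role"] == role])

    def modes_present(self) -> list[str]:
        return [m for m in MODES if (self.features["mode"] == m).any()]

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.samples.copy(),
                            self.abundance.copy(), validate=False)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        roles = self.samples["role"].value_counts().to_dict()
        return (f"<FeatureTable {self.n_features} features x "
                f"{self.n_samples} samples {roles}>")


# -- I/O -------------------------------------------------------------------

def read_feature_table(matrix_path: str | Path,
                       sample_sheet_path: str | Path) -> FeatureTable:
    """Read a feature matrix CSV plus its sample sheet into a FeatureTable.

    The matrix CSV carries the feature-metadata block
    ``feature_id, neutral_mass, rt, mode[, annotation, msi_level]`` followed
    by one column per sample. The sample sheet has one row per sample with
    ``sample_id, role, dose_uM, experiment_id, injection_order, protocol``.
    Columns and sheet rows are matched by ``sample_id``; order of the matrix
    columns is preserved.
    """
    mat = pd.read_csv(matrix_path, dtype={"feature_id": str})
    sheet = pd.read_csv(sample_sheet_path, dtype={"sample_id": str,
                                                  "protocol": str,
                                                  "experiment_id": str})
    missing = [c for c in FEATURE_COLUMNS if c not in mat.columns]
    if missing:
        raise FormatError(f"matrix missing columns {missing}")
    missing = [c for c in SAMPLE_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns {missing}")
    if sheet["sample_id"].duplicated().any():
        raise FormatError("duplicated sample_id in sample sheet")

    meta_cols = [c for c in mat.columns
                 if c in FEATURE_COLUMNS + ["annotation", "msi_level"]]
    sample_cols = [c for c in mat.columns if c not in meta_cols]
    sheet_ids = set(sheet["sample_id"])
    unknown = [c for c in sample_cols if c not in sheet_ids]
    if unknown:
        raise FormatError(f"matrix columns absent from sample sheet: {unknown}")

    fdf = mat[meta_cols].set_index("feature_id")
    if "annotation" not in fdf.columns:
        fdf["annotation"] = None
    if "msi_level" not in fdf.columns:
        fdf["msi_level"] = np.nan
    sdf = sheet.set_index("sample_id").loc[sample_cols]
    sdf = sdf[["role", "dose_uM", "experiment_id", "injection_order", "protocol"]]
    # blanks and QCs carry no dose: empty cells are fine, enforce the rule
    blank_dosed = sdf[(sdf["role"] == "blank") & sdf["dose_uM"].notna()]
    if len(blank_dosed):
        raise ValueError(
            f"blank samples carry no dose: {list(blank_dosed.index)}")
    ab = mat[sample_cols].astype(float)
    ab.index = fdf.index
    return FeatureTable(fdf, sdf, ab)


def write_feature_table(table: FeatureTable, matrix_path: str | Path,
                        sample_sheet_path: str | Path) -> None:
    """Write matrix + sample-sheet CSVs readable by :func:`read_feature_table`.

    Values are written with ``repr`` round-trip precision; missing values
    become empty cells.
    """
    mat = table.features.reset_index()
    mat = mat[[c for c in ["feature_id", "neutral_mass", "rt", "mode",
                           "annotation", "msi_level"] if c in mat.columns]]
    ab = table.abundance.reset_index(drop=True)
    out = pd.concat([mat, ab], axis=1)
    out.to_csv(matrix_path, index=False, float_format="%.17g")
    sheet = table.samples.reset_index()
    sheet.to_csv(sample_sheet_path, index=False, float_format="%.17g")


def subset(table: FeatureTable,
           sample_predicate: Callable[[pd.Series], bool] | None = None,
           feature_ids: Sequence[str] | None = None) -> FeatureTable:
    """Return a new FeatureTable restricted to selected samples/features.

    ``sample_predicate`` receives each sample's metadata row (a Series) and
    keeps the sample when it returns True; ``feature_ids`` keeps the listed
    features in the given order. Either may be None (keep all).
    """
    sdf = table.samples
    if sample_predicate is not None:
        keep = [sid for sid, row in sdf.iterrows() if sample_predicate(row)]
        sdf = sdf.loc[keep]
    fdf = table.features
    if feature_ids is not None:
        feature_ids = list(feature_ids)
        unknown = set(feature_ids) - set(fdf.index)
        if unknown:
            raise KeyError(f"unknown feature_id(s): {sorted(unknown)}")
        fdf = fdf.loc[feature_ids]
    ab = table.abundance.loc[fdf.index, sdf.index]
    return FeatureTable(fdf.copy(), sdf.copy(), ab.copy())
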