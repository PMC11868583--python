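"""Core data model: ROI schema, participant cohorts, CSV I/O, relative volumes.

A cohort is a thin wrapper around a :class:`pandas.DataFrame` with one row per
participant and a fixed column layout::

    id, age, sex, scanner, tiv, diagnosis, <roi columns...>, iqm_*, symptom_*

Volumes move through three feature kinds: ``raw`` (mm^3 as segmented),
``relative`` (divided by total intracranial volume) and ``harmonized``
(scanner effects removed). Transitions are one-way and guarded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("id", "age", "sex", "scanner", "tiv")
FEATURE_KINDS = ("raw", "relative", "harmonized")
SEX_CODES = {"F": 0, "M": 1}

REGION_GROUPS = (
    "frontal", "temporal", "parietal", "occipital", "insula", "cingulate",
    "subcortical", "cerebellum", "corpus callosum", "ventricles",
)


class SchemaError(ValueError):
    """A table or schema violates the expected column/region layout."""


@dataclass(frozen=True)
class RoiSchema:
    """An ordered set of brain regions with group and cortical annotations.

    Parameters
    ----------
    names
        Ordered, unique region identifiers; these are the ROI column names in
        cohort CSV files.
    group
        Map from region name to its high-level anatomical group (one of
        :data:`REGION_GROUPS`).
    cortical
        Map from region name to whether it belongs to the cortical
        parcellation (as opposed to the subcortical segmentation).
    """

    names: tuple[str, ...]
    group: Mapping[str, str]
    cortical: Mapping[str, bool]
    version: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SchemaError("ROI names must be unique")
        missing = [n for n in self.names if n not in self.group or n not in self.cortical]
        if missing:
            raise SchemaError(f"regions missing group/cortical annotation: {missing[:5]}")
        bad = sorted({g for g in self.group.values()} - set(REGION_GROUPS))
        if bad:
            raise SchemaError(f"unknown region groups: {bad}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_cortical(self) -> int:
        return sum(self.cortical[n] for n in self.names)

    def groups(self) -> dict[str, list[str]]:
        """Region names keyed by high-level group, in schema order."""
        out: dict[str, list[str]] = {}
        for name in self.names:
            out.setdefault(self.group[name], []).append(name)
        return out

    @classmethod
    def from_json(cls, path) -> "RoiSchema":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "RoiSchema":
        regions = payload["regions"]
        return cls(
            names=tuple(r["name"] for r in regions),
            group={r["name"]: r["group"] for r in regions},
            cortical={r["name"]: bool(r["cortical"]) for r in regions},
            version=str(payload.get("version", "custom")),
        )

    def to_json(self, path) -> None:
        payload = {
            "version": self.version,
            "regions": [
                {"name": n, "group": self.group[n], "cortical": self.cortical[n]}
                for n in self.names
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def default_schema() -> RoiSchema:
    """The shipped Desikan-Killiany + ASEG feature space (101 regions)."""
    ref = resources.files("neuronorm.data").joinpath("dk_aseg_101.json")
    payload = json.loads(ref.read_text())
    return RoiSchema._from_payload(payload)


@dataclass
class Cohort:
    """A participant table bound to an ROI schema.

    ``data`` holds one row per participant. ROI columns are named by
    ``schema.names``; image-quality metrics are prefixed ``iqm_`` and symptom
    scales ``symptom_``. Optional fields (diagnosis, symptoms) are nullable
    and never imputed.
    """

    schema: RoiSchema
    data: pd.DataFrame
    feature_kind: str = "raw"

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"cohort table missing required columns: {missing}")
        missing_roi = [n for n in self.schema.names if n not in self.data.columns]
        if missing_roi:
            raise SchemaError(
                f"cohort table missing {len(missing_roi)} ROI columns, "
                f"first: {missing_roi[:3]}"
            )
        ids = self.data["id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise SchemaError(f"duplicate participant ids: {dupes[:5]}")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def ids(self) -> pd.Series:
        return self.data["id"]

    @property
    def volumes(self) -> pd.DataFrame:
        """The n x k ROI feature block, columns in schema order."""
        return self.data.loc[:, list(self.schema.names)]

    @property
    def iqm_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("iqm_")]

    @property
    def symptom_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("symptom_")]

    def sex_codes(self) -> np.ndarray:
        """Sex as 0/1 integers (F=0, M=1)."""
        return self.data["sex"].map(SEX_CODES).to_numpy()

    def with_volumes(self, values: np.ndarray, feature_kind: str) -> "Cohort":
        """Return a copy with the ROI block replaced and the kind advanced."""
        order = [FEATURE_KINDS.index(self.feature_kind), FEATURE_KINDS.index(feature_kind)]
        if order[1] < order[0]:
            raise ValueError(
                f"feature_kind may only advance raw->relative->harmonized, "
                f"got {self.feature_kind}->{feature_kind}"
            )
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self), len(self.schema)):
            raise ValueError(f"expected shape {(len(self), len(self.schema))}, got {values.shape}")
        data = self.data.copy()
        data.loc[:, list(self.schema.names)] = values
        return Cohort(self.schema, data, feature_kind)

    def subset(self, mask) -> "Cohort":
        """Row subset preserving order; mask is boolean or an id iterable."""
        if isinstance(mask, (list, tuple, set, pd.Index)):
            keep = self.data["id"].isin(list(mask))
        else:
            keep = pd.Series(np.asarray(mask, dtype=bool), index=self.data.index)
        return Cohort(self.schema, self.data.loc[keep].copy(), self.feature_kind)


def read_cohort(path, schema: RoiSchema, feature_kind: str = "raw") -> Cohort:
    """Read a participant CSV into a :class:`Cohort`.

    The file must be RFC-4180 CSV with a header row, one row per participant,
    and at least the columns ``id, age, sex, scanner, tiv`` plus every ROI in
    ``schema``. Row order is preserved.
    """
    table = pd.read_csv(path, dtype={"id": str, "sex": str, "scanner": str},
                        float_precision="round_trip")
    if table.columns.duplicated().any():
        dupes = table.columns[table.columns.duplicated()].tolist()
        raise SchemaError(f"duplicate columns in {path}: {dupes}")
    numeric = ["age", "tiv", *schema.names,
               *[c for c in table.columns if c.startswith(("iqm_", "symptom_"))]]
    for col in numeric:
        if col not in table.columns:
            continue
        converted = pd.to_numeric(table[col], errors="coerce")
        bad = converted.isna() & table[col].notna()
        if bad.any():
            row = table.loc[bad, "id"].iloc[0] if "id" in table else bad.idxmax()
            raise ValueError(f"non-numeric value in column {col!r} for participant {row!r}")
        table[col] = converted
    if "diagnosis" not in table.columns:
        table["diagnosis"] = pd.NA
    bad_sex = ~table["sex"].isin(SEX_CODES)
    if bad_sex.any():
        raise SchemaError(f"sex must be F or M, got {table.loc[bad_sex, 'sex'].unique().tolist()}")
    vols = table.loc[:, [c for c in schema.names if c in table.columns]]
    if (vols.to_numpy() < 0).any():
        raise ValueError("negative ROI volumes are not allowed")
    return Cohort(schema, table, feature_kind)


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort back to CSV with full float precision (round-trip safe)."""
    lead = [c for c in ("id", "age", "sex", "scanner", "tiv", "diagnosis")
            if c in cohort.data.columns]
    roi = list(cohort.schema.names)
    rest = [c for c in cohort.data.columns if c not in lead + roi]
    cohort.data.loc[:, lead + roi + rest].to_csv(path, index=False, float_format="%.17g")


def compute_relative_volumes(cohort: Cohort) -> Cohort:
    """Divide every ROI volume by the participant's total intracranial volume.

    Relative volumes put participants with different head sizes on a common
    scale; all downstream modelling operates on them.
    """
    if cohort.feature_kind != "raw":
        raise ValueError(f"expected raw volumes, got feature_kind={cohort.feature_kind!r}")
    tiv = cohort.data["tiv"].to_numpy(dtype=float)
    if (tiv <= 0).any() or not np.isfinite(tiv).all():
        offender = cohort.data.loc[(tiv <= 0) | ~np.isfinite(tiv), "id"].iloc[0]
        raise ValueError(f"non-positive or non-finite tiv for participant {offender!r}")
    rel = cohort.volumes.to_numpy(dtype=float) / tiv[:, None]
    return cohort.with_volumes(rel, "relative")
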