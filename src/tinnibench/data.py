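"""Mixed-type patient table container and plain-text IO.

The central in-memory object is :class:`PatientTable`: a pandas DataFrame of
quantitative and categorical questionnaire features (NaN marks a missing
cell), a schema declaring each column's kind and admissible levels, and an
optional partial label column of endotype diagnoses.  Patients without a
diagnosis carry the sentinel :data:`NO_DIAGNOSIS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

#: Sentinel label for patients without an expert endotype diagnosis.
NO_DIAGNOSIS = "no diagnosis"

#: Name of the label column in serialized cohorts.
LABEL_COLUMN = "endotype"

QUANTITATIVE = "quantitative"
CATEGORICAL = "categorical"


@dataclass(frozen=True)
class ColumnSchema:
    """Kind and, for categorical columns, the declared levels."""

    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in (QUANTITATIVE, CATEGORICAL):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) == 0:
            raise ValueError("categorical column needs at least one level")


@dataclass
class PatientTable:
    """A patient-by-feature table with missingness and partial labels.

    Parameters
    ----------
    data:
        Feature matrix; index holds unique patient identifiers.  Missing
        cells are NaN (quantitative) or NaN/None (categorical).
    schema:
        Mapping column name -> :class:`ColumnSchema`, one entry per column
        of ``data``.
    labels:
        Optional per-patient endotype label aligned to ``data.index``;
        unlabeled patients hold :data:`NO_DIAGNOSIS`.  Never treated as a
        feature.
    """

    data: pd.DataFrame
    schema: dict[str, ColumnSchema]
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("patient identifiers must be unique")
        missing_schema = set(self.data.columns) - set(self.schema)
        if missing_schema:
            raise ValueError(f"columns without schema: {sorted(missing_schema)}")
        if self.labels is not None and not self.labels.index.equals(self.data.index):
            raise ValueError("labels must be aligned to the patient index")
        for name, col in self.schema.items():
            if name not in self.data.columns:
                continue
            if col.kind == CATEGORICAL:
                observed = self.data[name].dropna()
                bad = set(observed.unique()) - set(col.levels)
                if bad:
                    raise ValueError(
                        f"column {name!r} holds undeclared levels {sorted(bad)}"
                    )

    # -- derived views ---------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.data.index

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean matrix aligned to the features; True marks a missing cell."""
        return self.data.isna()

    @property
    def quantitative_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.schema[c].kind == QUANTITATIVE]

    @property
    def categorical_columns(self) -> list[str]:
        return [c for c in self.data.columns if self.schema[c].kind == CATEGORICAL]

    def subset(self, indices) -> "PatientTable":
        """Row subset by positional indices, preserving order."""
        data = self.data.iloc[np.asarray(indices)]
        labels = None if self.labels is None else self.labels.iloc[np.asarray(indices)]
        return PatientTable(data=data.copy(), schema=dict(self.schema), labels=labels)

    def copy(self) -> "PatientTable":
        labels = None if self.labels is None else self.labels.copy()
        return PatientTable(self.data.copy(), dict(self.schema), labels)

    # -- plain-text IO ---------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the cohort as CSV (empty string = missing, label column last)."""
        out = self.data.copy()
        if self.labels is not None:
            out[LABEL_COLUMN] = self.labels
        out.to_csv(path, index_label="patient_id", na_rep="")

    def write_schema(self, path) -> None:
        """Write the sidecar schema (YAML: column -> kind / levels)."""
        doc = {
            name: (
                {"kind": col.kind, "levels": list(col.levels)}
                if col.kind == CATEGORICAL
                else {"kind": col.kind}
            )
            for name, col in self.schema.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def read_schema(path) -> dict[str, ColumnSchema]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {
        name: ColumnSchema(
            kind=entry["kind"], levels=tuple(entry.get("levels", ()))
        )
        for name, entry in doc.items()
    }


def read_patient_table(csv_path, schema_path) -> PatientTable:
    """Read a cohort CSV plus its sidecar schema file."""
    schema = read_schema(schema_path)
    frame = pd.read_csv(csv_path, index_col="patient_id")
    labels = None
    if LABEL_COLUMN in frame.columns:
        labels = frame.pop(LABEL_COLUMN).fillna(NO_DIAGNOSIS)
    for name, col in schema.items():
        if name not in frame.columns:
            raise ValueError(f"schema column {name!r} absent from CSV")
        if col.kind == CATEGORICAL:
            frame[name] = frame[name].astype("object")
        else:
            frame[name] = pd.to_numeric(frame[name])
    return PatientTable(data=frame[list(schema)], schema=schema, labels=labels)
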