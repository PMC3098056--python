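"""Domain containers and delimited-text / graph serialization.

A peak table is cases x features: rows are individual spectra (replicate
spectra of one patient count as separate cases, optionally tied together by a
group id so cross-validation can keep them in one fold), columns are aligned
peaks identified by their m/z value in Daltons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SampleTable", "load_sample_table", "write_sample_table"]


@dataclass
class SampleTable:
    """Continuous peak abundances per case, with class labels.

    Attributes
    ----------
    case_ids : array of str
        Opaque per-row identifiers.
    class_labels : array of str
        Categorical label per case; at least two distinct values.
    feature_ids : array of float
        m/z value (Daltons) of each peak column; unique.
    abundances : ndarray, shape (n_cases, n_features)
        Peak intensities in arbitrary units; no missing values.
    groups : array or None
        Optional case-grouping id (e.g. patient of a replicate spectrum).
    """

    case_ids: np.ndarray
    class_labels: np.ndarray | None
    feature_ids: np.ndarray
    abundances: np.ndarray
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.case_ids = np.asarray(self.case_ids)
        self.feature_ids = np.asarray(self.feature_ids, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be 2-D (cases x features)")
        n, f = self.abundances.shape
        if self.class_labels is not None:
            self.class_labels = np.asarray(self.class_labels)
            if self.class_labels.shape != (n,):
                raise ValueError(
                    f"{self.class_labels.size} class labels for {n} abundance rows"
                )
        if self.case_ids.shape != (n,):
            raise ValueError(f"{self.case_ids.size} case ids for {n} abundance rows")
        if self.feature_ids.shape != (f,):
            raise ValueError(
                f"{self.feature_ids.size} feature ids for {f} abundance columns"
            )
        if np.unique(self.feature_ids).size != f:
            dupes = pd.Series(self.feature_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate feature ids: {dupes}")
        if self.class_labels is not None and np.unique(self.class_labels).size < 2:
            raise ValueError("class_labels must take at least 2 distinct values")
        if not np.isfinite(self.abundances).all():
            r, c = np.argwhere(~np.isfinite(self.abundances))[0]
            raise ValueError(
                f"non-finite abundance at row {r} (case {self.case_ids[r]}), "
                f"column {c} (feature {self.feature_ids[c]})"
            )
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != (n,):
                raise ValueError(f"{self.groups.size} group ids for {n} rows")

    @property
    def n_cases(self) -> int:
        return self.abundances.shape[0]

    @property
    def n_features(self) -> int:
        return self.abundances.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct class labels in first-seen (row) order."""
        if self.class_labels is None:
            raise ValueError("table carries no class labels")
        _, idx = np.unique(self.class_labels, return_index=True)
        return self.class_labels[np.sort(idx)]

    @property
    def class_codes(self) -> np.ndarray:
        """Integer coding of class_labels, first-seen order = 0, 1, ..."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[c] for c in self.class_labels], dtype=np.intp)

    def subset(self, rows: np.ndarray) -> "SampleTable":
        """New table restricted to the given row indices (order preserved)."""
        return SampleTable(
            case_ids=self.case_ids[rows],
            class_labels=None if self.class_labels is None else self.class_labels[rows],
            feature_ids=self.feature_ids,
            abundances=self.abundances[rows],
            groups=None if self.groups is None else self.groups[rows],
        )

    def to_frame(self, label_column: str = "class") -> pd.DataFrame:
        df = pd.DataFrame(
            self.abundances,
            columns=[repr(float(m)) for m in self.feature_ids],
            index=pd.Index(self.case_ids, name="case_id"),
        )
        if self.class_labels is not None:
            df.insert(0, label_column, self.class_labels)
        if self.groups is not None:
            df.insert(1, "group", self.groups)
        return df


def load_sample_table(
    path: str | Path,
    label_column: str | None = "class",
    delimiter: str = ",",
    group_column: str | None = None,
    impute: bool = False,
) -> SampleTable:
    """Read a peak table from delimited text.

    One header row; one label column (``label_column``; pass None for an
    unlabeled table); every remaining column must have a numeric (m/z) header
    and numeric cells.  Missing cells are rejected (with row/column
    coordinates) unless ``impute`` is set, in which case they are filled with
    the column median.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, float_precision="round_trip")
    if label_column is None:
        labels, feat = None, df
    else:
        if label_column not in df.columns:
            raise ValueError(
                f"label column {label_column!r} not found in {path} "
                f"(columns: {list(df.columns)[:5]}...)"
            )
        labels = df[label_column].astype(str).to_numpy()
        feat = df.drop(columns=[label_column])
    groups = None
    if group_column is not None:
        if group_column not in feat.columns:
            raise ValueError(f"group column {group_column!r} not found in {path}")
        groups = feat[group_column].to_numpy()
        feat = feat.drop(columns=[group_column])
    try:
        feature_ids = np.array([float(c) for c in feat.columns])
    except ValueError as exc:
        bad = [c for c in feat.columns if not _is_number(c)]
        raise ValueError(f"non-numeric feature (m/z) headers in {path}: {bad}") from exc
    values = feat.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad_cells = np.argwhere(np.isnan(values))
    if bad_cells.size:
        if impute:
            med = np.nanmedian(values, axis=0)
            values[np.isnan(values)] = np.take(med, bad_cells[:, 1])
        else:
            r, c = bad_cells[0]
            raise ValueError(
                f"missing or non-numeric abundance in {path} at row "
                f"{df.index[r]!r} (row {r}), feature column {feat.columns[c]!r}"
            )
    return SampleTable(
        case_ids=df.index.to_numpy().astype(str),
        class_labels=labels,
        feature_ids=feature_ids,
        abundances=values,
        groups=groups,
    )


def write_sample_table(
    table: SampleTable,
    path: str | Path,
    label_column: str = "class",
    delimiter: str = ",",
) -> None:
    """Write a peak table as delimited text, losslessly for float64 values."""
    df = table.to_frame(label_column=label_column)
    # shortest round-trip floats so a write -> load round trip is bit-identical
    df.to_csv(path, sep=delimiter, float_format=lambda x: repr(float(x)))


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False
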