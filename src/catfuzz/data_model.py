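"""Categorical datasets: ingestion, vocabularies, and mode imputation.

Category codes are opaque symbols (strings). Even when a file stores small
integers, they are never interpreted as ordered numbers: ``"10"`` is just
another symbol. Per-feature vocabularies are built from the observed
(non-missing) values and ordered lexicographically so that every downstream
index is reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Names of the nine cytological features of the UCI Wisconsin (Original)
#: breast-cancer dataset, in file order.
WBC_FEATURE_NAMES = (
    "clump_thickness",
    "uniformity_of_cell_size",
    "uniformity_of_cell_shape",
    "marginal_adhesion",
    "single_epithelial_cell_size",
    "bare_nuclei",
    "bland_chromatin",
    "normal_nucleoli",
    "mitoses",
)

WBC_CLASS_MAP = {"2": "benign", "4": "malignant"}


@dataclass(frozen=True)
class FeatureVocabulary:
    """The distinct category codes of one feature, in lexicographic order."""

    feature_index: int
    values: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError(f"feature {self.feature_index}: empty vocabulary")
        if len(set(self.values)) != len(self.values):
            raise ValueError(f"feature {self.feature_index}: duplicate values")

    @property
    def size(self) -> int:
        return len(self.values)

    def index(self, value: str) -> int:
        try:
            return self.values.index(value)
        except ValueError:
            raise KeyError(
                f"value {value!r} not in vocabulary of feature {self.feature_index}"
            ) from None


@dataclass(frozen=True)
class ImputationReport:
    """Summary of mode imputation: which features were touched and how."""

    per_feature_counts: dict[int, int] = field(default_factory=dict)
    per_feature_mode: dict[int, str] = field(default_factory=dict)
    total_imputed_records: int = 0

    @property
    def empty(self) -> bool:
        return self.total_imputed_records == 0


class CategoricalDataset:
    """An n x s table of category codes with per-feature vocabularies.

    Internally cells are stored as integer indices into each feature's
    vocabulary (``codes``), which keeps the clustering loops vectorised;
    ``cells()`` decodes back to symbols. At least two features are required
    because the co-occurrence distance of a feature is defined against the
    other features.
    """

    def __init__(
        self,
        codes: np.ndarray,
        vocabularies: list[FeatureVocabulary],
        labels: tuple[str, ...] | None = None,
        feature_names: tuple[str, ...] | None = None,
    ):
        codes = np.asarray(codes, dtype=np.intp)
        if codes.ndim != 2:
            raise ValueError("codes must be a 2-D array")
        n, s = codes.shape
        if s < 2:
            raise ValueError("at least two features are required (got s=%d)" % s)
        if len(vocabularies) != s:
            raise ValueError("one vocabulary per feature is required")
        for l, vocab in enumerate(vocabularies):
            col = codes[:, l]
            if col.min(initial=0) < 0 or (n > 0 and col.max() >= vocab.size):
                raise ValueError(f"feature {l}: code out of vocabulary range")
        if labels is not None and len(labels) != n:
            raise ValueError("labels length must equal the number of records")
        if feature_names is not None and len(feature_names) != s:
            raise ValueError("feature_names length must equal the number of features")
        self.codes = codes
        self.vocabularies = list(vocabularies)
        self.labels = tuple(labels) if labels is not None else None
        self.feature_names = (
            tuple(feature_names)
            if feature_names is not None
            else tuple(f"f{l}" for l in range(s))
        )

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def s(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_cells(
        cls,
        cells,
        labels=None,
        feature_names=None,
    ) -> "CategoricalDataset":
        """Build a dataset from a grid of symbols, deriving vocabularies.

        ``cells`` is any 2-D array-like of strings with no missing markers
        left in it (impute first; see :func:`impute_mode`).
        """
        grid = np.asarray(cells, dtype=object)
        if grid.ndim != 2:
            raise ValueError("cells must be a 2-D grid")
        n, s = grid.shape
        vocabularies = []
        codes = np.empty((n, s), dtype=np.intp)
        for l in range(s):
            col = [str(v) for v in grid[:, l]]
            values = tuple(sorted(set(col)))
            vocab = FeatureVocabulary(l, values)
            lookup = {v: k for k, v in enumerate(values)}
            codes[:, l] = [lookup[v] for v in col]
            vocabularies.append(vocab)
        return cls(codes, vocabularies, labels=labels, feature_names=feature_names)

    def cells(self) -> np.ndarray:
        """Decode the integer codes back to an object array of symbols."""
        out = np.empty(self.codes.shape, dtype=object)
        for l, vocab in enumerate(self.vocabularies):
            vals = np.asarray(vocab.values, dtype=object)
            out[:, l] = vals[self.codes[:, l]]
        return out

    def to_csv(self, path, label_column: str = "label") -> None:
        """Write the dataset (and labels, if any) as a headered CSV."""
        frame = pd.DataFrame(self.cells(), columns=list(self.feature_names))
        if self.labels is not None:
            frame[label_column] = list(self.labels)
        frame.to_csv(path, index=False)


def impute_mode(
    cells, missing_token: str = "?"
) -> tuple[np.ndarray, ImputationReport]:
    """Replace missing cells by their feature's most frequent observed value.

    Ties between equally frequent values are broken by lexicographic order.
    Raises if a feature has no observed value at all.
    """
    grid = np.asarray(cells, dtype=object).copy()
    if grid.ndim != 2:
        raise ValueError("cells must be a 2-D grid")
    n, s = grid.shape
    counts: dict[int, int] = {}
    modes: dict[int, str] = {}
    touched_records: set[int] = set()
    for l in range(s):
        col = np.array([str(v) for v in grid[:, l]], dtype=object)
        missing = col == missing_token
        if not missing.any():
            continue
        observed = col[~missing]
        if observed.size == 0:
            raise ValueError(f"feature {l}: all cells missing, mode undefined")
        values, freq = np.unique(observed, return_counts=True)
        # np.unique sorts lexicographically, argmax takes the first maximum:
        # exactly the tie-break rule.
        mode = str(values[np.argmax(freq)])
        grid[missing, l] = mode
        counts[l] = int(missing.sum())
        modes[l] = mode
        touched_records.update(np.nonzero(missing)[0].tolist())
    report = ImputationReport(
        per_feature_counts=counts,
        per_feature_mode=modes,
        total_imputed_records=len(touched_records),
    )
    return grid, report


def load_csv(
    path,
    label_column: str | None = None,
    missing_token: str = "?",
) -> tuple[CategoricalDataset, ImputationReport]:
    """Load a headered CSV of categorical columns.

    Every non-label column is treated as categorical symbols. Missing cells
    (``missing_token``) are mode-imputed before vocabularies are built, so no
    vocabulary ever contains the missing marker.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValueError(f"label column {label_column!r} not in header")
        labels = tuple(frame[label_column].astype(str))
        frame = frame.drop(columns=[label_column])
    cells, report = impute_mode(frame.to_numpy(dtype=object), missing_token)
    dataset = CategoricalDataset.from_cells(
        cells, labels=labels, feature_names=tuple(frame.columns)
    )
    return dataset, report


def load_wbc(path) -> tuple[CategoricalDataset, ImputationReport]:
    """Load a file in the UCI Wisconsin breast-cancer (Original) layout.

    Headerless, 11 comma-separated fields per line: a sample id (dropped),
    nine categorical features coded 1-10 with "?" for missing, and a class
    code 2 (benign) or 4 (malignant).
    """
    frame = pd.read_csv(path, header=None, dtype=str, keep_default_na=False)
    if frame.shape[1] != 11:
        raise ValueError(
            f"{path}: expected 11 columns in the Wisconsin layout, got {frame.shape[1]}"
        )
    class_codes = frame.iloc[:, 10].astype(str)
    bad = sorted(set(class_codes) - set(WBC_CLASS_MAP))
    if bad:
        raise ValueError(f"{path}: unknown class codes {bad}; expected 2 or 4")
    labels = tuple(WBC_CLASS_MAP[c] for c in class_codes)
    cells, report = impute_mode(
        frame.iloc[:, 1:10].to_numpy(dtype=object), missing_token="?"
    )
    dataset = CategoricalDataset.from_cells(
        cells, labels=labels, feature_names=WBC_FEATURE_NAMES
    )
    return dataset, report
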