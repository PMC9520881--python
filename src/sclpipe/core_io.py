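"""Data model, CSV readers/writers, and record-inclusion rules.

The universal input object is :class:`GroupedDataset`: a person x item
matrix of ordinal responses coded ``0..K-1``, a group label per person,
and optional positive survey weights.  Missing responses are stored as
the sentinel ``-1`` (an integer distinct from every valid category).

Two inclusion rules are provided:

* listwise deletion of respondents with any missing item
  (:func:`apply_completeness_filter`), and
* exclusion of entire groups in which a required item was never
  administered, i.e. is 100% missing within the group
  (:func:`validate_item_set`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GroupedDataset:
    """Ordinal response matrix with group labels and optional weights."""

    responses: np.ndarray          # (n, J) int, missing = -1
    item_names: list[str]
    group: np.ndarray              # (n,) str labels
    weights: np.ndarray | None = None   # (n,) positive floats; None = all 1.0
    n_categories: int | None = None     # K; inferred when None
    category_labels: dict | None = None # code -> original label, if recoded

    def __post_init__(self):
        self.responses = np.asarray(self.responses, dtype=int)
        if self.responses.ndim != 2:
            raise ValueError("responses must be a 2-D person x item matrix")
        n, j = self.responses.shape
        if len(self.item_names) != j:
            raise ValueError("item_names length must match number of columns")
        self.group = np.asarray(self.group)
        if self.group.shape != (n,):
            raise ValueError("group must have one label per row")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != (n,):
                raise ValueError("weights must have one entry per row")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")
        observed = self.responses[self.responses != MISSING]
        if observed.size and observed.min() < 0:
            raise ValueError("responses must be >= 0 or the missing sentinel -1")
        if self.n_categories is None:
            self.n_categories = int(observed.max()) + 1 if observed.size else 0
        elif observed.size and observed.max() >= self.n_categories:
            raise ValueError("response outside 0..K-1 for forced n_categories")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        _, idx = np.unique(self.group, return_index=True)
        return [str(self.group[i]) for i in sorted(idx)]

    def effective_weights(self) -> np.ndarray:
        return np.ones(self.n_persons) if self.weights is None else self.weights

    def subset(self, mask: np.ndarray) -> "GroupedDataset":
        return replace(
            self,
            responses=self.responses[mask],
            group=self.group[mask],
            weights=None if self.weights is None else self.weights[mask],
        )

    def group_data(self, label: str) -> "GroupedDataset":
        return self.subset(self.group == str(label))

    def to_frame(self, group_col: str = "group", weight_col: str = "weight") -> pd.DataFrame:
        df = pd.DataFrame(self.responses, columns=self.item_names)
        df = df.mask(df == MISSING)  # NaN for missing on output
        df.insert(0, group_col, self.group)
        if self.weights is not None:
            df[weight_col] = self.weights
        return df

    def to_csv(self, path, group_col: str = "group", weight_col: str = "weight") -> None:
        self.to_frame(group_col, weight_col).to_csv(path, index=False)


@dataclass
class InclusionReport:
    """Per-group record counts before/after a filter, with exclusions."""

    before: dict = field(default_factory=dict)   # group -> count
    after: dict = field(default_factory=dict)
    excluded_groups: dict = field(default_factory=dict)  # group -> reason

    def exclusion_percentage(self, group: str) -> float:
        b = self.before[group]
        return 100.0 * (b - self.after.get(group, 0)) / b if b else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, b in self.before.items():
            a = self.after.get(g, 0)
            rows.append({
                "group": g, "n_before": b, "n_after": a,
                "pct_excluded": round(self.exclusion_percentage(g), 3),
                "reason": self.excluded_groups.get(g, ""),
            })
        return pd.DataFrame(rows)

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False)


@dataclass
class ColumnSchema:
    """Mapping from CSV columns to the dataset fields."""

    group_col: str = "group"
    item_cols: list[str] | None = None   # None = every non-group/weight column
    weight_col: str | None = None
    # optional mapping from string labels to integer codes, e.g.
    # {"rarely or never": 0, ..., "about every day": 4}
    category_map: dict | None = None
    n_categories: int | None = None


def load_grouped_responses(path, schema: ColumnSchema | None = None) -> GroupedDataset:
    """Read a one-row-per-respondent CSV into a :class:`GroupedDataset`.

    Category labels are recoded to 0-based contiguous integer codes when
    ``schema.category_map`` is given; already-numeric columns are
    validated to be integers in ``0..K-1``.  Empty cells become missing.
    """
    schema = schema or ColumnSchema()
    df = pd.read_csv(path, dtype=object)
    if df.empty:
        raise ValueError("no records in CSV")
    if schema.group_col not in df.columns:
        raise ValueError(f"unknown group column {schema.group_col!r}")
    item_cols = schema.item_cols
    if item_cols is None:
        drop = {schema.group_col, schema.weight_col}
        item_cols = [c for c in df.columns if c not in drop]
    missing_cols = [c for c in item_cols if c not in df.columns]
    if missing_cols:
        raise ValueError(f"item columns not found: {missing_cols}")

    n = len(df)
    responses = np.full((n, len(item_cols)), MISSING, dtype=int)
    category_labels = None
    if schema.category_map is not None:
        category_labels = {v: k for k, v in schema.category_map.items()}
    for j, col in enumerate(item_cols):
        raw = df[col]
        for i, val in enumerate(raw):
            if val is None or (isinstance(val, float) and np.isnan(val)) or str(val).strip() == "":
                continue
            sval = str(val).strip()
            if schema.category_map is not None and sval in schema.category_map:
                responses[i, j] = int(schema.category_map[sval])
                continue
            try:
                fval = float(sval)
            except ValueError:
                raise ValueError(
                    f"non-integer category {val!r} at row {i}, column {col!r}"
                ) from None
            if fval != int(fval):
                raise ValueError(f"non-integer category {val!r} at row {i}, column {col!r}")
            responses[i, j] = int(fval)
    observed = responses[responses != MISSING]
    if observed.size == 0:
        raise ValueError("no records: all responses missing")
    if observed.min() < 0:
        i, j = np.argwhere((responses < 0) & (responses != MISSING))[0]
        raise ValueError(f"out-of-range category at row {i}, column {item_cols[j]!r}")
    k = schema.n_categories
    if k is not None and observed.max() >= k:
        i, j = np.argwhere(responses >= k)[0]
        raise ValueError(f"out-of-range category at row {i}, column {item_cols[j]!r}")

    weights = None
    if schema.weight_col is not None:
        weights = df[schema.weight_col].astype(float).to_numpy()
    return GroupedDataset(
        responses=responses,
        item_names=list(item_cols),
        group=df[schema.group_col].astype(str).to_numpy(),
        weights=weights,
        n_categories=k,
        category_labels=category_labels,
    )


def apply_completeness_filter(data: GroupedDataset) -> tuple[GroupedDataset, InclusionReport]:
    """Listwise deletion: keep only respondents with no missing item.

    Groups losing every row are removed entirely and listed in the
    report with the reason.  Idempotent.
    """
    complete = np.all(data.responses != MISSING, axis=1)
    report = InclusionReport()
    for g in data.groups:
        in_g = data.group == g
        report.before[g] = int(in_g.sum())
        report.after[g] = int((in_g & complete).sum())
        if report.after[g] == 0:
            report.excluded_groups[g] = "no complete records after listwise deletion"
    return data.subset(complete), report


def validate_item_set(data: GroupedDataset, required_items: list[str]) -> InclusionReport:
    """Flag groups in which a required item was never administered.

    A required item that is 100% missing within a group marks the group
    as excluded (the item was "not incorporated" there); partial item
    nonresponse is left to :func:`apply_completeness_filter`.
    """
    if not required_items:
        raise ValueError("required_items must be non-empty")
    idx = [data.item_names.index(it) for it in required_items]
    report = InclusionReport()
    for g in data.groups:
        rows = data.responses[data.group == g]
        report.before[g] = rows.shape[0]
        dead = [required_items[p] for p, j in enumerate(idx)
                if np.all(rows[:, j] == MISSING)]
        if dead:
            report.after[g] = 0
            report.excluded_groups[g] = f"items never administered: {', '.join(dead)}"
        else:
            report.after[g] = rows.shape[0]
    return report
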