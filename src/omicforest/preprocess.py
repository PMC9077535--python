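"""Design-matrix preprocessing: dummy encoding, variance and correlation
filters, centering/scaling, and complete-case filtering.

The filter semantics follow the classic caret contracts:

* near-zero variance: a predictor is flagged when the ratio of the most
  common to the second most common value exceeds ``freq_cut`` (strictly)
  AND the percentage of unique values is below ``unique_cut`` (strictly),
  or when it has a single unique value (zero variance);
* correlated-predictor removal: repeatedly take the pair with the highest
  absolute Pearson correlation above the cutoff and drop the member with
  the larger mean absolute correlation to the remaining predictors.

The pipeline order is fixed and part of the contract:
dummy encode -> NZV filter -> correlation filter -> center/scale ->
complete-case.  All statistics are learned on training rows only and
re-applied unchanged to test rows.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assemble import DesignMatrix

__all__ = [
    "NzvReport",
    "PreprocessState",
    "Preprocessor",
    "dummy_encode",
    "nzv_report",
    "drop_nzv",
    "correlation_matrix",
    "find_correlated",
    "center_scale",
    "drop_incomplete",
]


def dummy_encode(matrix: DesignMatrix) -> DesignMatrix:
    """Replace each categorical column with one 0/1 indicator per level.

    A column with a single observed level becomes one all-ones column,
    which the zero-variance filter removes downstream.
    """
    table = matrix.table
    manifest = dict(matrix.manifest)
    pieces, order = [], []
    for col in table.columns:
        if col in matrix.categorical:
            dummies = pd.get_dummies(table[col].astype(str), prefix=col,
                                     prefix_sep=".", dtype=float)
            cat = manifest.pop(col, "feature")
            for d in dummies.columns:
                manifest[d] = cat
            pieces.append(dummies)
            order.extend(dummies.columns)
        else:
            pieces.append(table[[col]])
            order.append(col)
    out = pd.concat(pieces, axis=1)[order]
    return DesignMatrix(table=out, manifest=manifest, categorical=[],
                        target=matrix.target)


@dataclass
class NzvReport:
    """Per-column variance diagnostics (freqRatio / percentUnique / flags)."""

    table: pd.DataFrame  # index: column; freqRatio, percentUnique, zeroVar, nzv
    freq_cut: float
    unique_cut: float

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["nzv"]])


def _column_nzv(values: pd.Series, freq_cut: float, unique_cut: float):
    x = values.dropna()
    n = len(x)
    if n == 0:
        return math.inf, 0.0, True, True
    counts = x.value_counts()
    n_unique = len(counts)
    if n_unique == 1:
        freq_ratio = math.inf
    else:
        freq_ratio = counts.iloc[0] / counts.iloc[1]
    percent_unique = 100.0 * n_unique / n
    zero_var = n_unique <= 1
    nzv = zero_var or (freq_ratio > freq_cut and percent_unique < unique_cut)
    return freq_ratio, percent_unique, zero_var, nzv


def nzv_report(matrix: DesignMatrix | pd.DataFrame, freq_cut: float = 95 / 5,
               unique_cut: float = 10.0) -> NzvReport:
    """Compute freqRatio and percentUnique for every predictor column.

    freqRatio = count(modal value) / count(second-most-common value)
    (infinite for a constant column); percentUnique = 100 * number of
    distinct values / number of non-missing rows.  Both cut comparisons
    are strict, so a 95:5 column (ratio exactly 19) is NOT flagged.
    """
    if isinstance(matrix, DesignMatrix):
        df = matrix.table[matrix.feature_columns]
    else:
        df = matrix
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError("cannot compute a variance report on an empty matrix")
    rows = {
        col: _column_nzv(df[col], freq_cut, unique_cut) for col in df.columns
    }
    table = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["freqRatio", "percentUnique", "zeroVar", "nzv"])
    table["zeroVar"] = table["zeroVar"].astype(bool)
    table["nzv"] = table["nzv"].astype(bool)
    return NzvReport(table=table, freq_cut=freq_cut, unique_cut=unique_cut)


def drop_nzv(matrix: DesignMatrix, report: NzvReport) -> DesignMatrix:
    """Remove the columns flagged by ``nzv_report``."""
    flagged = [c for c in report.flagged if c in matrix.table.columns]
    table = matrix.table.drop(columns=flagged)
    manifest = {c: v for c, v in matrix.manifest.items() if c not in flagged}
    return DesignMatrix(table=table, manifest=manifest,
                        categorical=[c for c in matrix.categorical
                                     if c not in flagged],
                        target=matrix.target)


def correlation_matrix(matrix: DesignMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations of the predictors (target excluded)."""
    if isinstance(matrix, DesignMatrix):
        df = matrix.table[matrix.feature_columns]
    else:
        df = matrix
    return df.corr(method="pearson")


def find_correlated(corr: pd.DataFrame, cutoff: float = 0.75) -> list[str]:
    """Greedy selection of predictors to drop so that no remaining pair has
    |r| > cutoff.

    At each step the highest-|r| offending pair is located; of the two, the
    column with the larger mean absolute correlation to all other remaining
    columns is dropped (ties drop the earlier column in manifest order).
    The target must have been excluded from ``corr`` beforehand.
    """
    if corr.shape[0] != corr.shape[1] or list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    arr = corr.to_numpy(dtype=float)
    if not np.allclose(arr, arr.T, atol=1e-10, equal_nan=True):
        raise ValueError("correlation matrix must be symmetric")
    if np.isnan(arr).any():
        bad = corr.columns[np.isnan(arr).any(axis=0)]
        raise ValueError(
            "correlation matrix contains missing entries (constant columns "
            f"must be removed first): {list(bad)[:5]}")

    names = list(corr.columns)
    a = np.abs(arr.copy())
    np.fill_diagonal(a, 0.0)
    active = list(range(len(names)))
    dropped: list[str] = []
    while len(active) > 1:
        sub = a[np.ix_(active, active)]
        flat = np.argmax(sub)
        i_loc, j_loc = divmod(flat, sub.shape[1])
        if sub[i_loc, j_loc] <= cutoff:
            break
        i, j = active[i_loc], active[j_loc]
        # mean |r| of each candidate against all other remaining columns
        mean_i = sub[i_loc].sum() / (len(active) - 1)
        mean_j = sub[j_loc].sum() / (len(active) - 1)
        if mean_i > mean_j:
            victim = i
        elif mean_j > mean_i:
            victim = j
        else:  # tie: drop the earlier column in manifest order
            victim = min(i, j)
        dropped.append(names[victim])
        active.remove(victim)
    return dropped


@dataclass
class PreprocessState:
    """The learned preprocessing transform, serializable to JSON."""

    dropped_nzv: list[str] = field(default_factory=list)
    dropped_correlated: list[str] = field(default_factory=list)
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)
    n_rows_dropped_incomplete: int = 0
    dummy_columns: list[str] = field(default_factory=list)

    def __post_init__(self):
        overlap = set(self.dropped_nzv) & set(self.dropped_correlated)
        if overlap:
            raise ValueError(f"columns dropped twice: {sorted(overlap)}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PreprocessState":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "PreprocessState":
        return cls.from_json(Path(path).read_text())


def center_scale(matrix: DesignMatrix, state: PreprocessState | None = None
                 ) -> tuple[DesignMatrix, PreprocessState]:
    """Center predictors to mean 0 and scale to sd 1 (sample sd, n-1).

    When ``state`` carries stored center/scale values they are re-applied
    unchanged (the test-set path); otherwise they are learned from this
    matrix and recorded.  The target column is left untouched.
    """
    table = matrix.table.copy()
    cols = matrix.feature_columns
    if state is None or not state.center:
        center = table[cols].mean()
        scale = table[cols].std(ddof=1)
        zero = scale[(scale == 0) | scale.isna()].index
        if len(zero):
            raise ValueError(
                f"zero-variance columns must be dropped before scaling: {list(zero)[:5]}")
        if state is None:
            state = PreprocessState()
        state.center = {c: float(center[c]) for c in cols}
        state.scale = {c: float(scale[c]) for c in cols}
    missing = [c for c in cols if c not in state.center]
    if missing:
        raise ValueError(f"no stored transform for columns: {missing[:5]}")
    for c in cols:
        table[c] = (table[c] - state.center[c]) / state.scale[c]
    return DesignMatrix(table=table, manifest=dict(matrix.manifest),
                        categorical=list(matrix.categorical),
                        target=matrix.target), state


def drop_incomplete(matrix: DesignMatrix, include_target: bool = True
                    ) -> tuple[DesignMatrix, int]:
    """Remove every row containing a missing value (complete-case rule).

    Returns the filtered matrix and the number of rows removed.  Raises if
    nothing survives, naming the worst columns.
    """
    cols = list(matrix.table.columns)
    if not include_target:
        cols = [c for c in cols if c != matrix.target]
    mask = matrix.table[cols].notna().all(axis=1)
    n_dropped = int((~mask).sum())
    if mask.sum() == 0:
        worst = matrix.table[cols].isna().sum().sort_values(ascending=False)
        raise ValueError(
            "complete-case filtering removed every row; worst columns: "
            f"{worst.head(5).to_dict()}")
    out = DesignMatrix(table=matrix.table.loc[mask], manifest=dict(matrix.manifest),
                       categorical=list(matrix.categorical), target=matrix.target)
    return out, n_dropped


class Preprocessor:
    """Fit the full preprocessing pipeline on training rows, apply anywhere.

    Order: dummy encode -> NZV filter -> correlation filter -> center/scale
    -> complete-case.  ``fit_transform`` learns every statistic from the
    training matrix; ``transform`` re-applies them to other rows without
    touching their statistics (leakage-free by construction).
    """

    def __init__(self, freq_cut: float = 95 / 5, unique_cut: float = 10.0,
                 corr_cutoff: float = 0.75):
        self.freq_cut = freq_cut
        self.unique_cut = unique_cut
        self.corr_cutoff = corr_cutoff
        self.state: PreprocessState | None = None

    def fit_transform(self, matrix: DesignMatrix) -> DesignMatrix:
        dm = dummy_encode(matrix)
        dummy_cols = [c for c in dm.table.columns if c not in matrix.table.columns]

        report = nzv_report(dm, self.freq_cut, self.unique_cut)
        dm = drop_nzv(dm, report)
        dropped_nzv = list(report.flagged)

        corr = correlation_matrix(dm)
        # columns rendered constant/empty on pairwise-complete rows: re-check
        degenerate = [c for c in corr.columns if corr[c].isna().any()]
        if degenerate:
            dm = DesignMatrix(table=dm.table.drop(columns=degenerate),
                              manifest={c: v for c, v in dm.manifest.items()
                                        if c not in degenerate},
                              categorical=dm.categorical, target=dm.target)
            dropped_nzv.extend(degenerate)
            corr = correlation_matrix(dm)
        dropped_corr = find_correlated(corr, self.corr_cutoff)
        dm = DesignMatrix(table=dm.table.drop(columns=dropped_corr),
                          manifest={c: v for c, v in dm.manifest.items()
                                    if c not in dropped_corr},
                          categorical=dm.categorical, target=dm.target)

        dm, state = center_scale(dm)
        state.dropped_nzv = dropped_nzv
        state.dropped_correlated = dropped_corr
        state.dummy_columns = dummy_cols
        dm, n_dropped = drop_incomplete(dm)
        state.n_rows_dropped_incomplete = n_dropped
        self.state = state
        return dm

    def transform(self, matrix: DesignMatrix) -> DesignMatrix:
        if self.state is None:
            raise ValueError("Preprocessor.transform called before fit_transform")
        dm = dummy_encode(matrix)
        dropped = set(self.state.dropped_nzv) | set(self.state.dropped_correlated)
        keep = [c for c in self.state.center] + [dm.target]
        # test rows may lack levels seen in training: add all-zero indicators
        table = dm.table
        for col in keep:
            if col not in table.columns:
                if col in self.state.dummy_columns:
                    table[col] = 0.0
                else:
                    raise ValueError(f"column {col} absent from matrix")
        table = table[[c for c in keep if c not in dropped]]
        dm = DesignMatrix(table=table,
                          manifest={c: dm.manifest.get(c, "feature")
                                    for c in table.columns if c != dm.target},
                          categorical=[], target=dm.target)
        dm, _ = center_scale(dm, self.state)
        dm, _ = drop_incomplete(dm)
        return dm
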