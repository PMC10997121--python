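"""Score-matrix data model, validation, subgroup aggregation and dispersion.

The central container is :class:`ScoreMatrix`: a labelled participants × items
grid of priority scores on a fixed scale ``[0, scale_max]``, in which a
missing entry (NaN) is an *abstention* — a deliberately withheld opinion,
distinct from a score of 0 ("no priority").  Rows may optionally carry a
subgroup label (e.g. a working group within a guideline panel), enabling the
subgroup-mean input mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScoreMatrix",
    "Violation",
    "ValidationReport",
    "ItemDispersion",
    "validate_scores",
    "aggregate_by_subgroup",
    "heterogeneity_stats",
    "dispersion_frame",
    "SubgroupMeanAggregator",
]


def _as_float(value):
    """Coerce a cell to float, returning None when it is not numeric."""
    if value is None:
        return np.nan
    if isinstance(value, (int, float, np.integer, np.floating)):
        return float(value)
    try:
        return float(str(value).strip())
    except (TypeError, ValueError):
        return None


@dataclass
class ScoreMatrix:
    """Participants × items grid of priority scores or abstentions.

    Parameters
    ----------
    scores : pandas.DataFrame
        Index = participant (or subgroup) labels, columns = item labels.
        NaN entries are abstentions.  The frame may hold non-numeric cells
        straight from a file; :func:`validate_scores` reports them and
        :attr:`values` refuses to run until they are fixed.
    scale_max : float
        The a-priori maximum scale score (K).  Scores are expected in
        ``[0, scale_max]``; violations are reported, not silently clipped.
    subgroups : mapping or pandas.Series, optional
        participant label → subgroup label.
    """

    scores: pd.DataFrame
    scale_max: float
    subgroups: pd.Series | None = None

    def __post_init__(self):
        if not isinstance(self.scores, pd.DataFrame):
            self.scores = pd.DataFrame(self.scores)
        if self.scores.shape[0] < 1 or self.scores.shape[1] < 1:
            raise ValueError("score matrix needs at least 1 participant and 1 item")
        if self.scores.index.has_duplicates:
            dupes = self.scores.index[self.scores.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate participant labels: {dupes}")
        if self.scores.columns.has_duplicates:
            dupes = self.scores.columns[self.scores.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate item labels: {dupes}")
        if not (self.scale_max > 0):
            raise ValueError("scale_max must be positive")
        self.scale_max = float(self.scale_max)
        if self.subgroups is not None and not isinstance(self.subgroups, pd.Series):
            self.subgroups = pd.Series(dict(self.subgroups))

    @property
    def participant_ids(self) -> list:
        return list(self.scores.index)

    @property
    def item_ids(self) -> list:
        return list(self.scores.columns)

    @property
    def n_participants(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def values(self) -> np.ndarray:
        """Float array of scores with NaN for abstentions.

        Raises ``ValueError`` if any cell is non-numeric; run
        :func:`validate_scores` first to locate such cells.
        """
        try:
            return self.scores.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise ValueError(
                "matrix contains non-numeric cells; run validate_scores() "
                f"to locate them ({exc})"
            ) from None

    def subgroup_of(self, participant) -> str | None:
        if self.subgroups is None:
            return None
        return self.subgroups.get(participant)


@dataclass(frozen=True)
class Violation:
    participant_id: object
    item_id: object
    value: object
    reason: str  # "negative" | "above_max" | "non_numeric"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        if self.is_valid:
            return "OK: all scores within range"
        lines = [f"{len(self.violations)} invalid cell(s):"]
        for v in self.violations:
            lines.append(
                f"  ({v.participant_id}, {v.item_id}): {v.value!r} [{v.reason}]"
            )
        return "\n".join(lines)


def validate_scores(matrix: ScoreMatrix) -> ValidationReport:
    """Check every cell against the allowed range ``[0, scale_max]``.

    Abstentions (empty cells) are never violations.  Out-of-range and
    non-numeric cells are reported with their coordinates; violations are
    data, not exceptions.
    """
    violations: list[Violation] = []
    for pid, row in matrix.scores.iterrows():
        for iid, raw in row.items():
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                continue
            if isinstance(raw, str) and raw.strip() == "":
                continue
            val = _as_float(raw)
            if val is None:
                violations.append(Violation(pid, iid, raw, "non_numeric"))
            elif np.isnan(val):
                continue
            elif val < 0:
                violations.append(Violation(pid, iid, val, "negative"))
            elif val > matrix.scale_max:
                violations.append(Violation(pid, iid, val, "above_max"))
    return ValidationReport(violations)


def aggregate_by_subgroup(matrix: ScoreMatrix, method: str = "mean") -> ScoreMatrix:
    """Collapse participant rows to one row per subgroup.

    Each aggregated entry is the mean of the subgroup's non-abstaining
    scores on that item; a subgroup in which every member abstained yields
    an abstention.  Subgroup order follows first appearance in the
    participant order.
    """
    if method != "mean":
        raise ValueError(f"unsupported aggregation method: {method!r}")
    if matrix.subgroups is None:
        raise ValueError("matrix has no subgroup labels")
    missing = [p for p in matrix.participant_ids if matrix.subgroups.get(p) is None]
    if missing:
        raise ValueError(f"participants without a subgroup: {missing}")

    labels = [matrix.subgroups[p] for p in matrix.participant_ids]
    data = matrix.scores.astype(float)
    grouped = data.groupby(pd.Index(labels, name="subgroup"), sort=False).mean()
    # groupby(sort=False) preserves first-appearance order already
    return ScoreMatrix(grouped, scale_max=matrix.scale_max)


@dataclass
class ItemDispersion:
    """Per-item heterogeneity statistics (descriptive; tie-break aid)."""

    item_id: object
    n_scorers: int
    mean: float | None
    sample_sd: float | None  # n-1 denominator; None when n_scorers < 2
    min: float | None
    max: float | None
    range: float | None
    subgroup_mean_sd: float | None = None


def heterogeneity_stats(matrix: ScoreMatrix) -> list[ItemDispersion]:
    """One dispersion record per item, abstentions excluded.

    ``subgroup_mean_sd`` — the standard deviation across subgroup means —
    is filled in only when the matrix carries subgroup labels.
    """
    data = matrix.scores.astype(float)
    sub_means = None
    if matrix.subgroups is not None:
        sub_means = aggregate_by_subgroup(matrix).scores

    out = []
    for iid in matrix.item_ids:
        col = data[iid].dropna()
        n = int(col.size)
        if n == 0:
            rec = ItemDispersion(iid, 0, None, None, None, None, None)
        else:
            sd = float(col.std(ddof=1)) if n >= 2 else None
            rec = ItemDispersion(
                iid,
                n,
                float(col.mean()),
                sd,
                float(col.min()),
                float(col.max()),
                float(col.max() - col.min()),
            )
        if sub_means is not None:
            scol = sub_means[iid].dropna()
            rec.subgroup_mean_sd = float(scol.std(ddof=1)) if scol.size >= 2 else None
        out.append(rec)
    return out


def dispersion_frame(matrix: ScoreMatrix) -> pd.DataFrame:
    """Heterogeneity statistics as a DataFrame indexed by item."""
    recs = heterogeneity_stats(matrix)
    return pd.DataFrame(
        {
            "n_scorers": [r.n_scorers for r in recs],
            "mean": [r.mean for r in recs],
            "sample_sd": [r.sample_sd for r in recs],
            "min": [r.min for r in recs],
            "max": [r.max for r in recs],
            "range": [r.range for r in recs],
            "subgroup_mean_sd": [r.subgroup_mean_sd for r in recs],
        },
        index=pd.Index([r.item_id for r in recs], name="item_id"),
    )


class SubgroupMeanAggregator(BaseEstimator, TransformerMixin):
    """Transformer collapsing participant rows to subgroup-mean rows.

    Composes with :class:`~rrvote.voting.ReweightedRangeVoting` in a
    pipeline to reproduce the subgroup-mean input mode.  ``groups`` maps
    participant label (or positional row index, for plain arrays) to a
    subgroup label.

    Parameters
    ----------
    groups : mapping
        participant label → subgroup label.
    """

    def __init__(self, groups: Mapping | None = None):
        self.groups = groups

    def fit(self, X, y=None):
        if self.groups is None and not isinstance(X, ScoreMatrix):
            raise ValueError("groups must be provided unless X is a labelled ScoreMatrix")
        self.n_features_in_ = (
            X.n_items if isinstance(X, ScoreMatrix) else np.asarray(X).shape[1]
        )
        return self

    def transform(self, X):
        if isinstance(X, ScoreMatrix):
            m = X
            if self.groups is not None:
                m = ScoreMatrix(X.scores, X.scale_max, subgroups=pd.Series(dict(self.groups)))
            return aggregate_by_subgroup(m)
        df = pd.DataFrame(np.asarray(X, dtype=float))
        labels = [self.groups[i] for i in df.index]
        return df.groupby(pd.Index(labels), sort=False).mean().to_numpy()
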