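"""Re-weighted range voting: iterative proportional ranking of scored items.

Each participant scores every item on a fixed scale ``[0, K]`` (abstentions
allowed).  Items win ranks one at a time: the item with the highest weighted
total takes the next rank, after which every participant's *individual
weight* is recomputed from the cumulative sum ``S`` of the scores they gave
to the winners so far::

    weight = C / (C + S**A / K)

With decay aggression ``A = 1`` this is standard re-weighted range voting,
whose sequential down-weighting yields proportional representation of
like-minded voter blocs.  ``A > 1`` makes the initial decay more aggressive
(a voter who had their way on the first winners loses influence almost
entirely, promoting minority perspectives); ``A < 1`` eases the decay.

The loop is exposed both as the scikit-learn style estimator
:class:`ReweightedRangeVoting` and as the function :func:`run_ranking`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .matrix import (
    ItemDispersion,
    ScoreMatrix,
    aggregate_by_subgroup,
    heterogeneity_stats,
    validate_scores,
)

__all__ = [
    "VotingConfig",
    "ParticipantState",
    "RankingRound",
    "RankingResult",
    "TieError",
    "individual_weight",
    "weighted_item_totals",
    "select_next_winner",
    "ReweightedRangeVoting",
    "run_ranking",
    "rank_under_conditions",
    "condition_presets",
    "top_list_intersection",
]

_TIE_POLICIES = ("error", "input_order", "lowest_dispersion")
_ZERO_TOTAL_POLICIES = ("stop", "rank_by_tie_policy")


class TieError(RuntimeError):
    """Raised under ``tie_policy='error'`` when items tie for a rank."""

    def __init__(self, rank: int, winner, tie_set: list):
        self.rank = rank
        self.tied_items = [winner, *tie_set]
        where = f"rank {rank}" if rank else "a rank"
        super().__init__(
            f"{len(self.tied_items)} items tied for {where}: {self.tied_items}"
        )


@dataclass(frozen=True)
class VotingConfig:
    """All parameters of the weighting formula and the selection loop.

    Parameters
    ----------
    constant : float
        The decay constant C (> 0).  Default 0.5, the reference
        illustration value; smaller C means steeper decay.
    max_scale : float
        Maximum scale score K (> 0), the a-priori top of the scoring scale.
    decay_aggression : float
        Exponent A (> 0) on the cumulative winner-score sum.  1.0 is the
        regular method.
    top_n : int or "all"
        How many ranks to assign.
    tie_policy : {"error", "input_order", "lowest_dispersion"}
        How to break ties for a rank.  The tie set is always reported.
    zero_total_policy : {"stop", "rank_by_tie_policy"}
        What to do when every remaining item's weighted total is zero.
    tie_tolerance : float
        Relative tolerance for tie detection (totals within
        ``tie_tolerance * max(1, |max total|)`` of the maximum tie).
    """

    constant: float = 0.5
    max_scale: float = 10.0
    decay_aggression: float = 1.0
    top_n: int | str = "all"
    tie_policy: str = "input_order"
    zero_total_policy: str = "stop"
    tie_tolerance: float = 1e-9

    def __post_init__(self):
        if not self.constant > 0:
            raise ValueError("constant must be > 0")
        if not self.max_scale > 0:
            raise ValueError("max_scale must be > 0")
        if not self.decay_aggression > 0:
            raise ValueError("decay_aggression must be > 0")
        if self.tie_tolerance < 0:
            raise ValueError("tie_tolerance must be >= 0")
        if self.tie_policy not in _TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {_TIE_POLICIES}")
        if self.zero_total_policy not in _ZERO_TOTAL_POLICIES:
            raise ValueError(f"zero_total_policy must be one of {_ZERO_TOTAL_POLICIES}")
        if self.top_n != "all":
            if not (isinstance(self.top_n, (int, np.integer)) and self.top_n >= 1):
                raise ValueError('top_n must be a positive integer or "all"')

    def resolve_top_n(self, n_items: int) -> int:
        if self.top_n == "all":
            return n_items
        if self.top_n > n_items:
            raise ValueError(f"top_n={self.top_n} exceeds the {n_items} items available")
        return int(self.top_n)


@dataclass
class ParticipantState:
    """A participant's cumulative winner-score sum S and current weight."""

    ranked_winner_score_sum: float = 0.0
    weight: float = 1.0


@dataclass
class RankingRound:
    """One selection round: the winner, its total, and any tie."""

    rank: int
    winner: object
    weighted_total: float
    tie_set: list = field(default_factory=list)
    tie_resolution: str = "none"  # "none" | "input_order" | "lowest_dispersion"


@dataclass
class RankingResult:
    """Ordered selection rounds plus everything needed to reproduce them."""

    rounds: list[RankingRound]
    unranked_items: list
    config_echo: VotingConfig
    participant_final_states: dict

    @property
    def ranking(self) -> list:
        return [r.winner for r in self.rounds]

    def rank_of(self, item) -> int | None:
        for r in self.rounds:
            if r.winner == item:
                return r.rank
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.rounds],
                "item_id": [r.winner for r in self.rounds],
                "weighted_total": [r.weighted_total for r in self.rounds],
                "tie_set": [";".join(map(str, r.tie_set)) for r in self.rounds],
                "tie_resolution": [r.tie_resolution for r in self.rounds],
            }
        )


def individual_weight(
    ranked_winner_score_sum, config: VotingConfig | None = None, **kwargs
) -> float | np.ndarray:
    """Weight C / (C + S**A / K) of a participant with winner-score sum S.

    Equals 1 exactly when S = 0 and decreases strictly and monotonically
    in S; always positive.  Accepts scalars or arrays.

    >>> individual_weight(10.0, VotingConfig(constant=0.5, max_scale=10.0))
    0.3333333333333333
    """
    cfg = config if config is not None else VotingConfig(**kwargs)
    s = np.asarray(ranked_winner_score_sum, dtype=float)
    if np.any(s < 0):
        raise ValueError("ranked_winner_score_sum must be nonnegative")
    w = cfg.constant / (cfg.constant + s ** cfg.decay_aggression / cfg.max_scale)
    return float(w) if np.isscalar(ranked_winner_score_sum) or s.ndim == 0 else w


def weighted_item_totals(
    matrix: ScoreMatrix,
    states: Mapping[object, ParticipantState],
    unranked_items: Sequence,
) -> dict:
    """Weighted column sums over the not-yet-ranked items.

    ``total_j = Σ_i weight_i × score_ij`` with abstentions contributing
    zero.  Only items in ``unranked_items`` appear in the result.
    """
    unknown = [i for i in unranked_items if i not in matrix.scores.columns]
    if unknown:
        raise KeyError(f"unknown items: {unknown}")
    missing = [p for p in matrix.participant_ids if p not in states]
    if missing:
        raise KeyError(f"participants without a state: {missing}")

    weights = np.array([states[p].weight for p in matrix.participant_ids])
    vals = matrix.values  # NaN = abstain
    filled = np.nan_to_num(vals, nan=0.0)
    totals = weights @ filled
    by_item = dict(zip(matrix.item_ids, totals))
    return {i: float(by_item[i]) for i in unranked_items}


def select_next_winner(
    totals: Mapping[object, float],
    config: VotingConfig,
    dispersion: Mapping[object, ItemDispersion] | None = None,
    input_order: Sequence | None = None,
) -> tuple:
    """Pick the item with the maximal total, detecting and resolving ties.

    Returns ``(winner, tie_set, tie_resolution)`` where ``tie_set`` lists
    the items tied with the winner within the relative tie tolerance
    (empty when the winner is unique).  Under ``tie_policy='error'`` a
    tie raises :class:`TieError` naming the tied items.
    """
    if not totals:
        raise ValueError("totals must be nonempty")
    order = list(input_order) if input_order is not None else list(totals)
    order = [i for i in order if i in totals]

    max_total = max(totals.values())
    tol = config.tie_tolerance * max(1.0, abs(max_total))
    contenders = [i for i in order if max_total - totals[i] <= tol]

    if len(contenders) == 1:
        return contenders[0], [], "none"

    if config.tie_policy == "error":
        raise TieError(0, contenders[0], contenders[1:])

    resolution = config.tie_policy
    if config.tie_policy == "lowest_dispersion" and dispersion is not None:
        # smallest per-item sample SD wins; missing SD sorts last; equal
        # SDs fall back to input order (list order is the stable key)
        def sd_key(item):
            rec = dispersion.get(item)
            sd = getattr(rec, "sample_sd", rec) if rec is not None else None
            return (sd is None, sd if sd is not None else 0.0)

        winner = min(contenders, key=sd_key)
    else:
        winner = contenders[0]
        resolution = "input_order"
    tie_set = [i for i in contenders if i != winner]
    return winner, tie_set, resolution


class ReweightedRangeVoting(BaseEstimator, TransformerMixin):
    """Proportional multiwinner ranking of item columns by re-weighted range voting.

    ``fit(X)`` runs the sequential selection loop on a participants × items
    score matrix; ``transform(X)`` then returns the columns of the ranked
    items in rank order (a score-based feature/item selector).

    Parameters
    ----------
    constant : float, default 0.5
        Decay constant C of the weight formula.
    max_scale : float, optional
        Maximum scale score K.  When None it is taken from a
        :class:`~rrvote.matrix.ScoreMatrix` input, or inferred as the
        largest observed score for plain arrays/frames.
    decay_aggression : float, default 1.0
        Exponent A; 1.0 is regular re-weighted range voting, larger values
        decay dominant voters' influence faster.
    top_n : int or "all", default "all"
        Number of ranks to assign.
    tie_policy : {"input_order", "lowest_dispersion", "error"}
    zero_total_policy : {"stop", "rank_by_tie_policy"}
        Behaviour when every remaining item's weighted total is zero.
    tie_tolerance : float, default 1e-9
        Relative tolerance for tie detection.
    validate : bool, default True
        Check scores against ``[0, max_scale]`` before ranking.

    Attributes
    ----------
    result_ : RankingResult
        Full record of the run: rounds, tie sets, final participant states.
    ranking_ : list
        Item identifiers in rank order.
    rounds_ : list of RankingRound
    unranked_items_ : list
        Items never ranked (beyond ``top_n`` or halted at zero totals).
    weights_ : ndarray of shape (n_participants,)
        Final individual weights.
    feature_names_in_ : ndarray
        Item identifiers in input column order.

    Examples
    --------
    >>> import pandas as pd
    >>> X = pd.DataFrame({"P": [5, 0], "Q": [4, 4], "R": [0, 5]})
    >>> ReweightedRangeVoting(max_scale=5).fit(X).ranking_
    ['Q', 'P', 'R']
    """

    def __init__(
        self,
        constant: float = 0.5,
        max_scale: float | None = None,
        decay_aggression: float = 1.0,
        top_n: int | str = "all",
        tie_policy: str = "input_order",
        zero_total_policy: str = "stop",
        tie_tolerance: float = 1e-9,
        validate: bool = True,
    ):
        self.constant = constant
        self.max_scale = max_scale
        self.decay_aggression = decay_aggression
        self.top_n = top_n
        self.tie_policy = tie_policy
        self.zero_total_policy = zero_total_policy
        self.tie_tolerance = tie_tolerance
        self.validate = validate

    # -- input handling -----------------------------------------------------

    def _coerce(self, X) -> ScoreMatrix:
        if isinstance(X, ScoreMatrix):
            m = X
        else:
            df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
            k = self.max_scale
            if k is None:
                k = float(np.nanmax(df.astype(float).to_numpy()))
                if not k > 0:
                    k = 1.0
            m = ScoreMatrix(df, scale_max=k)
        if self.max_scale is not None:
            m = ScoreMatrix(m.scores, scale_max=self.max_scale, subgroups=m.subgroups)
        return m

    def _config(self, matrix: ScoreMatrix) -> VotingConfig:
        return VotingConfig(
            constant=self.constant,
            max_scale=matrix.scale_max,
            decay_aggression=self.decay_aggression,
            top_n=self.top_n,
            tie_policy=self.tie_policy,
            zero_total_policy=self.zero_total_policy,
            tie_tolerance=self.tie_tolerance,
        )

    # -- the selection loop -------------------------------------------------

    def fit(self, X, y=None):
        """Run the re-weighted selection rounds on the score matrix X."""
        matrix = self._coerce(X)
        config = self._config(matrix)
        if self.validate:
            report = validate_scores(matrix)
            if not report.is_valid:
                raise ValueError(f"invalid score matrix:\n{report}")

        vals = matrix.values
        filled = np.nan_to_num(vals, nan=0.0)
        participants = matrix.participant_ids
        items = matrix.item_ids
        col_of = {item: j for j, item in enumerate(items)}

        dispersion = None
        if config.tie_policy == "lowest_dispersion":
            dispersion = {d.item_id: d for d in heterogeneity_stats(matrix)}

        n_ranks = config.resolve_top_n(len(items))
        sums = np.zeros(len(participants))
        weights = np.ones(len(participants))
        unranked = list(items)
        rounds: list[RankingRound] = []

        for rank in range(1, n_ranks + 1):
            totals_vec = weights @ filled
            totals = {i: float(totals_vec[col_of[i]]) for i in unranked}
            if max(totals.values()) <= 0.0 and config.zero_total_policy == "stop":
                break
            try:
                winner, tie_set, resolution = select_next_winner(
                    totals, config, dispersion=dispersion, input_order=unranked
                )
            except TieError as err:
                raise TieError(rank, err.tied_items[0], err.tied_items[1:]) from None
            rounds.append(
                RankingRound(rank, winner, totals[winner], tie_set, resolution)
            )
            unranked.remove(winner)
            # abstentions on the winner add 0 to the sum: abstaining never
            # spends influence
            sums += filled[:, col_of[winner]]
            weights = individual_weight(sums, config)
            if not unranked:
                break

        self.result_ = RankingResult(
            rounds=rounds,
            unranked_items=unranked,
            config_echo=config,
            participant_final_states={
                p: ParticipantState(float(s), float(w))
                for p, s, w in zip(participants, sums, weights)
            },
        )
        self.ranking_ = self.result_.ranking
        self.rounds_ = self.result_.rounds
        self.unranked_items_ = unranked
        self.weights_ = weights
        self.n_features_in_ = len(items)
        self.feature_names_in_ = np.asarray(items, dtype=object)
        return self

    def transform(self, X):
        """Return the ranked items' columns of X, in rank order."""
        if not hasattr(self, "result_"):
            raise AttributeError("this ReweightedRangeVoting instance is not fitted yet")
        matrix = self._coerce(X)
        if isinstance(X, (ScoreMatrix, pd.DataFrame)):
            return matrix.scores.loc[:, self.ranking_]
        idx = [list(self.feature_names_in_).index(i) for i in self.ranking_]
        return np.asarray(X, dtype=float)[:, idx]

    def get_support(self) -> np.ndarray:
        """Boolean mask over input columns marking the ranked items."""
        if not hasattr(self, "result_"):
            raise AttributeError("this ReweightedRangeVoting instance is not fitted yet")
        ranked = set(self.ranking_)
        return np.array([i in ranked for i in self.feature_names_in_])


def run_ranking(matrix: ScoreMatrix, config: VotingConfig | None = None, **kwargs) -> RankingResult:
    """Run the full re-weighted range voting loop; thin estimator wrapper.

    ``config`` may be a :class:`VotingConfig`; keyword arguments override
    its fields (or build one from scratch).
    """
    cfg = config if config is not None else VotingConfig(max_scale=matrix.scale_max)
    if kwargs:
        cfg = replace(cfg, **kwargs)
    est = ReweightedRangeVoting(
        constant=cfg.constant,
        max_scale=cfg.max_scale,
        decay_aggression=cfg.decay_aggression,
        top_n=cfg.top_n,
        tie_policy=cfg.tie_policy,
        zero_total_policy=cfg.zero_total_policy,
        tie_tolerance=cfg.tie_tolerance,
    )
    return est.fit(matrix).result_


def condition_presets(mild_a: float, aggressive_a: float = 4.0) -> list[tuple[str, float]]:
    """The four standard evaluation conditions: (input mode, decay A).

    1. subgroup means, regular weighting (A = 1);
    2. individual scores, regular weighting;
    3. individual scores, mild decay (``mild_a``, no default claimed);
    4. individual scores, aggressive decay (A = 4).
    """
    return [
        ("subgroup_mean", 1.0),
        ("individual", 1.0),
        ("individual", float(mild_a)),
        ("individual", float(aggressive_a)),
    ]


def rank_under_conditions(
    matrix: ScoreMatrix,
    subgroup_map: Mapping | None = None,
    condition_set: Sequence[tuple[str, float]] | None = None,
    top_n: int | str = "all",
    constant: float = 0.5,
    mild_a: float | None = None,
    **config_kwargs,
) -> dict[str, RankingResult]:
    """Rank the same panel under several (input mode, decay) conditions.

    ``condition_set`` is a list of ``(input_mode, decay_aggression)`` with
    input_mode ∈ {"individual", "subgroup_mean"}; when omitted, the four
    standard presets are used and ``mild_a`` must be given.  Returns a dict
    keyed by a readable condition label.
    """
    if condition_set is None:
        if mild_a is None:
            raise ValueError("mild_a is required when using the default condition presets")
        condition_set = condition_presets(mild_a)

    needs_subgroups = any(mode == "subgroup_mean" for mode, _ in condition_set)
    work = matrix
    if subgroup_map is not None:
        work = ScoreMatrix(matrix.scores, matrix.scale_max, subgroups=pd.Series(dict(subgroup_map)))
    if needs_subgroups and work.subgroups is None:
        raise ValueError("subgroup_map is required for subgroup_mean conditions")

    aggregated = aggregate_by_subgroup(work) if needs_subgroups else None

    results: dict[str, RankingResult] = {}
    for mode, a in condition_set:
        if mode not in ("individual", "subgroup_mean"):
            raise ValueError(f"unknown input mode: {mode!r}")
        source = aggregated if mode == "subgroup_mean" else work
        cfg = VotingConfig(
            constant=constant,
            max_scale=matrix.scale_max,
            decay_aggression=float(a),
            top_n=top_n,
            **config_kwargs,
        )
        label = f"{mode}_A{a:g}"
        if label in results:  # identical conditions repeated: determinism
            label = f"{label}#{sum(k.startswith(label) for k in results)}"
        results[label] = run_ranking(source, cfg)
    return results


def top_list_intersection(results: Mapping[str, RankingResult], n: int | None = None) -> set:
    """Items present in the top-n of every condition's ranking."""
    common: set | None = None
    for res in results.values():
        top = set(res.ranking if n is None else res.ranking[:n])
        common = top if common is None else common & top
    return common or set()
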