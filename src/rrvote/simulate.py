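"""Synthetic score panels with controlled bloc structure.

Generates participants × items matrices in which blocs of like-minded
voters favour disjoint (or overlapping) item sets, with optional Gaussian
score noise, integer rounding and independent per-cell abstentions.  The
generator makes every ranking behaviour — proportional seat splits, decay
effects, exact ties, abstention handling — testable without any external
data file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ScoreMatrix

__all__ = [
    "BlocSpec",
    "PanelSimConfig",
    "generate_panel",
    "disjoint_bloc_panel",
    "kleefstra_like_panel",
]


@dataclass(frozen=True)
class BlocSpec:
    """One voter bloc: who they are and what they favour."""

    name: str
    n_members: int
    favored_items: tuple = ()
    favored_score: float = 0.0
    other_score: float = 0.0


@dataclass
class PanelSimConfig:
    """Specification of a synthetic panel.

    With ``noise_sd = 0`` and ``abstain_prob = 0`` the output is the exact
    deterministic bloc profile.  Noise is Gaussian, applied per cell, then
    clamped to ``[0, scale_max]`` and (optionally) rounded to integers —
    simple, bounded, and enough to create realistic near-ties.
    """

    blocs: list[BlocSpec]
    n_items: int
    scale_max: float
    item_ids: Sequence | None = None
    noise_sd: float = 0.0
    abstain_prob: float = 0.0
    integer_scores: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.blocs:
            raise ValueError("at least one bloc is required")
        for b in self.blocs:
            if b.n_members < 1:
                raise ValueError(f"bloc {b.name!r} must have at least one member")
            for s in (b.favored_score, b.other_score):
                if not (0 <= s <= self.scale_max):
                    raise ValueError(
                        f"bloc {b.name!r} scores must lie in [0, {self.scale_max}]"
                    )
        if self.item_ids is not None and len(self.item_ids) != self.n_items:
            raise ValueError(
                f"item_ids has {len(self.item_ids)} entries but n_items = {self.n_items}"
            )
        if not 0 <= self.abstain_prob <= 1:
            raise ValueError("abstain_prob must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def generate_panel(config: PanelSimConfig) -> ScoreMatrix:
    """Draw a score matrix from the bloc specification; deterministic per seed."""
    items = (
        list(config.item_ids)
        if config.item_ids is not None
        else [f"Q{j + 1:02d}" for j in range(config.n_items)]
    )
    item_set = set(items)
    for b in config.blocs:
        unknown = [i for i in b.favored_items if i not in item_set]
        if unknown:
            raise ValueError(f"bloc {b.name!r} favours unknown items: {unknown}")

    rng = np.random.default_rng(config.seed)
    rows, row_ids, groups = [], [], {}
    for bloc in config.blocs:
        base = np.full(config.n_items, float(bloc.other_score))
        fav = np.isin(items, list(bloc.favored_items))
        base[fav] = float(bloc.favored_score)
        for k in range(bloc.n_members):
            pid = f"{bloc.name}_{k + 1:02d}"
            row = base.copy()
            if config.noise_sd > 0:
                row = row + rng.normal(0.0, config.noise_sd, size=config.n_items)
            row = np.clip(row, 0.0, config.scale_max)
            if config.integer_scores:
                row = np.rint(row)
            if config.abstain_prob > 0:
                row[rng.random(config.n_items) < config.abstain_prob] = np.nan
            rows.append(row)
            row_ids.append(pid)
            groups[pid] = bloc.name

    frame = pd.DataFrame(rows, index=row_ids, columns=items)
    return ScoreMatrix(frame, scale_max=config.scale_max, subgroups=pd.Series(groups))


def disjoint_bloc_panel(
    n_majority: int = 60,
    n_minority: int = 40,
    items_per_bloc: int = 5,
    scale_max: float = 10.0,
    seed: int = 0,
) -> ScoreMatrix:
    """Two disjoint blocs: A-voters give A1..Ak the top score and B1..Bk zero,
    B-voters the reverse.  The canonical proportionality fixture: at 60/40 the
    top 5 under regular weighting splits 3:2 between the blocs."""
    a_items = tuple(f"A{j + 1}" for j in range(items_per_bloc))
    b_items = tuple(f"B{j + 1}" for j in range(items_per_bloc))
    config = PanelSimConfig(
        blocs=[
            BlocSpec("A", n_majority, a_items, favored_score=scale_max),
            BlocSpec("B", n_minority, b_items, favored_score=scale_max),
        ],
        n_items=2 * items_per_bloc,
        scale_max=scale_max,
        item_ids=[*a_items, *b_items],
        seed=seed,
    )
    return generate_panel(config)


def kleefstra_like_panel(seed: int = 0) -> ScoreMatrix:
    """A panel shaped like a rare-disease guideline prioritization exercise:
    31 participants in 7 subgroups (a core group, five expertise working
    groups, ten patient representatives) scoring 45 key questions on 0-5
    integers, with moderate bloc structure and occasional abstentions.

    A synthetic fixture preset, not a reconstruction of any real score set.
    """
    items = [f"KQ{j + 1:02d}" for j in range(45)]

    def span(lo, hi):  # items KQ{lo}..KQ{hi}, 1-based inclusive
        return tuple(items[lo - 1 : hi])

    config = PanelSimConfig(
        blocs=[
            BlocSpec("core", 3, span(1, 8), favored_score=5, other_score=2),
            BlocSpec("wg_diagnostics", 4, span(7, 14), favored_score=5, other_score=2),
            BlocSpec("wg_neurology", 4, span(13, 20), favored_score=5, other_score=2),
            BlocSpec("wg_behaviour", 4, span(19, 26), favored_score=5, other_score=2),
            BlocSpec("wg_somatic", 3, span(25, 32), favored_score=5, other_score=2),
            BlocSpec("wg_transition", 3, span(31, 38), favored_score=5, other_score=2),
            BlocSpec("patients", 10, span(37, 45), favored_score=5, other_score=2),
        ],
        n_items=45,
        scale_max=5.0,
        item_ids=items,
        noise_sd=1.0,
        abstain_prob=0.05,
        integer_scores=True,
        seed=seed,
    )
    return generate_panel(config)
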