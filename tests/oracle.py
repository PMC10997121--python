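"""Naive pure-python re-weighted range voting, written independently of the
package internals, used only as a cross-check oracle in tests.

Operates on plain lists of lists (None = abstention) with explicit loops and
the weight formula spelled out inline; no numpy, no shared helpers.
"""

from __future__ import annotations


def naive_rrv(
    scores: list[list[float | None]],
    items: list,
    constant: float,
    max_scale: float,
    decay_aggression: float = 1.0,
    top_n: int | None = None,
    tie_tolerance: float = 1e-9,
) -> list[tuple[int, object, float]]:
    """Step-by-step selection loop; returns [(rank, item, total_at_selection)].

    Ties broken by input (column) order; stops when every remaining item's
    weighted total is zero.
    """
    n_voters = len(scores)
    n_items = len(items)
    sums = [0.0] * n_voters
    remaining = list(range(n_items))
    rounds: list[tuple[int, object, float]] = []
    limit = n_items if top_n is None else top_n

    for rank in range(1, limit + 1):
        if not remaining:
            break
        weights = []
        for s in sums:
            weights.append(constant / (constant + (s ** decay_aggression) / max_scale))
        totals = {}
        for j in remaining:
            total = 0.0
            for i in range(n_voters):
                v = scores[i][j]
                if v is not None:
                    total += weights[i] * v
            totals[j] = total
        best = max(totals.values())
        if best <= 0.0:
            break
        tol = tie_tolerance * max(1.0, abs(best))
        winner = None
        for j in remaining:  # input order breaks ties
            if best - totals[j] <= tol:
                winner = j
                break
        rounds.append((rank, items[winner], totals[winner]))
        remaining.remove(winner)
        for i in range(n_voters):
            v = scores[i][winner]
            if v is not None:
                sums[i] += v
    return rounds
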