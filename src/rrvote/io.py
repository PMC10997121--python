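"""Reading score matrices (CSV/XLSX), writing rankings, run manifests.

The input dialect: a header row of item identifiers, a first column of
participant identifiers, comma-separated, UTF-8, dot decimals.  Empty cells
and the token ``NA`` are abstentions.  XLSX is supported read-only with the
same layout.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .matrix import ScoreMatrix, _as_float
from .voting import ParticipantState, RankingResult, RankingRound, VotingConfig

__all__ = [
    "ParseError",
    "read_score_matrix",
    "read_subgroup_map",
    "write_score_matrix",
    "write_subgroup_map",
    "write_ranking",
    "read_ranking_json",
    "RunManifest",
    "write_manifest",
]

_ABSTAIN_TOKENS = {"", "NA"}


class ParseError(ValueError):
    """Malformed input file (bad header, duplicate labels, ragged rows)."""


def _check_csv_header(path) -> None:
    # pandas silently mangles duplicate columns (q1 -> q1.1); inspect the
    # raw header so duplicates are reported by their actual names
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise ParseError(f"{path}: malformed header (item id columns required)")
    items = [h.strip() for h in header[1:]]
    seen, dupes = set(), []
    for name in items:
        if name in seen:
            dupes.append(name)
        else:
            seen.add(name)
    if dupes:
        raise ParseError(f"{path}: duplicate item columns: {sorted(set(dupes))}")


def _check_xlsx_header(path) -> None:
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True)
    try:
        header = next(wb.active.iter_rows(max_row=1, values_only=True), None)
    finally:
        wb.close()
    if not header or len(header) < 2:
        raise ParseError(f"{path}: malformed header (item id columns required)")
    items = [str(h).strip() for h in header[1:]]
    dupes = sorted({n for n in items if items.count(n) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate item columns: {dupes}")


def _clean_frame(raw: pd.DataFrame, path) -> pd.DataFrame:
    """Map abstention tokens to NaN and numeric strings to floats;
    leave genuinely non-numeric cells intact for validation to report."""
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate participant labels: {dupes}")
    if raw.columns.has_duplicates:
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate item columns: {dupes}")

    def convert(cell):
        if cell is None:
            return np.nan
        if isinstance(cell, str) and cell.strip() in _ABSTAIN_TOKENS:
            return np.nan
        val = _as_float(cell)
        return cell if val is None else val  # keep bad cells for validation

    return raw.map(convert)


def read_score_matrix(path, format: str | None = None, scale_max: float = 10.0) -> ScoreMatrix:
    """Load a participants × items score matrix from CSV or XLSX.

    ``format`` is inferred from the file suffix when omitted.  Empty cells
    and ``NA`` become abstentions; parsing is locale-independent (dot
    decimal).  Duplicate participant or item labels raise
    :class:`ParseError`.
    """
    path = Path(path)
    fmt = format or ("xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv")
    try:
        if fmt == "csv":
            _check_csv_header(path)
            raw = pd.read_csv(
                path, index_col=0, dtype=str, keep_default_na=False, skipinitialspace=True
            )
        elif fmt == "xlsx":
            _check_xlsx_header(path)
            raw = pd.read_excel(path, index_col=0, dtype=object, engine="openpyxl")
        else:
            raise ParseError(f"unsupported input format: {fmt!r}")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    if raw.shape[1] == 0:
        raise ParseError(f"{path}: no item columns found (header row of item ids required)")
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    return ScoreMatrix(_clean_frame(raw, path), scale_max=scale_max)


def read_subgroup_map(path) -> pd.Series:
    """Read a participant → subgroup CSV (columns: participant_id, subgroup)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: subgroup map needs two columns (participant_id, subgroup)")
    pids = df.iloc[:, 0].str.strip()
    if pids.duplicated().any():
        dupes = pids[pids.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate participant ids in subgroup map: {dupes}")
    return pd.Series(df.iloc[:, 1].str.strip().to_numpy(), index=pids.to_numpy())


def write_score_matrix(matrix: ScoreMatrix, path) -> None:
    """Write a score matrix in the standard CSV dialect (abstentions empty)."""
    matrix.scores.to_csv(path, index_label="participant_id")


def write_subgroup_map(matrix: ScoreMatrix, path) -> None:
    if matrix.subgroups is None:
        raise ValueError("matrix has no subgroup labels to write")
    pd.DataFrame(
        {
            "participant_id": matrix.participant_ids,
            "subgroup": [matrix.subgroups[p] for p in matrix.participant_ids],
        }
    ).to_csv(path, index=False)


@dataclass
class RunManifest:
    """Everything needed to reproduce an emitted result file bit-for-bit."""

    inputs: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    conditions: list = field(default_factory=list)
    tool_version: str = __version__
    seed: int | None = None
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_dict(self) -> dict:
        return asdict(self)


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")


def _result_to_dict(result: RankingResult, manifest: RunManifest | None) -> dict:
    out = {
        "rounds": [
            {
                "rank": r.rank,
                "winner": r.winner,
                "weighted_total": r.weighted_total,
                "tie_set": list(r.tie_set),
                "tie_resolution": r.tie_resolution,
            }
            for r in result.rounds
        ],
        "unranked_items": list(result.unranked_items),
        "config": asdict(result.config_echo),
        "participant_final_states": {
            str(p): {
                "ranked_winner_score_sum": s.ranked_winner_score_sum,
                "weight": s.weight,
            }
            for p, s in result.participant_final_states.items()
        },
    }
    if manifest is not None:
        out["manifest"] = manifest.to_dict()
    return out


def write_ranking(
    result: RankingResult,
    path,
    format: str = "csv",
    manifest: RunManifest | None = None,
) -> None:
    """Write a ranking as CSV (fixed 6-decimal totals) or JSON (full precision).

    CSV columns: rank, item_id, weighted_total, tie_set (semicolon-joined),
    tie_resolution.  JSON mirrors the full :class:`RankingResult`, including
    unranked items, final participant states and (optionally) the manifest.
    """
    path = Path(path)
    if format == "csv":
        frame = result.to_frame()
        frame["weighted_total"] = frame["weighted_total"].map(lambda v: f"{v:.6f}")
        frame.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(_result_to_dict(result, manifest), indent=2) + "\n")
    else:
        raise ValueError(f"unsupported output format: {format!r}")


def read_ranking_json(path) -> RankingResult:
    """Re-load a JSON ranking written by :func:`write_ranking`."""
    data = json.loads(Path(path).read_text())
    return RankingResult(
        rounds=[
            RankingRound(
                rank=r["rank"],
                winner=r["winner"],
                weighted_total=r["weighted_total"],
                tie_set=list(r["tie_set"]),
                tie_resolution=r["tie_resolution"],
            )
            for r in data["rounds"]
        ],
        unranked_items=list(data["unranked_items"]),
        config_echo=VotingConfig(**data["config"]),
        participant_final_states={
            p: ParticipantState(s["ranked_winner_score_sum"], s["weight"])
            for p, s in data["participant_final_states"].items()
        },
    )
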