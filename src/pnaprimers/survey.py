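"""Literature-survey computations: hit counting, ranking, usage diversity.

A "hit" is one recorded use of a primer pair by one study for one target
microbial group; a study can contribute zero or many hits per group.  The
operations here reproduce the survey-style summaries used to characterize
primer usage across PNA/PN/anammox reactor studies: per-pair hit counts,
descending rankings, and the per-group diversity of primer choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "StudyRecord",
    "count_hits",
    "rank_by_hits",
    "group_usage_distribution",
    "load_study_records",
    "write_study_records",
    "records_from_hit_counts",
]


@dataclass(frozen=True)
class StudyRecord:
    """One (study, target group, primer pair) usage row."""

    study_id: str
    year: Optional[int]
    system_type: str  # PNA | PN | A
    target_group: str
    pair_name: str
    gene: str = "16S"


def count_hits(records: Sequence[StudyRecord], scope: str = "ALL") -> dict[str, int]:
    """Hit count per primer pair, optionally restricted to one target group.

    The total over all pairs equals the number of in-scope records
    (conservation), since each record is exactly one hit.
    """
    counter: Counter[str] = Counter()
    for rec in records:
        if scope == "ALL" or rec.target_group == scope:
            counter[rec.pair_name] += 1
    return dict(counter)


def rank_by_hits(hits: Mapping[str, int]) -> list[tuple[str, int]]:
    """Pairs ordered by descending hit count; ties broken alphabetically."""
    return sorted(hits.items(), key=lambda kv: (-kv[1], kv[0]))


def group_usage_distribution(records: Sequence[StudyRecord]) -> pd.DataFrame:
    """Per-group primer diversity: distinct pair count and share of all hits.

    Returns a DataFrame indexed by target group with columns
    ``distinct_pairs``, ``hits`` and ``hit_share_pct``; the shares sum to
    100% up to rounding.
    """
    if not records:
        return pd.DataFrame(columns=["distinct_pairs", "hits", "hit_share_pct"])
    rows: dict[str, dict] = {}
    total = len(records)
    for group in sorted({r.target_group for r in records}):
        in_group = [r for r in records if r.target_group == group]
        rows[group] = {
            "distinct_pairs": len({r.pair_name for r in in_group}),
            "hits": len(in_group),
            "hit_share_pct": len(in_group) / total * 100.0,
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "target_group"
    return df


_COLUMNS = ["study_id", "year", "system_type", "target_group", "pair_name", "gene"]


def load_study_records(path) -> list[StudyRecord]:
    """Read study records from TSV (columns study_id, year, system_type,
    target_group, pair_name, gene; year may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"study-record file {path} missing columns: {sorted(missing)}")
    return [
        StudyRecord(
            study_id=row["study_id"],
            year=int(row["year"]) if row["year"] else None,
            system_type=row["system_type"],
            target_group=row["target_group"],
            pair_name=row["pair_name"],
            gene=row["gene"] or "16S",
        )
        for _, row in df.iterrows()
    ]


def write_study_records(records: Sequence[StudyRecord], path) -> None:
    pd.DataFrame(
        [(r.study_id, r.year, r.system_type, r.target_group, r.pair_name, r.gene)
         for r in records],
        columns=_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def records_from_hit_counts(
    hits_by_pair: Mapping[str, int],
    target_group: str = "EUB",
    gene: str = "16S",
    system_type: str = "PNA",
) -> list[StudyRecord]:
    """Synthetic reconstruction of study records from published hit counts.

    The underlying per-study table is not available, so each hit is
    expanded into one record with a synthetic study id; counting the
    result recovers the input exactly.
    """
    records = []
    i = 0
    for pair in sorted(hits_by_pair):
        for _ in range(hits_by_pair[pair]):
            i += 1
            records.append(
                StudyRecord(f"synthetic-study-{i:03d}", None, system_type,
                            target_group, pair, gene)
            )
    return records
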