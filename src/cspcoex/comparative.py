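"""Comparative table of species pairs exhibiting conspecific sperm precedence.

Each record classifies one congeneric pair by how the two species are
arranged in space and niche: ``sympatry`` (broad overlap with little or no
niche separation), ``niche_partitioning`` (overlapping ranges but local
separation by food, habitat or season), ``parapatry`` (adjacent ranges with
a narrow contact zone), or ``allopatry`` (disjoint ranges).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "SpeciesPairRecord",
    "load_pairs",
    "load_packaged_pairs",
    "category_summary",
]

CATEGORIES = ("sympatry", "niche_partitioning", "parapatry", "allopatry")

_COLUMNS = ["group", "common_name", "species_pair", "category", "description", "references"]


@dataclass(frozen=True)
class SpeciesPairRecord:
    group: str
    common_name: str
    species_pair: str
    category: str
    description: str = ""
    references: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )


def load_pairs(path: str | Path) -> list[SpeciesPairRecord]:
    """Read and validate a species-pair CSV (exact enum categories required)."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pairs file {path} lacks columns {sorted(missing)}")
    if len(df) == 0:
        raise ValueError(f"pairs file {path} contains no records")
    records = []
    for idx, row in df.iterrows():
        if row["category"] not in CATEGORIES:
            raise ValueError(
                f"row {idx} ({row['species_pair']!r}) has invalid category "
                f"{row['category']!r}; expected one of {CATEGORIES}"
            )
        records.append(SpeciesPairRecord(**{c: str(row[c]) for c in _COLUMNS}))
    return records


def load_packaged_pairs() -> list[SpeciesPairRecord]:
    """The packaged 24-pair comparative table."""
    from importlib.resources import files

    return load_pairs(files("cspcoex.data") / "species_pairs.csv")


def category_summary(
    records: Sequence[SpeciesPairRecord],
) -> tuple[pd.Series, pd.DataFrame]:
    """Counts per category and per (group x category).

    Returns ``(by_category, by_group)``: a Series indexed by the four
    categories in fixed order, and a DataFrame of groups (rows, sorted) by
    categories (columns, fixed order).  Counts always sum to the number of
    records.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record set")
    df = pd.DataFrame(
        [(r.group, r.category) for r in records], columns=["group", "category"]
    )
    by_category = (
        df["category"].value_counts().reindex(CATEGORIES, fill_value=0).astype(int)
    )
    by_category.name = "count"
    by_group = (
        df.groupby(["group", "category"])
        .size()
        .unstack(fill_value=0)
        .reindex(columns=CATEGORIES, fill_value=0)
        .sort_index()
        .astype(int)
    )
    return by_category, by_group
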