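"""Grazing-history index (GHI) for semi-natural grassland plots.

Grassland indicator species are classified by how their abundance changes
during the three successional phases (T1 early, T2 intermediate, T3 late)
that follow grazing abandonment:

* category A — strong decline or local extinction already in the early phase,
* category B — possibly stable or increasing early, decline or extinction in
  the intermediate phase,
* category C — increase during the early and intermediate phases, decline
  only in the long term.

Every admissible phase-change combination (a triple of codes from
``dead < -2 < -1 < X < +1 < +2``) is ranked by how early its regression sets
in and projected linearly onto a 0-100 scale: the combination that collapses
first (the most grazing-dependent trajectory, the strongest signal of recent
management) maps to 100, the most persistent one to 0.  A plot's GHI is the
mean of the values of the indicator species present, so recently grazed plots
— where even the most sensitive indicators survive — score high, and
long-abandoned plots score low.

The admissible combinations per category ship as an editable CSV
(``data/ghi_rules_synthetic_default.csv``).  The default file is a synthetic
stand-in constructed from the category definitions above, not a transcription
of the original published indicator tables; users reproducing a particular
indicator system should supply their own rules file in the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

#: Phase-change codes in ranking order: extinction sorts before strong
#: decline, unchanged before increase.
PHASE_CODES = ("dead", "-2", "-1", "X", "+1", "+2")
_PHASE_ORDER = {c: i for i, c in enumerate(PHASE_CODES)}

CATEGORIES = ("A", "B", "C")


@dataclass(frozen=True)
class GhiCombination:
    """One admissible trajectory with its rank and 0-100 value."""

    category: str
    phases: tuple[str, str, str]
    rank: int
    value: float


def load_rules(path: str | Path | None = None) -> pd.DataFrame:
    """Load an admissible-combination rules table (category, t1, t2, t3)."""
    if path is None:
        ref = resources.files("islandveg") / "data" / "ghi_rules_synthetic_default.csv"
        with resources.as_file(ref) as p:
            rules = pd.read_csv(p, dtype=str)
    else:
        rules = pd.read_csv(path, dtype=str)
    required = {"category", "t1", "t2", "t3"}
    if not required.issubset(rules.columns):
        raise ValueError(f"rules file needs columns {sorted(required)}")
    return rules


def enumerate_combinations(
    rules: pd.DataFrame, invert_scale: bool = False
) -> list[GhiCombination]:
    """Rank all admissible combinations and project them onto 0-100.

    Combinations are ordered by increasing persistence: primary key is the
    sum of phase-code ordinals (``dead``=0 ... ``+2``=5), ties broken
    lexicographically by the phase triple in code order.  Rank 1 maps to 100
    and rank K to 0 (inverted when ``invert_scale``).
    """
    if len(rules) == 0:
        raise ValueError("empty rule set")
    triples: list[tuple[str, tuple[str, str, str]]] = []
    seen = set()
    for _, row in rules.iterrows():
        cat = str(row["category"]).strip()
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        phases = tuple(str(row[c]).strip() for c in ("t1", "t2", "t3"))
        for p in phases:
            if p not in _PHASE_ORDER:
                raise ValueError(f"unknown phase code {p!r}")
        key = (cat, phases)
        if key in seen:
            continue
        seen.add(key)
        triples.append(key)

    def sort_key(item: tuple[str, tuple[str, str, str]]):
        _, phases = item
        ordinals = tuple(_PHASE_ORDER[p] for p in phases)
        return (sum(ordinals), ordinals)

    triples.sort(key=sort_key)
    k = len(triples)
    out = []
    for i, (cat, phases) in enumerate(triples, start=1):
        out.append(
            GhiCombination(cat, phases, i, project_to_scale(i, k, invert_scale))
        )
    return out


def project_to_scale(rank: int, k: int, invert: bool = False) -> float:
    """Linear projection of rank 1..K onto [0, 100]; rank 1 -> 100, K -> 0."""
    if k < 2:
        raise ValueError("need at least two combinations to span the scale")
    if not 1 <= rank <= k:
        raise ValueError(f"rank {rank} outside 1..{k}")
    value = 100.0 * (k - rank) / (k - 1)
    return 100.0 - value if invert else value


@dataclass
class GhiTable:
    """Species-level grazing-history values for the indicator taxa."""

    values: pd.Series  # taxon -> value in [0, 100]
    categories: pd.Series  # taxon -> A | B | C

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("indicator taxa must have exactly one value each")
        bad = self.values[(self.values < 0) | (self.values > 100)]
        if len(bad):
            raise ValueError(f"values outside [0, 100]: {bad.to_dict()}")


def build_ghi_table(
    assignments: pd.DataFrame,
    rules: pd.DataFrame | None = None,
    invert_scale: bool = False,
) -> GhiTable:
    """Attach a 0-100 value to every indicator taxon.

    ``assignments`` needs columns taxon, category and may carry t1, t2, t3 to
    pin a taxon to a specific trajectory; taxa without an explicit trajectory
    get the median-ranked combination of their category.
    """
    if rules is None:
        rules = load_rules()
    combos = enumerate_combinations(rules, invert_scale=invert_scale)
    by_phases = {(c.category, c.phases): c.value for c in combos}
    by_category: dict[str, list[float]] = {}
    for c in combos:
        by_category.setdefault(c.category, []).append(c.value)

    values, cats = {}, {}
    for _, row in assignments.iterrows():
        taxon, cat = row["taxon"], str(row["category"]).strip()
        if cat not in by_category:
            raise ValueError(f"taxon {taxon!r}: category {cat!r} has no combinations")
        if {"t1", "t2", "t3"}.issubset(assignments.columns) and pd.notna(row.get("t1")):
            phases = tuple(str(row[c]).strip() for c in ("t1", "t2", "t3"))
            try:
                values[taxon] = by_phases[(cat, phases)]
            except KeyError:
                raise ValueError(
                    f"taxon {taxon!r}: trajectory {phases} not admissible for {cat}"
                ) from None
        else:
            values[taxon] = float(np.median(by_category[cat]))
        cats[taxon] = cat
    return GhiTable(pd.Series(values, name="ghi_value"), pd.Series(cats, name="category"))


def plot_ghi(
    cover: pd.Series,
    table: GhiTable,
    habitat: str = "grassland",
    cover_weighted: bool = False,
) -> float:
    """GHI of one plot: mean species-level value over indicators present.

    Defined for grassland plots only.  Returns NaN when no indicator taxon
    occurs in the plot.  ``cover_weighted`` switches from the unweighted mean
    to a cover-weighted mean.
    """
    if habitat != "grassland":
        raise ValueError(f"GHI is defined for grassland plots, not {habitat!r}")
    present = cover[cover > 0]
    indicators = present.index.intersection(table.values.index)
    if len(indicators) == 0:
        return float("nan")
    vals = table.values.loc[indicators].astype(float)
    if cover_weighted:
        w = present.loc[indicators].astype(float)
        return float(np.sum(vals * w) / np.sum(w))
    return float(vals.mean())
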