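"""Community and environment data model for plot-based vegetation surveys.

The analyses in this package operate on two aligned tables: a plot x species
cover matrix (:class:`CommunityMatrix`) recorded on an ordinal cover-abundance
scale, and a plot x variable environment table grouped into named variable-sets
(:class:`VariableSetMap`).  This module holds the cover-scale dialects, the
readers/writers for the CSV exchange formats, and the standard preprocessing
transforms: arcsine-square-root transformation of cover proportions,
proportional down-weighting of rare species, per-habitat min-max scaling of
predictors, and a pairwise-correlation screen for collinear predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HABITATS = ("rocky_shore", "grassland", "forest")

#: Variable-set membership following the study design: local sets describe
#: the plot itself, landscape sets the surrounding seascape.
DEFAULT_VARIABLE_SETS: dict[str, tuple[str, str]] = {
    # variable -> (set name, scope)
    "REGION_B": ("region", "local"),
    "REGION_S": ("region", "local"),
    "ELEV": ("topography", "local"),
    "EAST": ("topography", "local"),
    "NOR": ("topography", "local"),
    "SLO": ("topography", "local"),
    "SKEL": ("soil_morphology", "local"),
    "SOIL_D": ("soil_morphology", "local"),
    "TYPE_CL": ("soil_morphology", "local"),
    "TYPE_SN": ("soil_morphology", "local"),
    "TYPE_RO": ("soil_morphology", "local"),
    "COND": ("soil_fertility", "local"),
    "CN": ("soil_fertility", "local"),
    "P": ("soil_fertility", "local"),
    "PH": ("soil_fertility", "local"),
    "EIV_M": ("soil_water", "local"),
    "OPEN": ("light_availability", "local"),
    "GHI": ("grazing_history", "local"),
    "VEG_A": ("vegetated_area", "local"),
    "DMI": ("distance", "landscape"),
    "PROX": ("distance", "landscape"),
    "REI": ("distance", "landscape"),
    "HAB_A": ("island_configuration", "landscape"),
    "ISL_A": ("island_configuration", "landscape"),
    "R_COV": ("island_configuration", "landscape"),
    "T_COV": ("island_configuration", "landscape"),
}

#: 0/1 indicator columns that are exempt from min-max scaling.
DUMMY_VARIABLES = frozenset(
    {"REGION_B", "REGION_S", "TYPE_CL", "TYPE_SN", "TYPE_RO"}
)


class CoverScaleError(ValueError):
    """Unknown cover code or malformed cover value."""


@dataclass(frozen=True)
class CoverCode:
    """One step of an ordinal cover-abundance scale.

    ``upper`` is the upper bound of the cover-class interval the code denotes;
    ``midpoint`` is the class midpoint used as the quantitative cover value.
    """

    code: str
    midpoint: float
    upper: float


@dataclass(frozen=True)
class CoverScale:
    """An ordinal cover-abundance scale dialect.

    The default dialect is the extended nine-step scale (r, +, 1, 2m, 2a, 2b,
    3, 4, 5) with class midpoints expressed as cover proportions.  Midpoints
    must strictly increase along the scale and lie in (0, 1].
    """

    name: str
    codes: tuple[CoverCode, ...]

    def __post_init__(self) -> None:
        mids = [c.midpoint for c in self.codes]
        if any(not (0.0 < m <= 1.0) for m in mids):
            raise CoverScaleError("cover midpoints must lie in (0, 1]")
        if any(b <= a for a, b in zip(mids, mids[1:])):
            raise CoverScaleError("cover midpoints must strictly increase")

    @property
    def mapping(self) -> dict[str, float]:
        return {c.code: c.midpoint for c in self.codes}

    def parse(self, code: str) -> float:
        """Return the midpoint proportion for an ordinal cover ``code``."""
        try:
            return self.mapping[str(code).strip()]
        except KeyError:
            raise CoverScaleError(
                f"unknown cover code {code!r} for scale {self.name!r}"
            ) from None

    def discretize(self, p: float) -> str | None:
        """Return the code whose class interval contains proportion ``p``.

        Zero cover returns ``None`` (absence: no record is emitted).
        """
        if not 0.0 <= p <= 1.0:
            raise CoverScaleError(f"cover proportion {p} outside [0, 1]")
        if p == 0.0:
            return None
        for c in self.codes:
            if p <= c.upper:
                return c.code
        return self.codes[-1].code


#: Extended Braun-Blanquet scale with 2m/2a/2b subdivision; midpoints are
#: class-interval midpoints, with conventional minimal covers for r and +.
DEFAULT_SCALE = CoverScale(
    name="braun-blanquet-extended",
    codes=(
        CoverCode("r", 0.001, 0.002),
        CoverCode("+", 0.005, 0.01),
        CoverCode("1", 0.025, 0.04),
        CoverCode("2m", 0.05, 0.06),
        CoverCode("2a", 0.10, 0.15),
        CoverCode("2b", 0.205, 0.26),
        CoverCode("3", 0.375, 0.50),
        CoverCode("4", 0.625, 0.75),
        CoverCode("5", 0.875, 1.00),
    ),
)


def parse_cover_code(code: str, dialect: CoverScale = DEFAULT_SCALE) -> float:
    """Translate an ordinal cover code into its class-midpoint proportion.

    Percentages recorded directly (e.g. ``"12.5"`` meaning 12.5 % cover) are
    accepted as well and divided by 100, since deposited datasets sometimes
    store percentages instead of scale codes.
    """
    text = str(code).strip()
    if text in dialect.mapping:
        return dialect.mapping[text]
    try:
        value = float(text)
    except ValueError:
        raise CoverScaleError(
            f"unknown cover code {code!r} for scale {dialect.name!r}"
        ) from None
    if not 0.0 <= value <= 100.0:
        raise CoverScaleError(f"cover percentage {value} outside [0, 100]")
    return value / 100.0


@dataclass
class CommunityMatrix:
    """Plot x species cover proportions with per-plot metadata.

    ``cover`` is a DataFrame indexed by plot id with one column per taxon,
    entries are cover proportions in [0, 1] (or transformed values after
    :func:`arcsine_sqrt_transform`).  ``meta`` is indexed identically and
    carries ``region``, ``island`` and ``habitat`` for every plot.
    """

    cover: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.cover.index.duplicated().any():
            raise ValueError("duplicate plot identifiers in community matrix")
        if (self.cover.values < 0).any():
            raise ValueError("negative cover entries")
        missing = self.cover.index.difference(self.meta.index)
        if len(missing):
            raise ValueError(f"plots missing metadata: {list(missing)[:5]}")
        for col in ("region", "island", "habitat"):
            if col not in self.meta.columns:
                raise ValueError(f"plot metadata lacks column {col!r}")
        self.meta = self.meta.loc[self.cover.index]

    @property
    def plots(self) -> pd.Index:
        return self.cover.index

    @property
    def species(self) -> pd.Index:
        return self.cover.columns

    def subset_habitat(self, habitat: str) -> "CommunityMatrix":
        keep = self.meta.index[self.meta["habitat"] == habitat]
        cov = self.cover.loc[keep]
        cov = cov.loc[:, cov.sum(axis=0) > 0]
        return CommunityMatrix(cov, self.meta.loc[keep])

    def drop_empty_plots(self) -> "CommunityMatrix":
        keep = self.cover.index[self.cover.sum(axis=1) > 0]
        return CommunityMatrix(self.cover.loc[keep], self.meta.loc[keep])


@dataclass
class VariableSetMap:
    """Assignment of every environment variable to one named variable-set."""

    sets: dict[str, str]
    scope: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var in self.sets:
            self.scope.setdefault(var, "local")
        bad = [v for v, s in self.scope.items() if s not in ("local", "landscape")]
        if bad:
            raise ValueError(f"scope must be local|landscape, got {bad}")

    @classmethod
    def default(cls, habitat: str | None = None) -> "VariableSetMap":
        """The study's variable-set map, restricted to one habitat if given.

        Grazing history applies only to grassland, vegetated area only to the
        rocky shore, and soil-type dummies are undefined on the rocky shore.
        """
        sets = {v: s for v, (s, _) in DEFAULT_VARIABLE_SETS.items()}
        scope = {v: sc for v, (_, sc) in DEFAULT_VARIABLE_SETS.items()}
        if habitat is not None:
            if habitat not in HABITATS:
                raise ValueError(f"unknown habitat {habitat!r}")
            drop: set[str] = set()
            if habitat != "grassland":
                drop.add("GHI")
            if habitat != "rocky_shore":
                drop.add("VEG_A")
            if habitat == "rocky_shore":
                drop |= {"TYPE_CL", "TYPE_SN", "TYPE_RO"}
            sets = {v: s for v, s in sets.items() if v not in drop}
            scope = {v: s for v, s in scope.items() if v not in drop}
        return cls(sets, scope)

    def variables_of(self, set_name: str) -> list[str]:
        return [v for v, s in self.sets.items() if s == set_name]

    def set_of(self, variable: str) -> str:
        try:
            return self.sets[variable]
        except KeyError:
            raise KeyError(f"variable {variable!r} not mapped to a set") from None

    @property
    def set_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.sets.values():
            if s not in seen:
                seen.append(s)
        return seen


def build_community_matrix(
    records: pd.DataFrame,
    plot_table: pd.DataFrame,
    dialect: CoverScale = DEFAULT_SCALE,
) -> CommunityMatrix:
    """Pivot a long-format releve table into a wide community matrix.

    ``records`` needs columns plot_id, taxon, cover_code; ``plot_table`` needs
    plot_id, island_id, region, habitat.  Absences become zeros.
    """
    required = {"plot_id", "taxon", "cover_code"}
    if not required.issubset(records.columns):
        raise ValueError(f"releve table needs columns {sorted(required)}")
    if len(records) == 0:
        raise ValueError("empty releve table: no plots to build")
    dup = records.duplicated(subset=["plot_id", "taxon"])
    if dup.any():
        pairs = records.loc[dup, ["plot_id", "taxon"]].values[:5].tolist()
        raise ValueError(f"duplicate (plot, species) records: {pairs}")
    values = records["cover_code"].map(lambda c: parse_cover_code(c, dialect))
    wide = (
        records.assign(_cover=values)
        .pivot(index="plot_id", columns="taxon", values="_cover")
        .fillna(0.0)
    )
    meta = plot_table.set_index("plot_id") if "plot_id" in plot_table.columns else plot_table
    meta = meta.rename(columns={"island_id": "island"})
    absent = wide.index.difference(meta.index)
    if len(absent):
        raise ValueError(f"plots without metadata: {list(absent)[:5]}")
    return CommunityMatrix(wide, meta.loc[wide.index])


def arcsine_sqrt_transform(m: CommunityMatrix) -> CommunityMatrix:
    """Apply y = arcsin(sqrt(p)) to every cover proportion.

    The transform is monotone, maps 0 to 0 and 1 to pi/2, and stabilises the
    variance of proportion data before correspondence analysis.
    """
    vals = m.cover.values
    if (vals < 0).any() or (vals > 1).any():
        raise ValueError("cover entries must lie in [0, 1] before transforming")
    return CommunityMatrix(
        pd.DataFrame(
            np.arcsin(np.sqrt(vals)), index=m.cover.index, columns=m.cover.columns
        ),
        m.meta.copy(),
    )


def downweight_rare_species(m: CommunityMatrix) -> pd.Series:
    """Proportional down-weighting of infrequent species.

    Species occurring in fewer than ``f_max/5`` plots (f_max the highest
    occurrence frequency in the matrix) get weight ``f / (f_max/5)``; all
    others weight 1.  All-zero species get weight 0 with a warning.
    """
    if m.cover.size == 0:
        raise ValueError("empty community matrix")
    freq = (m.cover.values > 0).sum(axis=0).astype(float)
    f_max = freq.max()
    if f_max == 0:
        raise ValueError("community matrix has no occurrences")
    thresh = f_max / 5.0
    weights = np.where(freq < thresh, freq / thresh, 1.0)
    if (freq == 0).any():
        warnings.warn(
            f"{int((freq == 0).sum())} all-zero species receive weight 0",
            stacklevel=2,
        )
    return pd.Series(weights, index=m.cover.columns, name="weight")


def minmax_scale(
    env: pd.DataFrame,
    dummy_columns: Iterable[str] = DUMMY_VARIABLES,
) -> pd.DataFrame:
    """Scale every numeric column to [0, 1] as (x - min) / (max - min).

    Call this on the plot subset of a single habitat — scaling is defined
    within habitat.  0/1 dummy columns pass through unchanged.  A constant
    column is an error (its scaled value would be undefined).
    """
    dummy_columns = set(dummy_columns)
    out = env.copy()
    for col in env.columns:
        if col in dummy_columns:
            vals = set(pd.unique(env[col].dropna()))
            if not vals <= {0, 1, 0.0, 1.0}:
                raise ValueError(f"dummy column {col!r} is not 0/1")
            continue
        x = env[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(f"constant column {col!r} cannot be min-max scaled")
        out[col] = (x - lo) / (hi - lo)
    return out


def collinearity_screen(
    env: pd.DataFrame,
    priority: Sequence[str],
    threshold: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the lower-priority member of every strongly correlated pair.

    ``priority`` orders variables by ecological significance (first = most
    important, kept on conflict).  A pair conflicts when Pearson |r| is
    strictly greater than ``threshold``.  Returns the reduced table and a log
    of dropped variables with the correlated partner and r.
    """
    numeric = [c for c in env.columns if pd.api.types.is_numeric_dtype(env[c])]
    if len(numeric) < 2:
        raise ValueError("need at least two numeric columns to screen")
    corr = env[numeric].corr(method="pearson")
    rank = {v: i for i, v in enumerate(priority)}

    kept: list[str] = []
    log_rows: list[dict] = []
    ordered = sorted(numeric, key=lambda v: rank.get(v, np.inf))
    for var in ordered:
        conflict = None
        for k in kept:
            r = corr.loc[var, k]
            if np.isfinite(r) and abs(r) > threshold:
                conflict = (k, r)
                break
        if conflict is None:
            kept.append(var)
        else:
            if var not in rank:
                raise ValueError(
                    f"variable {var!r} conflicts with {conflict[0]!r} "
                    "but is missing from the priority list"
                )
            log_rows.append(
                {"dropped": var, "kept": conflict[0], "r": conflict[1]}
            )
    kept_in_order = [c for c in env.columns if c in kept or c not in numeric]
    log = pd.DataFrame(log_rows, columns=["dropped", "kept", "r"])
    return env[kept_in_order], log


# ---------------------------------------------------------------------------
# readers / writers


def write_tables(
    out_dir: str | Path,
    community: CommunityMatrix,
    env: pd.DataFrame | None = None,
    traits: pd.DataFrame | None = None,
    dialect: CoverScale = DEFAULT_SCALE,
) -> dict[str, Path]:
    """Write the CSV exchange bundle (releves, plots, environment, traits).

    Cover proportions are written as ordinal codes via the dialect, so a
    write -> read round trip reproduces the code-midpoint values exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for plot in community.plots:
        vec = community.cover.loc[plot]
        for taxon, p in vec[vec > 0].items():
            rows.append((plot, taxon, dialect.discretize(float(p))))
    releves = pd.DataFrame(rows, columns=["plot_id", "taxon", "cover_code"])
    paths["releves"] = out / "releves.csv"
    releves.to_csv(paths["releves"], index=False)

    plot_table = community.meta.reset_index(names="plot_id").rename(
        columns={"island": "island_id"}
    )[["plot_id", "island_id", "region", "habitat"]]
    paths["plots"] = out / "plots.csv"
    plot_table.to_csv(paths["plots"], index=False)

    if env is not None:
        paths["environment"] = out / "environment.csv"
        env.reset_index(names="plot_id").to_csv(paths["environment"], index=False)
    if traits is not None:
        paths["traits"] = out / "traits.csv"
        traits.to_csv(paths["traits"], index=False)
    return paths


def read_tables(
    in_dir: str | Path, dialect: CoverScale = DEFAULT_SCALE
) -> dict[str, object]:
    """Read the CSV exchange bundle written by :func:`write_tables`."""
    in_dir = Path(in_dir)
    releves_path = in_dir / "releves.csv"
    plots_path = in_dir / "plots.csv"
    for p in (releves_path, plots_path):
        if not p.exists():
            raise FileNotFoundError(p)
    releves = pd.read_csv(releves_path, dtype={"cover_code": str})
    _require_columns(releves, {"plot_id", "taxon", "cover_code"}, releves_path)
    plots = pd.read_csv(plots_path)
    _require_columns(
        plots, {"plot_id", "island_id", "region", "habitat"}, plots_path
    )
    bundle: dict[str, object] = {
        "community": build_community_matrix(releves, plots, dialect)
    }
    env_path = in_dir / "environment.csv"
    if env_path.exists():
        env = pd.read_csv(env_path)
        _require_columns(env, {"plot_id"}, env_path)
        bundle["environment"] = env.set_index("plot_id")
    traits_path = in_dir / "traits.csv"
    if traits_path.exists():
        bundle["traits"] = pd.read_csv(traits_path)
    return bundle


def read_s1_dataset(
    path: str | Path,
    cover_sheet: str | int = 0,
    env_sheet: str | int = 1,
    dialect: CoverScale = DEFAULT_SCALE,
) -> dict[str, object]:
    """Ingest a deposited XLSX workbook (wide plot x species cover + environment).

    Expects a first sheet whose first column is the plot identifier and whose
    remaining columns are taxa holding cover codes or percentages, and a
    second sheet of plot-level environment columns including region, island
    and habitat metadata.  Layout quirks of a particular deposition can be
    accommodated via the sheet arguments.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cover = pd.read_excel(path, sheet_name=cover_sheet, index_col=0)
    env = pd.read_excel(path, sheet_name=env_sheet, index_col=0)
    long_rows = cover.stack().reset_index()
    long_rows.columns = ["plot_id", "taxon", "cover_code"]
    long_rows = long_rows[long_rows["cover_code"].astype(str) != "0"]
    meta_cols = {}
    for name in ("region", "island", "habitat"):
        match = [c for c in env.columns if c.lower() == name or c.lower() == name + "_id"]
        if not match:
            raise ValueError(f"environment sheet lacks a {name!r} column")
        meta_cols[name] = env[match[0]]
    plots = pd.DataFrame(meta_cols)
    plots.index.name = "plot_id"
    community = build_community_matrix(
        long_rows, plots.reset_index().rename(columns={"island": "island_id"}), dialect
    )
    return {"community": community, "environment": env}


def _require_columns(df: pd.DataFrame, required: set[str], path: Path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
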