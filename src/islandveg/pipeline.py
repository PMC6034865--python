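"""Per-habitat analysis workflows and the command-line interface.

Two workflows mirror the study design:

* composition — arcsine-square-root transform, rare-species down-weighting,
  permutation forward selection within each variable-set (region always a
  covariable), a full CCA pooling all surviving variables, gross/net
  variance partitioning (ETV/EMV), and the DCA gradient length;
* diversity — plot richness and Smith-Wilson evenness, [0, 1]-scaled
  predictors, collinearity screen, backward-selected nested random-intercept
  models, marginal/conditional pseudo-R2, and variable-set attribution.

The CLI is a thin shell over the library: ``simulate`` writes a synthetic
dataset bundle, ``analyze-composition`` and ``analyze-diversity`` run the
workflows, ``ghi`` scores grassland plots, ``report`` re-prints saved
tables.  All constants of the study design (alpha = 0.05, 9999 permutations,
|r| > 0.6 collinearity cutoff, 500 m proximity radius, 50 ha mainland
threshold) are surfaced as configurable defaults.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import mixedmodels as mm
from . import ordination as ord_
from . import synthdata
from .diversity import diversity_table
from .vegdata import (
    DUMMY_VARIABLES,
    CommunityMatrix,
    VariableSetMap,
    arcsine_sqrt_transform,
    collinearity_screen,
    downweight_rare_species,
    minmax_scale,
    read_tables,
    write_tables,
)

log = logging.getLogger("islandveg")


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of one analysis run."""

    input_dir: str | None = None
    simulate: bool = False
    habitats: tuple = ("rocky_shore", "grassland", "forest")
    alpha: float = 0.05
    n_perm: int = 9999
    seed: int = 0
    collinearity_threshold: float = 0.6
    outlier_plots: tuple = ()
    out_dir: str = "results"
    cover_weighted_ghi: bool = False
    invert_ghi_scale: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("use at least 99 permutations")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("habitats", "outlier_plots"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _load_bundle(config: AnalysisConfig) -> dict:
    if config.simulate:
        log.info("simulating archipelago dataset, seed=%d", config.seed)
        return synthdata.simulate_archipelago(seed=config.seed)
    if not config.input_dir:
        raise ValueError("either simulate=True or an input directory is required")
    return read_tables(config.input_dir)


def prepare_habitat(
    bundle: dict, habitat: str, config: AnalysisConfig
) -> tuple[CommunityMatrix, pd.DataFrame, VariableSetMap, pd.DataFrame]:
    """Habitat subset, scaled predictors, collinearity screen and set map."""
    community = bundle["community"].subset_habitat(habitat).drop_empty_plots()
    if len(community.plots) < 2:
        raise ValueError(f"habitat {habitat!r} has fewer than 2 plots")
    setmap = VariableSetMap.default(habitat)
    env = bundle["environment"].loc[community.plots]
    # region enters as drop-first dummy coding built from the plot metadata,
    # so the dummies are full-rank within the habitat's region subset
    env = env[[c for c in env.columns if not c.startswith("REGION_")]]
    for c in list(setmap.sets):
        if c.startswith("REGION_"):
            del setmap.sets[c]
            del setmap.scope[c]
    region_dummies = pd.get_dummies(
        community.meta["region"], prefix="REGION", drop_first=True
    ).astype(float)
    env = pd.concat([region_dummies, env], axis=1)
    for col in region_dummies.columns:
        setmap.sets[col] = "region"
        setmap.scope[col] = "local"
    usable = [
        v for v in setmap.sets
        if v in env.columns and env[v].notna().all() and env[v].nunique() > 1
    ]
    # soil-type dummies sum to one; drop the reference level (rock)
    if {"TYPE_CL", "TYPE_SN", "TYPE_RO"} <= set(usable):
        usable.remove("TYPE_RO")
    setmap = VariableSetMap(
        {v: setmap.sets[v] for v in usable},
        {v: setmap.scope[v] for v in usable},
    )
    env = env[usable]
    dummies = (DUMMY_VARIABLES | {c for c in usable if c.startswith("REGION_")}) & set(usable)
    scaled = minmax_scale(env, dummy_columns=dummies)
    # 0/1 design dummies bypass the correlation screen (region is a factor)
    numeric = [c for c in scaled.columns if c not in dummies]
    if len(numeric) >= 2:
        screened_num, drop_log = collinearity_screen(
            scaled[numeric], priority=numeric,
            threshold=config.collinearity_threshold,
        )
        screened = pd.concat(
            [screened_num, scaled[[c for c in scaled.columns if c in dummies]]],
            axis=1,
        )
    else:
        screened, drop_log = scaled, pd.DataFrame(columns=["dropped", "kept", "r"])
    if len(drop_log):
        log.info("%s: collinearity screen dropped %s", habitat,
                 list(drop_log["dropped"]))
    kept = [v for v in usable if v in screened.columns]
    setmap = VariableSetMap(
        {v: setmap.sets[v] for v in kept}, {v: setmap.scope[v] for v in kept}
    )
    return community, screened, setmap, drop_log


def run_composition_analysis(
    bundle: dict, habitat: str, config: AnalysisConfig
) -> dict:
    """Forward selection, full CCA and gross/net partitioning for one habitat."""
    community, env, setmap, drop_log = prepare_habitat(bundle, habitat, config)
    transformed = arcsine_sqrt_transform(community)
    weights = downweight_rare_species(transformed)
    m = transformed.cover
    region_vars = setmap.variables_of("region")
    region_df = env[region_vars] if region_vars else None

    rng = np.random.default_rng(config.seed)
    selections: dict[str, list[str]] = {}
    selection_rows = []
    for set_name in setmap.set_names:
        candidates = setmap.variables_of(set_name)
        if set_name == "region":
            selections[set_name] = candidates
            continue
        result = ord_.forward_select(
            m, env, candidates, covariables=region_df,
            alpha=config.alpha, n_perm=config.n_perm,
            seed=int(rng.integers(2**31 - 1)), species_weights=weights,
        )
        selections[set_name] = result.selected
        for var, p, pa in zip(result.order, result.p_values, result.p_adjusted):
            selection_rows.append(
                {"set": set_name, "variable": var, "p": p, "p_fdr": pa,
                 "selected": var in result.selected}
            )
        if not result.selected:
            log.info("%s: set %s n.s.", habitat, set_name)

    partition = ord_.variance_partition(
        m, selections, env, species_weights=weights
    )
    all_vars = [v for vs in selections.values() for v in vs]
    full = ord_.cca(m, env[all_vars], None, species_weights=weights)
    f_obs, p_full = ord_.permutation_test(
        m, env[all_vars], None, n_perm=min(config.n_perm, 999),
        seed=int(rng.integers(2**31 - 1)), species_weights=weights,
    )
    gradient_length = ord_.dca_gradient_length(m)
    return {
        "habitat": habitat,
        "selection": pd.DataFrame(selection_rows),
        "partition": partition,
        "collinearity": drop_log,
        "total_inertia": full.total_inertia,
        "full_model_inertia": full.canonical_inertia,
        "full_model_etv_pct": 100.0 * full.canonical_inertia / full.total_inertia,
        "pseudo_f": f_obs,
        "p_value": p_full,
        "gradient_length_sd": gradient_length,
        "n_plots": len(community.plots),
        "n_species": len(m.columns),
    }


def run_diversity_analysis(
    bundle: dict, habitat: str, config: AnalysisConfig
) -> dict:
    """Backward-selected LMMs and set attribution for richness and evenness."""
    community, env, setmap, _ = prepare_habitat(bundle, habitat, config)
    meta = community.meta
    if meta["island"].nunique() < 2:
        raise ValueError("diversity models need at least two islands")
    traits = bundle.get("traits")
    moisture = (
        traits.set_index("taxon")["eiv_m"] if traits is not None else None
    )
    div = diversity_table(community, moisture=moisture)
    if config.outlier_plots:
        div = mm.exclude_outliers(div, list(config.outlier_plots))
        env = env.loc[div.index]
        meta = meta.loc[div.index]
        log.info("%s: excluded %d outlier plots", habitat, len(config.outlier_plots))
    predictors = [
        v for v in setmap.sets
        if setmap.sets[v] != "region" and env[v].nunique() > 1
    ]
    X = env[predictors]
    if X.shape[1] + 1 >= len(div):
        raise ValueError(
            f"{habitat}: {X.shape[1]} predictors for {len(div)} plots; "
            "the initial mixed model needs more plots than fixed effects"
        )

    out = {"habitat": habitat, "models": {}}
    for proxy in ("richness", "evenness"):
        y = div[proxy].astype(float)
        ok = y.notna()
        fit, elim = mm.backward_select(
            y[ok].values, X.loc[ok], meta.loc[ok, "region"].values,
            meta.loc[ok, "island"].values, alpha=config.alpha, response=proxy,
        )
        part = mm.set_contributions(fit, setmap)
        out["models"][proxy] = {
            "fit": fit,
            "elimination": elim,
            "partition": part,
            "mr2": part.mr2,
            "cr2": part.cr2,
            "full_model_etv_pct": part.full_model_etv_pct,
        }
    return out


def composition_report(results: dict) -> pd.DataFrame:
    """Flat report table of one composition run (one row per variable-set)."""
    part = results["partition"].copy()
    part.insert(0, "habitat", results["habitat"])
    return part


def diversity_report(results: dict) -> pd.DataFrame:
    rows = []
    for proxy, model in results["models"].items():
        t = model["partition"].table.copy()
        t.insert(0, "habitat", results["habitat"])
        t.insert(1, "proxy", proxy)
        t["mr2"] = model["mr2"]
        t["cr2"] = model["cr2"]
        rows.append(t)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def cli(verbose: bool) -> None:
    """Plot-scale island vegetation analysis."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(name)s %(levelname)s %(message)s",
    )


@cli.command()
@click.option("--seed", type=int, required=True)
@click.option("--out", "out_dir", type=click.Path(), default="simulated")
def simulate(seed: int, out_dir: str) -> None:
    """Write a synthetic archipelago dataset bundle as CSV."""
    bundle = synthdata.simulate_archipelago(seed=seed)
    paths = write_tables(
        out_dir, bundle["community"], env=bundle["environment"],
        traits=bundle["traits"],
    )
    truth_path = Path(out_dir) / "truth.json"
    truth_path.write_text(json.dumps(bundle["truth"], indent=2, default=str))
    click.echo(f"wrote {', '.join(str(p) for p in paths.values())} and {truth_path}")


def _config_from_options(config_path, **overrides) -> AnalysisConfig:
    cfg = (
        AnalysisConfig.from_yaml(config_path)
        if config_path
        else AnalysisConfig()
    )
    for key, value in overrides.items():
        if value is not None:
            cfg = dataclasses.replace(cfg, **{key: value})
    return cfg


@cli.command("analyze-composition")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--input", "input_dir", type=click.Path())
@click.option("--simulate", "simulate_", is_flag=True, default=None)
@click.option("--habitat", multiple=True)
@click.option("--n-perm", type=int)
@click.option("--alpha", type=float)
@click.option("--seed", type=int)
@click.option("--out", "out_dir", type=click.Path())
def analyze_composition_cmd(config_path, input_dir, simulate_, habitat,
                            n_perm, alpha, seed, out_dir) -> None:
    """Run the per-habitat composition workflow and write report CSVs."""
    cfg = _config_from_options(
        config_path, input_dir=input_dir, simulate=simulate_,
        habitats=tuple(habitat) or None, n_perm=n_perm, alpha=alpha,
        seed=seed, out_dir=out_dir,
    )
    bundle = _load_bundle(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = []
    for hab in cfg.habitats:
        res = run_composition_analysis(bundle, hab, cfg)
        reports.append(composition_report(res))
        res["selection"].to_csv(out / f"selection_{hab}.csv", index=False)
        click.echo(
            f"{hab}: TI={res['total_inertia']:.3f} "
            f"ETV={res['full_model_etv_pct']:.1f}% "
            f"F={res['pseudo_f']:.2f} p={res['p_value']:.4f} "
            f"gradient={res['gradient_length_sd']:.2f} SD"
        )
    pd.concat(reports, ignore_index=True).to_csv(
        out / "composition_partition.csv", index=False
    )
    click.echo(f"reports in {out}")


@cli.command("analyze-diversity")
@click.option("--config", "config_path", type=click.Path(exists=True))
@click.option("--input", "input_dir", type=click.Path())
@click.option("--simulate", "simulate_", is_flag=True, default=None)
@click.option("--habitat", multiple=True)
@click.option("--alpha", type=float)
@click.option("--seed", type=int)
@click.option("--out", "out_dir", type=click.Path())
def analyze_diversity_cmd(config_path, input_dir, simulate_, habitat,
                          alpha, seed, out_dir) -> None:
    """Run the per-habitat diversity (LMM) workflow and write report CSVs."""
    cfg = _config_from_options(
        config_path, input_dir=input_dir, simulate=simulate_,
        habitats=tuple(habitat) or None, alpha=alpha, seed=seed,
        out_dir=out_dir,
    )
    bundle = _load_bundle(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = []
    for hab in cfg.habitats:
        res = run_diversity_analysis(bundle, hab, cfg)
        reports.append(diversity_report(res))
        for proxy, model in res["models"].items():
            click.echo(
                f"{hab}/{proxy}: mR2={model['mr2']:.3f} cR2={model['cr2']:.3f} "
                f"full-model ETV={model['full_model_etv_pct']:.1f}%"
            )
    pd.concat(reports, ignore_index=True).to_csv(
        out / "diversity_partition.csv", index=False
    )
    click.echo(f"reports in {out}")


@cli.command("ghi")
@click.option("--input", "input_dir", type=click.Path(exists=True), required=True)
@click.option("--rules", type=click.Path(exists=True))
@click.option("--out", "out_path", type=click.Path(), default="ghi.csv")
@click.option("--cover-weighted", is_flag=True)
def ghi_cmd(input_dir, rules, out_path, cover_weighted) -> None:
    """Score grassland plots with the grazing-history index."""
    from .ghi import build_ghi_table, load_rules, plot_ghi

    bundle = read_tables(input_dir)
    traits = bundle.get("traits")
    if traits is None or "ghi_category" not in traits.columns:
        raise click.ClickException("traits.csv with a ghi_category column required")
    cats = traits["ghi_category"].astype(str).str.strip()
    has_cat = traits["ghi_category"].notna() & (cats != "") & (cats.str.lower() != "nan")
    assignments = (
        traits[has_cat]
        .rename(columns={"ghi_category": "category"})[["taxon", "category"]]
    )
    table = build_ghi_table(assignments, load_rules(rules))
    community = bundle["community"].subset_habitat("grassland")
    rows = [
        {"plot_id": p,
         "ghi": plot_ghi(community.cover.loc[p], table,
                         cover_weighted=cover_weighted)}
        for p in community.plots
    ]
    pd.DataFrame(rows).to_csv(out_path, index=False)
    click.echo(f"wrote {out_path}")


@cli.command("report")
@click.option("--out", "out_dir", type=click.Path(exists=True), required=True)
def report_cmd(out_dir) -> None:
    """Print saved report tables."""
    out = Path(out_dir)
    found = False
    for name in ("composition_partition.csv", "diversity_partition.csv"):
        path = out / name
        if path.exists():
            found = True
            click.echo(f"== {name} ==")
            click.echo(pd.read_csv(path).to_string(index=False))
    if not found:
        raise click.ClickException(f"no report tables in {out}")
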