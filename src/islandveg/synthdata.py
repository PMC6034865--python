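"""Seeded generator of synthetic archipelago datasets.

The generator emulates the statistical structure the analysis modules
assume: three study regions of islands, up to three plots per habitat per
island, habitat-specific species pools whose members respond unimodally
(Gaussian response curves) to latent environmental gradients, ordinal cover
codes obtained by discretising noisy covers, nested region/island random
intercepts on plot suitability (and hence richness/evenness), grassland
indicator species whose occurrence tracks time since grazing abandonment,
and island geometry plus a directional wind climate from which the landscape
predictors (REI, PROX, DMI, island configuration) are computed with the
:mod:`islandveg.landscape` module.

Every generating parameter is stored in a truth record so that recovery
tests can compare estimates against the known data-generating process.
The generator targets statistical structure, not spatial mechanism: there is
no dispersal, no island biogeography dynamics, and environmental variables
are drawn independently (apart from configurable collinearity) rather than
from a correlated field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from . import landscape as ls
from .diversity import weighted_ellenberg
from .ghi import build_ghi_table, plot_ghi
from .vegdata import (
    DEFAULT_SCALE,
    CommunityMatrix,
    CoverScale,
)

#: Species-pool sizes per habitat (total taxa observed per habitat).
DEFAULT_POOLS = {"rocky_shore": 165, "grassland": 155, "forest": 128}

#: Regions in which each habitat occurs (two habitats are absent from one
#: region each, mirroring a three-archipelago design with partial overlap).
DEFAULT_HABITAT_REGIONS = {
    "rocky_shore": ("R1", "R2", "R3"),
    "grassland": ("R2", "R3"),
    "forest": ("R1", "R2"),
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic archipelago.

    Defaults are chosen so that the full pipeline runs in seconds while
    keeping the study's structure: 3 regions x 10 islands, <= 3 plots per
    habitat per island, habitat pools of 165/155/128 species, two latent
    compositional gradients per habitat (a soil-pH axis and a moisture axis,
    plus the abandonment-time axis for grassland), Gaussian species
    responses with tolerance ~ a quarter of the gradient span, lognormal
    cover noise, and moderate region/island random intercepts.
    """

    n_regions: int = 3
    islands_per_region: int = 10
    plots_per_habitat: int = 3  # per island, upper bound 3
    pools: dict = field(default_factory=lambda: dict(DEFAULT_POOLS))
    habitat_regions: dict = field(
        default_factory=lambda: dict(DEFAULT_HABITAT_REGIONS)
    )
    gradient_span: float = 4.0  # latent gradient range in tolerance units
    tolerance: float = 1.0  # Gaussian response tolerance on the latent scale
    max_cover_range: tuple = (0.05, 0.7)
    noise_sigma: float = 0.5  # lognormal sd of cover noise
    detection_floor: float = 0.002  # covers below this are not recorded
    region_sd: float = 0.5  # random-intercept sd on plot suitability (logit)
    island_sd: float = 0.5
    effect_pH: float = 1.0  # effect of scaled pH on plot suitability
    occupancy_logit: float = 0.8  # baseline of the occurrence-thinning logit
    n_indicators: int = 8  # indicator species per GHI category
    indicator_sharpness: float = 0.08  # occurrence transition width over t
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.plots_per_habitat < 1 or self.plots_per_habitat > 3:
            raise ValueError("plots per habitat per island must be 1..3")
        if self.tolerance <= 0:
            raise ValueError("species tolerance must be positive")
        for sd in (self.region_sd, self.island_sd, self.noise_sigma):
            if sd < 0:
                raise ValueError("standard deviations must be non-negative")


def gaussian_response(x, u: float, t: float, c: float):
    """Expected cover of a species with optimum u, tolerance t, maximum c."""
    if t <= 0:
        raise ValueError("tolerance must be positive")
    if not 0.0 < c <= 1.0:
        raise ValueError("maximum cover must lie in (0, 1]")
    return c * np.exp(-((np.asarray(x, dtype=float) - u) ** 2) / (2.0 * t**2))


def discretize_cover(p: float, dialect: CoverScale = DEFAULT_SCALE) -> str | None:
    """Ordinal cover code whose class interval contains proportion ``p``."""
    return dialect.discretize(p)


def simulate_archipelago(
    config: SimulationConfig | None = None, seed: int | None = None
) -> dict:
    """Generate a full synthetic dataset bundle.

    Returns a dict with ``community`` (:class:`CommunityMatrix` over all
    habitats), ``environment`` (plot x variable table including the derived
    EIV_M and GHI columns), ``traits`` (taxon-level moisture values and GHI
    categories), ``islands``/``wind`` (geometry and wind climate), and
    ``truth`` (every generating parameter).  Identical seeds give identical
    bundles.
    """
    cfg = config or SimulationConfig()
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    rng = np.random.default_rng(seed)

    regions = [f"R{i+1}" for i in range(cfg.n_regions)]
    wind = ls.WindClimate(
        frequency={"N": 0.08, "NE": 0.07, "E": 0.10, "SE": 0.12, "S": 0.15,
                   "SW": 0.25, "W": 0.15, "NW": 0.08},
        speed={"N": 5.0, "NE": 4.5, "E": 5.5, "SE": 6.0, "S": 6.5,
               "SW": 8.0, "W": 7.0, "NW": 5.5},
    )

    islands, mainland = _make_geometry(cfg, regions, rng)
    all_land = islands + [mainland]

    truth: dict = {"seed": int(seed), "config": cfg.__dict__.copy(),
                   "islands": {}, "species": {}, "plots": {}}
    plot_meta_rows, env_rows, releve_frames = [], [], []
    traits_rows = []

    # nested random intercepts on plot suitability
    region_eff = {r: rng.normal(0.0, cfg.region_sd) for r in regions}
    island_eff = {isl.island_id: rng.normal(0.0, cfg.island_sd) for isl in islands}
    truth["region_effects"] = region_eff
    truth["island_effects"] = island_eff

    ghi_assign, ghi_table, indicator_names = _make_indicators(cfg, rng)
    truth["ghi_categories"] = dict(zip(ghi_assign["taxon"], ghi_assign["category"]))

    abandonment = {
        isl.island_id: float(rng.uniform(0.0, 1.0)) for isl in islands
    }
    truth["abandonment_time"] = abandonment

    for habitat, pool_n in cfg.pools.items():
        hab_regions = cfg.habitat_regions.get(habitat, tuple(regions))
        species = [f"{habitat[:2]}_sp{i+1:03d}" for i in range(pool_n)]
        # species optima over a 2-d latent gradient box (pH axis, moisture axis)
        span = cfg.gradient_span
        u1 = rng.uniform(-0.5, span + 0.5, pool_n)
        u2 = rng.uniform(-0.5, span + 0.5, pool_n)
        cmax = rng.uniform(*cfg.max_cover_range, pool_n)
        moisture_trait = np.clip(
            1.0 + 11.0 * u2 / span + rng.normal(0, 0.8, pool_n), 1.0, 12.0
        )
        # grassland: a third niche axis along abandonment time
        u3 = rng.uniform(0.0, 1.0, pool_n)
        truth["species"][habitat] = {
            "names": species, "u_pH": u1.tolist(), "u_moist": u2.tolist(),
            "u_abandon": u3.tolist(), "c_max": cmax.tolist(),
            "tolerance": cfg.tolerance,
        }
        for s, mtrait in zip(species, moisture_trait):
            traits_rows.append(
                {"taxon": s, "eiv_m": float(mtrait),
                 "ghi_category": truth["ghi_categories"].get(s, "")}
            )

        for isl in islands:
            region = isl.island_id.split("-")[0]
            if region not in hab_regions:
                continue
            for k in range(cfg.plots_per_habitat):
                plot_id = f"{isl.island_id}-{habitat[:2]}{k+1}"
                env, xy = _draw_environment(
                    habitat, isl, all_land, wind, rng, cfg
                )
                pH_scaled = (env["PH"] - 4.0) / 3.5
                g1 = pH_scaled * cfg.gradient_span
                g2 = rng.uniform(0.0, cfg.gradient_span)  # latent moisture
                t_ab = float(np.clip(
                    abandonment[isl.island_id] + rng.normal(0, 0.03), 0, 1
                ))
                suit = (
                    region_eff[region]
                    + island_eff[isl.island_id]
                    + cfg.effect_pH * (pH_scaled - 0.5)
                )
                mu = cmax * np.exp(
                    -((g1 - u1) ** 2) / (2 * cfg.tolerance**2)
                    - ((g2 - u2) ** 2) / (2 * cfg.tolerance**2)
                )
                if habitat == "grassland":
                    mu = mu * np.exp(-((t_ab - u3) ** 2) / (2 * 0.35**2))
                # suitability shifts occurrence via thinning
                keep_p = 1.0 / (1.0 + np.exp(-(suit + cfg.occupancy_logit)))
                present = rng.uniform(size=pool_n) < keep_p
                noise = rng.lognormal(0.0, cfg.noise_sigma, pool_n)
                cover = np.clip(mu * noise * present, 0.0, 1.0)
                cover[cover < cfg.detection_floor] = 0.0
                if habitat == "grassland":
                    cover = _overlay_indicators(
                        cover, species, indicator_names, t_ab, cfg, rng
                    )
                if not (cover > 0).any():
                    # guarantee the every-plot-nonempty invariant
                    cover[int(rng.integers(pool_n))] = 0.025
                codes = {
                    sp: DEFAULT_SCALE.discretize(float(cv))
                    for sp, cv in zip(species, cover)
                    if cv > 0
                }
                releve_frames.append(
                    pd.DataFrame(
                        {"plot_id": plot_id, "taxon": list(codes),
                         "cover_code": list(codes.values())}
                    )
                )
                plot_meta_rows.append(
                    {"plot_id": plot_id, "island_id": isl.island_id,
                     "region": region, "habitat": habitat}
                )
                env_rows.append({"plot_id": plot_id, **env})
                truth["plots"][plot_id] = {
                    "g_pH": float(g1), "g_moist": float(g2),
                    "abandonment": t_ab, "suitability": float(suit),
                }

    releves = pd.concat(releve_frames, ignore_index=True)
    plots = pd.DataFrame(plot_meta_rows)
    meta = plots.set_index("plot_id").rename(columns={"island_id": "island"})
    # build the community matrix from the discretised codes (midpoints)
    from .vegdata import build_community_matrix

    community = build_community_matrix(releves, plots)
    env_table = pd.DataFrame(env_rows).set_index("plot_id").loc[community.plots]
    traits = pd.DataFrame(traits_rows)

    # derived predictors from the community itself
    moisture = traits.set_index("taxon")["eiv_m"]
    eiv = []
    ghi_vals = []
    for plot in community.plots:
        vec = community.cover.loc[plot]
        eiv.append(
            weighted_ellenberg(vec.values, moisture.reindex(vec.index).values)
        )
        if meta.loc[plot, "habitat"] == "grassland":
            ghi_vals.append(plot_ghi(vec, ghi_table))
        else:
            ghi_vals.append(np.nan)
    env_table["EIV_M"] = eiv
    env_table["GHI"] = ghi_vals
    # region dummies (first region is the reference level)
    for r in regions[1:]:
        env_table[f"REGION_{r[-1]}"] = (
            meta.loc[community.plots, "region"] == r
        ).astype(float)

    return {
        "community": community,
        "environment": env_table,
        "traits": traits,
        "islands": islands,
        "mainland": mainland,
        "wind": wind,
        "ghi_table": ghi_table,
        "truth": truth,
    }


def simulate_lmm_dataset(
    n_regions: int = 3,
    islands_per_region: int = 10,
    plots_per_island: int = 3,
    beta: dict | None = None,
    sigma_region: float = 0.5,
    sigma_island: float = 0.5,
    sigma_resid: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Direct generator of nested random-intercept data for model recovery.

    ``beta`` maps predictor names to slopes; predictors are iid Uniform(0, 1)
    (the common scale of the analysis pipeline).  Returns a tidy frame with
    y, the predictors, region and island columns.
    """
    rng = np.random.default_rng(seed)
    beta = beta or {}
    rows = []
    for r in range(n_regions):
        a_r = rng.normal(0.0, sigma_region)
        for i in range(islands_per_region):
            a_i = rng.normal(0.0, sigma_island)
            for p in range(plots_per_island):
                x = {name: rng.uniform() for name in beta}
                y = (
                    sum(b * x[name] for name, b in beta.items())
                    + a_r + a_i + rng.normal(0.0, sigma_resid)
                )
                rows.append(
                    {"y": y, **x, "region": f"R{r+1}", "island": f"R{r+1}-I{i+1:02d}"}
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internals


def _make_geometry(cfg, regions, rng):
    islands = []
    for ri, region in enumerate(regions):
        x0 = ri * 60_000.0
        for ii in range(cfg.islands_per_region):
            area = float(rng.lognormal(np.log(20_000.0), 1.0))
            area = min(area, 4.9e5)  # sampled islands stay below 50 ha
            radius = np.sqrt(area / np.pi)
            x = x0 + rng.uniform(2_000.0, 20_000.0)
            y = rng.uniform(2_000.0, 20_000.0)
            isl = ls.IslandGeometry.circle(
                f"{region}-I{ii+1:02d}", x, y, radius,
                rock_cover=float(rng.uniform(5, 90)),
                tree_cover=float(rng.uniform(0, 85)),
            )
            # habitats occupy a drawn fraction of the island
            isl.habitat_area = float(rng.uniform(0.1, 0.6)) * isl.area
            islands.append(isl)
    # the mainland is a coastline south of all three regions, so distance to
    # it varies within regions rather than between them
    from shapely.geometry import box

    coast = box(-60_000.0, -30_000.0, cfg.n_regions * 60_000.0 + 30_000.0, 0.0)
    mainland = ls.IslandGeometry("mainland", coast, is_mainland=True)
    return islands, mainland


def _draw_environment(habitat, isl, all_land, wind, rng, cfg):
    """Local variables from plausible ranges; landscape variables from geometry."""
    centre = isl.shape.centroid
    edge_pt = Point(
        centre.x + 0.95 * np.sqrt(isl.area / np.pi), centre.y
    )
    site = edge_pt if habitat == "rocky_shore" else centre
    fetch = ls.fetch_by_ray_casting(
        site, [l for l in all_land], max_fetch=25_000.0, exclude=isl.island_id
    )
    env = {
        "ELEV": float(rng.uniform(0.5, 30.0)),
        "EAST": float(rng.uniform(-1.0, 1.0)),
        "NOR": float(rng.uniform(-1.0, 1.0)),
        "SLO": float(rng.uniform(0.0, 45.0)),
        "SKEL": float(rng.uniform(0.0, 80.0)),
        "SOIL_D": float(rng.uniform(0.01, 0.6)),
        "COND": float(rng.uniform(20.0, 250.0)),
        "CN": float(rng.uniform(10.0, 40.0)),
        "P": float(rng.uniform(5.0, 120.0)),
        "PH": float(rng.uniform(4.0, 7.5)),
        "OPEN": float(
            rng.uniform(5.0, 40.0) if habitat == "forest" else rng.uniform(40.0, 100.0)
        ),
        "REI": ls.rei(wind, fetch),
        "PROX": ls.prox(site, all_land, radius=500.0, exclude=isl.island_id),
        "DMI": ls.dmi(isl, all_land),
        **ls.island_config(isl),
    }
    if habitat != "rocky_shore":
        soil = rng.choice(["CL", "SN", "RO"])
        for t in ("CL", "SN", "RO"):
            env[f"TYPE_{t}"] = 1.0 if soil == t else 0.0
    if habitat == "rocky_shore":
        env["VEG_A"] = float(rng.uniform(0.1, 6.0))
    return env, site


def _make_indicators(cfg, rng):
    """Indicator taxa (grassland pool members) with A/B/C categories."""
    names = {
        "A": [f"gr_sp{i+1:03d}" for i in range(cfg.n_indicators)],
        "B": [f"gr_sp{i+1:03d}" for i in range(cfg.n_indicators, 2 * cfg.n_indicators)],
        "C": [f"gr_sp{i+1:03d}" for i in range(2 * cfg.n_indicators, 3 * cfg.n_indicators)],
    }
    rows = [
        {"taxon": t, "category": cat}
        for cat, taxa in names.items()
        for t in taxa
    ]
    assignments = pd.DataFrame(rows)
    table = build_ghi_table(assignments)
    return assignments, table, names


def _overlay_indicators(cover, species, indicator_names, t_ab, cfg, rng):
    """Impose the category occurrence trajectories on the indicator taxa.

    Occurrence probability declines sigmoidally with abandonment time t, with
    category-specific transition points: A species vanish early (t ~ 0.25),
    B in the medium term (t ~ 0.55), while C species decline only beyond the
    observed window (t ~ 1.2), so every grassland plot retains at least some
    indicators and GHI is defined throughout.
    """
    thresholds = {"A": 0.25, "B": 0.55, "C": 1.2}
    index = {s: i for i, s in enumerate(species)}
    cover = cover.copy()
    for cat, taxa in indicator_names.items():
        thr = thresholds[cat]
        p_occ = 0.9 / (1.0 + np.exp((t_ab - thr) / cfg.indicator_sharpness))
        for taxon in taxa:
            i = index[taxon]
            if rng.uniform() < p_occ:
                if cover[i] <= 0:
                    cover[i] = float(
                        np.clip(rng.lognormal(np.log(0.03), 0.5), 0.005, 0.5)
                    )
            else:
                cover[i] = 0.0
    return cover
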