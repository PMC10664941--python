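"""Seeded synthetic mini-country generator.

Produces, from a single :class:`LandscapeConfig`, every input the risk
pipeline consumes: rasters (elevation, landcover, roads), an enumeration-
area (EA) table tiled over the grid with archetype-conditional covariates,
per-species suitability surfaces with occurrence points, treating-facility
locations, and a case registry whose per-EA counts follow a Poisson
log-linear model with a planted elevation effect.

Everything is driven by ``numpy.random.Generator`` streams derived from
``config.rng_seed``, so identical configs give bit-identical output.
"""

from __future__ import annotations

import calendar
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .grid import GridLayer, require_same_grid

ARCHETYPES = ("urban", "peri_urban", "commercial_protected", "rural_poor")

LANDCOVER_CLASSES = {
    "built_up": 0,
    "cropland": 1,
    "trees": 2,
    "grassland": 3,
    "water_protected": 4,
}
LANDCOVER_NAMES = {v: k for k, v in LANDCOVER_CLASSES.items()}

# Archetype-conditional covariate means; columns follow ARCHETYPES order.
# Separation between archetype means is deliberately large relative to the
# within-archetype noise so that cluster-recovery experiments have planted
# structure to find.
_COVARIATE_MEANS = {
    #                         urban  peri  comm  rural
    "poverty":               (0.10, 0.32, 0.30, 0.72),
    "prop_firewood":         (0.05, 0.28, 0.35, 0.82),
    "prop_candles_paraffin": (0.04, 0.22, 0.30, 0.72),
    "prop_elderly":          (0.035, 0.05, 0.05, 0.095),
    "prop_children_youth":   (0.28, 0.38, 0.34, 0.48),
    "building_density":      (320.0, 130.0, 15.0, 55.0),
    "building_occupancy":    (4.5, 4.0, 2.8, 5.6),
    "population":            (2000.0, 3800.0, 160.0, 950.0),
}
_COVARIATE_SD = {
    "poverty": 0.03,
    "prop_firewood": 0.03,
    "prop_candles_paraffin": 0.03,
    "prop_elderly": 0.008,
    "prop_children_youth": 0.025,
    "building_density": 15.0,
    "building_occupancy": 0.25,
    "population": 100.0,
}
_PROPORTION_VARS = (
    "poverty", "prop_firewood", "prop_candles_paraffin",
    "prop_elderly", "prop_children_youth",
)
_POULTRY_PROB = {"urban": 0.05, "peri_urban": 0.9,
                 "commercial_protected": 0.05, "rural_poor": 0.9}
# Multiplicative archetype effect on the case rate. Neutral by default:
# archetype assignment follows the landcover raster and therefore
# correlates with elevation, so a non-neutral multiplier would confound
# the planted elevation effect. Per-capita counts still separate the
# archetypes through the population means above.
_ARCHETYPE_RATE_MULT = {"urban": 1.0, "peri_urban": 1.0,
                        "commercial_protected": 1.0, "rural_poor": 1.0}


def _truncated_geometric_pmf(p: float, k_max: int = 25) -> np.ndarray:
    k = np.arange(1, k_max + 1)
    pmf = (1.0 - p) ** (k - 1) * p
    return pmf / pmf.sum()


def vial_distribution(mean: float = 5.0, k_max: int = 25) -> dict[int, float]:
    """Truncated geometric on 1..k_max with the requested mean."""

    def gap(p: float) -> float:
        pmf = _truncated_geometric_pmf(p, k_max)
        return float(np.arange(1, k_max + 1) @ pmf) - mean

    p = optimize.brentq(gap, 1e-6, 0.999)
    pmf = _truncated_geometric_pmf(p, k_max)
    return {int(k): float(v) for k, v in zip(range(1, k_max + 1), pmf)}


def default_attribute_tables() -> dict[str, dict]:
    """Default categorical case-attribute distributions.

    Calibrated to the registry case mix the pipeline is validated against:
    30% of bites between 18:00 and 22:00, a January peak, 55% cytotoxic
    syndromes, 66% any first aid (83% of those with a tourniquet), 200/932
    antivenom recipients with mean 5 vials on 1..25 and 35% adverse
    reactions, and the printed age/sex/occupation margins.
    """
    hour = {}
    for h in range(24):
        if 18 <= h <= 21:
            hour[h] = 0.075
        elif h <= 5:
            hour[h] = 0.012
        elif h <= 11:
            hour[h] = 0.035
        elif h <= 15:
            hour[h] = 0.045
        elif h <= 17:
            hour[h] = 0.055
        elif h == 22:
            hour[h] = 0.07
        else:
            hour[h] = 0.058
    month = {1: 0.14, 2: 0.11, 3: 0.10, 4: 0.08, 5: 0.06, 6: 0.03,
             7: 0.035, 8: 0.035, 9: 0.07, 10: 0.09, 11: 0.12, 12: 0.13}
    age_band = {
        "0-9": 116 / 932, "10-19": 252 / 932, "20-29": 174 / 932,
        "30-39": 135 / 932, "40-49": 65 / 932, "50-59": 45 / 932,
        "60-69": 23 / 932, "70-79": 17 / 932, "80+": 12 / 932,
        "missing": 93 / 932,
    }
    occupation = {
        "professionals": 7 / 932,
        "technicians_associate_professionals": 2 / 932,
        "clerical_workers": 1 / 932,
        "services_sales_workers": 11 / 932,
        "skilled_agricultural_forestry_fishery": 20 / 932,
        "craft_related_trades": 14 / 932,
        "plant_machine_operators": 2 / 932,
        "elementary_occupations": 65 / 932,
        "armed_forces": 4 / 932,
        "unemployed": 212 / 932,
        "student": 327 / 932,
        "self_employed": 13 / 932,
        "retiree": 33 / 932,
        "pre_school_child": 53 / 932,
        "unknown": 168 / 932,
    }
    syndrome = {
        "asymptomatic": 0.403,
        "mild swelling": 0.300,
        "painful progressive swelling": 0.245,
        "venom ophthalmia": 0.005,
        "progressive weakness": 0.045,
        "bleeding": 0.002,
    }
    bite_site = {
        "lower_extremity": 0.60, "hand_finger_wrist": 0.14,
        "upper_leg": 0.10, "trunk": 0.05, "head_face": 0.03,
        "missing": 0.08,
    }
    activity = {
        "walking": 0.27, "farming": 0.12, "fetching_water": 0.08,
        "playing": 0.10, "sleeping": 0.05, "domestic_work": 0.10,
        "other": 0.08, "missing": 0.20,
    }
    location = {"outdoors": 0.65, "indoors": 0.13, "missing": 0.22}
    sex = {"male": 511 / 932, "female": 421 / 932}
    outcome = {"recovered": 0.93, "died": 10 / 932,
               "long-term impairment": 8 / 932,
               "unknown": 1.0 - 0.93 - 18 / 932}
    return {
        "month": month,
        "hour": hour,
        "age_band": age_band,
        "sex": sex,
        "occupation": occupation,
        "bite_site": bite_site,
        "activity": activity,
        "location": location,
        "syndrome": syndrome,
        "first_aid_any": {True: 0.66, False: 0.34},
        "tourniquet_given_first_aid": {True: 0.83, False: 0.17},
        "incision_given_first_aid": {True: 0.10, False: 0.90},
        "herbal_given_first_aid": {True: 0.20, False: 0.80},
        "bandage_given_first_aid": {True: 0.15, False: 0.85},
        "antivenom": {True: 200 / 932, False: 732 / 932},
        "vials_given_antivenom": vial_distribution(mean=5.0, k_max=25),
        "adrenaline_given_antivenom": {True: 167 / 200, False: 33 / 200},
        "reaction_given_antivenom": {True: 0.35, False: 0.65},
        "outcome": outcome,
    }


@dataclass
class LandscapeConfig:
    """All knobs of the synthetic mini-country."""

    rng_seed: int = 0
    grid_rows: int = 120
    grid_cols: int = 120
    cell_size: float = 500.0
    n_species: int = 11
    n_eas: int = 400
    archetype_mix: tuple[float, float, float, float] = (0.15, 0.25, 0.20, 0.40)
    elevation_range: tuple[float, float] = (71.0, 1499.0)
    elevation_noise: float = 0.15
    elevation_rate_effect: float = 0.038  # proportional rate drop per 100 m
    baseline_rate: float = 4.0           # cases / 1,000 population / year
    period_years: float = 2.0
    period_start_year: int = 2019
    n_facilities: int = 20
    n_urban_seeds: int = 4
    n_presence_points: int = 40
    n_background_points: int = 120
    case_attribute_tables: dict[str, dict] = field(
        default_factory=default_attribute_tables)

    def __post_init__(self) -> None:
        if self.grid_rows < 20 or self.grid_cols < 20:
            raise ValueError("grid dims must be >= 20")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0.0 <= self.elevation_rate_effect < 1.0:
            raise ValueError("elevation_rate_effect must be in [0, 1)")
        mix = np.asarray(self.archetype_mix, dtype=float)
        if mix.shape != (4,):
            raise ValueError("archetype_mix needs 4 proportions")
        if np.any(mix < 0) or np.any(mix > 1):
            raise ValueError("archetype_mix proportions must be in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_mix must sum to 1")
        lo, hi = self.elevation_range
        if not hi > lo:
            raise ValueError("degenerate elevation_range")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        for name, table in self.case_attribute_tables.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"attribute table {name!r} sums to {total}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent named substream of the master seed (stable hash —
        Python's builtin ``hash`` is salted per process)."""
        key = zlib.crc32(stream.encode())
        seed_seq = np.random.SeedSequence(self.rng_seed, spawn_key=(key,))
        return np.random.default_rng(seed_seq)


@dataclass
class EATable:
    """EA attribute table plus the label raster mapping cells to EAs."""

    table: pd.DataFrame
    labels: np.ndarray         # int raster, value = EA index (0..n-1)
    cell_size: float

    @property
    def n_eas(self) -> int:
        return len(self.table)

    def cells_of(self, ea_index: int) -> np.ndarray:
        return np.argwhere(self.labels == ea_index)


@dataclass
class SyntheticTruth:
    """Planted ground truth for recovery tests."""

    archetype: pd.Series              # per EA
    expected_cases: pd.Series         # per EA, over the whole study period
    elevation_coef: float             # log rate-ratio per 100 m
    species_presence: list[np.ndarray] | None = None


# ---------------------------------------------------------------------------
# rasters


def _line_cells(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    n = max(abs(r1 - r0), abs(c1 - c0), 1)
    rows = np.rint(np.linspace(r0, r1, n + 1)).astype(int)
    cols = np.rint(np.linspace(c0, c1, n + 1)).astype(int)
    return list(zip(rows, cols))


def generate_rasters(config: LandscapeConfig) -> dict[str, GridLayer]:
    """Elevation (monotone gradient + smoothed noise, exact range),
    categorical landcover, and a binary road raster joining urban seeds."""
    rng = config.rng("rasters")
    nr, nc = config.grid_rows, config.grid_cols
    lo, hi = config.elevation_range

    base = np.tile(np.linspace(0.0, 1.0, nc), (nr, 1))
    if config.elevation_noise > 0:
        noise = ndimage.gaussian_filter(rng.normal(size=(nr, nc)), sigma=6.0)
        span = np.ptp(noise)
        if span > 0:
            noise = noise / span
        elev = base + config.elevation_noise * noise
    else:
        elev = base
    elev = lo + (elev - elev.min()) / np.ptp(elev) * (hi - lo)

    seeds = [(int(rng.integers(0, nr)), int(rng.integers(0, nc)))
             for _ in range(config.n_urban_seeds)]
    seed_mask = np.zeros((nr, nc), dtype=bool)
    for r, c in seeds:
        seed_mask[r, c] = True
    dist = ndimage.distance_transform_edt(~seed_mask)

    elev_norm = (elev - lo) / (hi - lo)
    smooth = lambda: ndimage.gaussian_filter(  # noqa: E731
        rng.normal(size=(nr, nc)), sigma=4.0)
    scores = np.stack([
        2.5 * np.exp(-dist / 4.0) + 0.3 * smooth(),            # built_up
        0.62 - 0.5 * np.abs(elev_norm - 0.35) + 0.3 * smooth(),  # cropland
        0.25 + 0.45 * elev_norm + 0.3 * smooth(),              # trees
        0.48 + 0.3 * smooth(),                                 # grassland
        0.18 + 0.55 * ndimage.gaussian_filter(                 # water/protected
            rng.normal(size=(nr, nc)), sigma=9.0),
    ])
    landcover_fine = np.argmax(scores, axis=0).astype(np.int16)
    # majority-vote the class over coarse patches (with a sprinkle of the
    # fine-scale class kept) so landuse forms contiguous blocks, as real
    # landscapes do at EA scale
    patch = 6
    landcover = np.empty_like(landcover_fine)
    for i in range(0, nr, patch):
        for j in range(0, nc, patch):
            block = landcover_fine[i:i + patch, j:j + patch]
            vals, freq = np.unique(block, return_counts=True)
            dominant = vals[np.argmax(freq)]
            keep_fine = rng.random(block.shape) < 0.15
            landcover[i:i + patch, j:j + patch] = np.where(
                keep_fine, block, dominant)

    roads = np.zeros((nr, nc), dtype=np.int16)
    for (a, b) in zip(seeds, seeds[1:]):
        for r, c in _line_cells(*a, *b):
            roads[r, c] = 1

    cs = config.cell_size
    return {
        "elevation": GridLayer(elev, cell_size=cs),
        "landcover": GridLayer(landcover, cell_size=cs),
        "roads": GridLayer(roads, cell_size=cs),
    }


# ---------------------------------------------------------------------------
# enumeration areas


def _tile_factors(n_eas: int, nr: int, nc: int) -> tuple[int, int]:
    """Factor pair (block_rows, block_cols) of n_eas closest to the grid
    aspect ratio."""
    best = (1, n_eas)
    best_cost = float("inf")
    for br in range(1, n_eas + 1):
        if n_eas % br:
            continue
        bc = n_eas // br
        if br > nr or bc > nc:
            continue
        cost = abs(np.log((br / bc) / (nr / nc)))
        if cost < best_cost:
            best, best_cost = (br, bc), cost
    if best[0] > nr or best[1] > nc:
        raise ValueError("n_eas too large for grid")
    return best


def _quota_counts(mix, n: int) -> np.ndarray:
    """Largest-remainder allocation of n EAs to the four archetypes."""
    target = np.asarray(mix, dtype=float) * n
    counts = np.floor(target).astype(int)
    remainder = target - counts
    for k in np.argsort(-remainder)[: n - counts.sum()]:
        counts[k] += 1
    return counts


def _assign_archetypes(mix, zonal_props: dict[str, np.ndarray],
                       n: int) -> np.ndarray:
    """Archetypes follow the landscape: the most built-up/roaded EAs become
    urban then peri-urban; of the rest, those dominated by water/protected
    or cropland become commercial/protected and the remainder rural-poor.
    Quotas match archetype_mix exactly."""
    counts = _quota_counts(mix, n)
    urban_score = zonal_props["built_up"] + 0.5 * zonal_props["roads"]
    comm_score = zonal_props["water_protected"] + zonal_props["cropland"]
    arche_idx = np.full(n, 3)  # rural_poor default
    by_urban = np.argsort(-urban_score, kind="stable")
    arche_idx[by_urban[:counts[0]]] = 0
    arche_idx[by_urban[counts[0]:counts[0] + counts[1]]] = 1
    rest = by_urban[counts[0] + counts[1]:]
    by_comm = rest[np.argsort(-comm_score[rest], kind="stable")]
    arche_idx[by_comm[:counts[2]]] = 2
    return arche_idx


def generate_eas(config: LandscapeConfig,
                 rasters: dict[str, GridLayer]) -> tuple[EATable, SyntheticTruth]:
    """Tile the grid into n_eas rectangular EAs and draw archetype-
    conditional covariates with planted between-archetype separation."""
    require_same_grid(*rasters.values())
    rng = config.rng("eas")
    nr, nc = config.grid_rows, config.grid_cols
    br, bc = _tile_factors(config.n_eas, nr, nc)

    row_edges = np.linspace(0, nr, br + 1).astype(int)
    col_edges = np.linspace(0, nc, bc + 1).astype(int)
    labels = np.empty((nr, nc), dtype=np.int32)
    bounds = []
    idx = 0
    for i in range(br):
        for j in range(bc):
            r0, r1 = row_edges[i], row_edges[i + 1]
            c0, c1 = col_edges[j], col_edges[j + 1]
            labels[r0:r1, c0:c1] = idx
            bounds.append((r0, r1, c0, c1))
            idx += 1

    n = config.n_eas
    lc = rasters["landcover"].data
    cell_counts = np.bincount(labels.ravel(), minlength=n)
    zonal_props = {}
    for cls_name, cls in LANDCOVER_CLASSES.items():
        zonal_props[cls_name] = np.bincount(
            labels.ravel(), weights=(lc == cls).ravel().astype(float),
            minlength=n) / cell_counts
    zonal_props["roads"] = np.bincount(
        labels.ravel(),
        weights=rasters["roads"].data.ravel().astype(float),
        minlength=n) / cell_counts
    arche_idx = _assign_archetypes(config.archetype_mix, zonal_props, n)
    archetype = np.array(ARCHETYPES)[arche_idx]

    records: dict[str, np.ndarray] = {
        "ea_id": np.array([f"EA{k:04d}" for k in range(n)]),
        "archetype": archetype,
    }
    for var, means in _COVARIATE_MEANS.items():
        vals = np.asarray(means)[arche_idx] + rng.normal(
            0.0, _COVARIATE_SD[var], size=n)
        if var in _PROPORTION_VARS:
            vals = np.clip(vals, 0.0, 1.0)
        else:
            vals = np.maximum(vals, 1.0)
        records[var] = vals
    records["poultry"] = (
        rng.random(n) < np.array([_POULTRY_PROB[a] for a in archetype])
    ).astype(int)

    elev = rasters["elevation"].data
    lc = rasters["landcover"].data
    mean_elev = np.empty(n)
    for cls_name, cls in (("prop_built_up", 0), ("prop_cropland", 1),
                          ("prop_trees", 2)):
        records[cls_name] = np.bincount(
            labels.ravel(), weights=(lc == cls).ravel().astype(float),
            minlength=n) / np.bincount(labels.ravel(), minlength=n)
    mean_elev = np.bincount(labels.ravel(), weights=elev.ravel(),
                            minlength=n) / np.bincount(labels.ravel(),
                                                       minlength=n)
    records["mean_elevation"] = mean_elev
    for name, col in zip(("row0", "row1", "col0", "col1"),
                         np.array(bounds).T):
        records[name] = col

    table = pd.DataFrame(records)

    beta = float(np.log1p(-config.elevation_rate_effect))  # per 100 m
    mult = np.array([_ARCHETYPE_RATE_MULT[a] for a in archetype])
    expected = (
        table["population"].to_numpy() / 1000.0
        * config.baseline_rate * config.period_years
        * mult * np.exp(beta * mean_elev / 100.0)
    )
    truth = SyntheticTruth(
        archetype=pd.Series(archetype, index=table["ea_id"], name="archetype"),
        expected_cases=pd.Series(expected, index=table["ea_id"],
                                 name="expected_cases"),
        elevation_coef=beta,
    )
    return EATable(table=table, labels=labels,
                   cell_size=config.cell_size), truth


# ---------------------------------------------------------------------------
# species layers


def suitability_from_weights(rasters: dict[str, GridLayer],
                             intercept: float,
                             elevation_weight: float,
                             landcover_weights: dict[int, float]) -> GridLayer:
    """Logistic suitability from a linear score of normalized elevation and
    landcover class indicators. All-zero weights give flat 0.5."""
    elev = rasters["elevation"].data
    lc = rasters["landcover"].data
    span = np.ptp(elev)
    elev_norm = (elev - elev.mean()) / span if span > 0 else np.zeros_like(elev)
    score = intercept + elevation_weight * elev_norm
    for cls, w in landcover_weights.items():
        score = score + w * (lc == cls)
    suit = 1.0 / (1.0 + np.exp(-score))
    return rasters["elevation"].copy_with(suit)


def generate_species_layers(
        config: LandscapeConfig,
        rasters: dict[str, GridLayer],
) -> tuple[list[GridLayer], pd.DataFrame, list[np.ndarray]]:
    """Per-species suitability layers, occurrence points (presence sampled
    proportional to suitability, background uniform) and a presence-truth
    mask per species."""
    rng = config.rng("species")
    nr, nc = config.grid_rows, config.grid_cols
    layers: list[GridLayer] = []
    truth_masks: list[np.ndarray] = []
    rows = []
    # species avoid built-up cells and thin out with altitude — so stacked
    # richness is lowest in urban areas and carries archetype signal
    for s in range(config.n_species):
        intercept = rng.normal(1.2, 0.4)
        w_elev = rng.normal(-1.0, 0.8)
        w_lc = {
            LANDCOVER_CLASSES["built_up"]: rng.normal(-2.0, 0.4),
            LANDCOVER_CLASSES["cropland"]: rng.normal(0.4, 0.3),
            LANDCOVER_CLASSES["trees"]: rng.normal(0.6, 0.3),
            LANDCOVER_CLASSES["grassland"]: rng.normal(0.4, 0.3),
            LANDCOVER_CLASSES["water_protected"]: rng.normal(0.0, 0.5),
        }
        layer = suitability_from_weights(rasters, intercept, w_elev, w_lc)
        layers.append(layer)
        truth_masks.append(layer.data >= 0.5)

        suit = layer.data.ravel()
        p = suit / suit.sum()
        pres = rng.choice(nr * nc, size=config.n_presence_points, p=p)
        bg = rng.integers(0, nr * nc, size=config.n_background_points)
        for cell, flag in [(pres, 1), (bg, 0)]:
            r, c = np.unravel_index(cell, (nr, nc))
            for rr, cc in zip(r, c):
                rows.append((s, int(rr), int(cc), flag,
                             float(layer.data[rr, cc])))
    points = pd.DataFrame(
        rows, columns=["species", "row", "col", "presence", "suitability"])
    return layers, points, truth_masks


# ---------------------------------------------------------------------------
# facilities

_FACILITY_WEIGHT = {"urban": 10.0, "peri_urban": 5.0,
                    "commercial_protected": 1.0, "rural_poor": 1.0}


def generate_facilities(config: LandscapeConfig, eas: EATable) -> pd.DataFrame:
    """Treating facilities placed preferentially in urban/peri-urban EAs."""
    if config.n_facilities < 1:
        raise ValueError("at least one facility is required")
    rng = config.rng("facilities")
    w = np.array([_FACILITY_WEIGHT[a] for a in eas.table["archetype"]])
    p = w / w.sum()
    chosen = rng.choice(eas.n_eas, size=config.n_facilities, p=p)
    rows = []
    for k, ea in enumerate(chosen):
        r0, r1, c0, c1 = eas.table.loc[ea, ["row0", "row1", "col0", "col1"]]
        r = int(rng.integers(r0, r1))
        c = int(rng.integers(c0, c1))
        rows.append({
            "facility_id": f"HF{k:02d}",
            "ea_id": eas.table.loc[ea, "ea_id"],
            "row": r, "col": c,
            "x": (c + 0.5) * eas.cell_size,
            "y": (eas.labels.shape[0] - r - 0.5) * eas.cell_size,
            "treats_snakebite": True,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# case registry


def _sample_categorical(rng: np.random.Generator, table: dict, size: int):
    keys = list(table.keys())
    p = np.asarray([table[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


_AGE_BAND_RANGE = {
    "0-9": (0, 9), "10-19": (10, 19), "20-29": (20, 29), "30-39": (30, 39),
    "40-49": (40, 49), "50-59": (50, 59), "60-69": (60, 69),
    "70-79": (70, 79), "80+": (80, 99),
}


def generate_cases(config: LandscapeConfig, eas: EATable,
                   truth: SyntheticTruth, seed: int | None = None) -> pd.DataFrame:
    """Case registry: per-EA counts are Poisson with the planted log-linear
    rate; attributes are drawn independently from the configured tables."""
    rng = (config.rng("cases") if seed is None
           else np.random.default_rng(seed))
    counts = rng.poisson(truth.expected_cases.to_numpy())
    n = int(counts.sum())
    tables = config.case_attribute_tables

    ea_ids = np.repeat(eas.table["ea_id"].to_numpy(), counts)
    elev = np.repeat(eas.table["mean_elevation"].to_numpy(), counts)

    months = np.array(_sample_categorical(rng, tables["month"], n), dtype=int)
    years = config.period_start_year + rng.integers(
        0, max(int(round(config.period_years)), 1), size=n)
    days = np.array([
        int(rng.integers(1, calendar.monthrange(int(y), int(m))[1] + 1))
        for y, m in zip(years, months)])
    dates = [f"{y}-{m:02d}-{d:02d}" for y, m, d in zip(years, months, days)]

    bands = _sample_categorical(rng, tables["age_band"], n)
    ages = np.full(n, np.nan)
    for i, b in enumerate(bands):
        if b != "missing":
            lo, hi = _AGE_BAND_RANGE[b]
            ages[i] = rng.integers(lo, hi + 1)

    first_aid = np.array(_sample_categorical(rng, tables["first_aid_any"], n))
    def _cond(table_name, cond):  # sub-attribute only where cond holds
        out = np.zeros(n, dtype=bool)
        k = int(cond.sum())
        if k:
            out[cond] = _sample_categorical(rng, tables[table_name], k)
        return out

    tourniquet = _cond("tourniquet_given_first_aid", first_aid == True)  # noqa: E712
    incision = _cond("incision_given_first_aid", first_aid == True)  # noqa: E712
    herbal = _cond("herbal_given_first_aid", first_aid == True)  # noqa: E712
    bandage = _cond("bandage_given_first_aid", first_aid == True)  # noqa: E712

    antivenom = np.array(_sample_categorical(rng, tables["antivenom"], n))
    vials = np.full(n, np.nan)
    av = antivenom == True  # noqa: E712
    if av.sum():
        vials[av] = _sample_categorical(rng, tables["vials_given_antivenom"],
                                        int(av.sum()))
    adrenaline = _cond("adrenaline_given_antivenom", av)
    reaction = _cond("reaction_given_antivenom", av)

    df = pd.DataFrame({
        "ea_id": ea_ids,
        "date": dates,
        "month": months,
        "hour": np.array(_sample_categorical(rng, tables["hour"], n),
                         dtype=int),
        "age": ages,
        "age_band": bands,
        "sex": _sample_categorical(rng, tables["sex"], n),
        "occupation": _sample_categorical(rng, tables["occupation"], n),
        "elevation": elev,
        "bite_site": _sample_categorical(rng, tables["bite_site"], n),
        "activity": _sample_categorical(rng, tables["activity"], n),
        "location": _sample_categorical(rng, tables["location"], n),
        "syndrome": _sample_categorical(rng, tables["syndrome"], n),
        "first_aid_any": first_aid.astype(bool),
        "first_aid_tourniquet": tourniquet,
        "first_aid_incision": incision,
        "first_aid_herbal": herbal,
        "first_aid_bandage": bandage,
        "antivenom": av,
        "vials": vials,
        "adrenaline_pretreatment": adrenaline,
        "adverse_reaction": reaction,
        "outcome": _sample_categorical(rng, tables["outcome"], n),
    })
    return df


def case_counts_per_ea(cases: pd.DataFrame, eas: EATable) -> pd.Series:
    """Reported-bite count per EA (zero-filled), aligned to the EA table."""
    counts = cases["ea_id"].value_counts()
    return counts.reindex(eas.table["ea_id"], fill_value=0).rename(
        "bite_count")


def generate_landscape(config: LandscapeConfig) -> dict:
    """Run all five generators; returns a dict bundle."""
    rasters = generate_rasters(config)
    eas, truth = generate_eas(config, rasters)
    species, occurrences, presence_truth = generate_species_layers(
        config, rasters)
    truth.species_presence = presence_truth
    facilities = generate_facilities(config, eas)
    cases = generate_cases(config, eas, truth)
    return {
        "config": config,
        "rasters": rasters,
        "eas": eas,
        "truth": truth,
        "species_layers": species,
        "occurrences": occurrences,
        "facilities": facilities,
        "cases": cases,
    }
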