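"""Worst-case cosine-similarity risk indices.

Each index (hazard, exposure, susceptibility, resource scarcity) is built
the same way: z-standardize the EA variables, construct a hypothetical
worst-case reference holding the riskiest value of every variable, score
each EA by the cosine similarity between its standardized row and the
standardized reference, rank EAs from most similar (rank 1) to least, and
map ranks linearly onto [0, 1] with rank 1 -> 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridLayer
from .synthetic_landscape import EATable

HIGHER = "higher-is-worse"
LOWER = "lower-is-worse"


@dataclass(frozen=True)
class VariableSpec:
    name: str
    orientation: str = HIGHER
    index_membership: str = "hazard"

    def __post_init__(self) -> None:
        if self.orientation not in (HIGHER, LOWER):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class WorstCaseReference:
    raw: pd.Series           # reference value per variable, original units
    standardized: pd.Series  # same, after the EA-table z-transform


@dataclass
class RiskIndex:
    name: str
    variables: list[str]
    table: pd.DataFrame      # ea_id, similarity, rank, score
    reference: WorstCaseReference

    def scores(self) -> pd.Series:
        return self.table.set_index("ea_id")["score"]

    def ranks(self) -> pd.Series:
        return self.table.set_index("ea_id")["rank"]


def zscore_columns(matrix: pd.DataFrame,
                   ddof: int = 0) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Column-wise z-transform (population sd by default).

    Raises on constant columns: their z-score is undefined and a constant
    carries no ranking information anyway.
    """
    if len(matrix) < 2:
        raise ValueError("need at least 2 rows")
    means = matrix.mean()
    sds = matrix.std(ddof=ddof)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(
            f"constant column(s) {list(constant.index)} cannot be z-scored")
    return (matrix - means) / sds, means, sds


def build_worst_case(ea_table: pd.DataFrame,
                     specs: list[VariableSpec]) -> WorstCaseReference:
    """Column max for higher-is-worse variables, min for lower-is-worse,
    standardized with the EA-table means/sds."""
    names = [s.name for s in specs]
    missing = [n for n in names if n not in ea_table.columns]
    if missing:
        raise KeyError(f"missing variable(s): {missing}")
    raw = pd.Series({
        s.name: (ea_table[s.name].max() if s.orientation == HIGHER
                 else ea_table[s.name].min())
        for s in specs})
    if len(ea_table) == 1:  # degenerate: reference is the single EA itself
        return WorstCaseReference(raw=raw, standardized=raw * 0.0)
    _, means, sds = zscore_columns(ea_table[names])
    standardized = (raw - means) / sds
    return WorstCaseReference(raw=raw, standardized=standardized)


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def similarity_rank_index(ea_table: pd.DataFrame, specs: list[VariableSpec],
                          name: str, id_col: str = "ea_id") -> RiskIndex:
    """The full pipeline: z-transform -> worst-case reference -> cosine to
    each EA -> rank (1 = most similar = riskiest) -> (N - rank)/(N - 1)."""
    if len(ea_table) < 2:
        raise ValueError("need at least 2 EAs")
    names = [s.name for s in specs]
    reference = build_worst_case(ea_table, specs)
    z, _, _ = zscore_columns(ea_table[names])
    ref = reference.standardized.to_numpy()
    sims = np.array([cosine_similarity(row, ref) for row in z.to_numpy()])
    dists = np.linalg.norm(z.to_numpy() - ref, axis=1)

    out = pd.DataFrame({id_col: ea_table[id_col].to_numpy(),
                        "similarity": sims, "_dist": dists})
    # rank 1 = highest similarity; similarity ties broken by proximity to
    # the worst-case reference (keeps single-variable indices monotone in
    # the raw value, where cosine degenerates to a sign), then by EA id
    order = out.sort_values(["similarity", "_dist", id_col],
                            ascending=[False, True, True],
                            kind="mergesort").index
    ranks = pd.Series(index=order, data=np.arange(1, len(out) + 1))
    out["rank"] = ranks.sort_index().to_numpy()
    n = len(out)
    out["score"] = (n - out["rank"]) / (n - 1)
    out = out.drop(columns=["_dist"])
    return RiskIndex(name=name, variables=names, table=out,
                     reference=reference)


def landscape_metrics(landcover: GridLayer, eas: EATable) -> pd.DataFrame:
    """Per-EA fragmentation: Shannon diversity of landcover classes and
    edge density (4-adjacent unlike pairs x cell size / EA area)."""
    lc = landcover.data
    if lc.shape != eas.labels.shape:
        raise ValueError("landcover and EA labels must share the grid frame")
    labels = eas.labels
    cell = eas.cell_size
    rows = []
    for i, ea_id in enumerate(eas.table["ea_id"]):
        in_ea = labels == i
        vals = lc[in_ea]
        if vals.size == 0:
            rows.append({"ea_id": ea_id, "shannon": np.nan,
                         "edge_density": np.nan})
            continue
        _, counts = np.unique(vals, return_counts=True)
        p = counts / counts.sum()
        shannon = float(-(p * np.log(p)).sum())
        # count 4-adjacent pairs with both cells inside the EA and
        # differing classes
        horiz = in_ea[:, :-1] & in_ea[:, 1:] & (lc[:, :-1] != lc[:, 1:])
        vert = in_ea[:-1, :] & in_ea[1:, :] & (lc[:-1, :] != lc[1:, :])
        edges = int(horiz.sum() + vert.sum())
        area = vals.size * cell * cell
        rows.append({"ea_id": ea_id, "shannon": shannon,
                     "edge_density": edges * cell / area})
    return pd.DataFrame(rows)


DEFAULT_SPECS: list[VariableSpec] = [
    VariableSpec("zonal_richness", HIGHER, "hazard"),
    VariableSpec("bite_count", HIGHER, "hazard"),
    VariableSpec("prop_trees", HIGHER, "exposure"),
    VariableSpec("prop_cropland", HIGHER, "exposure"),
    VariableSpec("prop_built_up", HIGHER, "exposure"),
    VariableSpec("building_density", HIGHER, "exposure"),
    VariableSpec("building_occupancy", HIGHER, "exposure"),
    VariableSpec("edge_density", HIGHER, "exposure"),
    VariableSpec("shannon", HIGHER, "exposure"),
    VariableSpec("poultry", HIGHER, "exposure"),
    VariableSpec("prop_elderly", HIGHER, "susceptibility"),
    VariableSpec("prop_children_youth", HIGHER, "susceptibility"),
    VariableSpec("poverty", HIGHER, "susceptibility"),
    VariableSpec("prop_firewood", HIGHER, "susceptibility"),
    VariableSpec("prop_candles_paraffin", HIGHER, "susceptibility"),
    VariableSpec("travel_minutes", HIGHER, "scarcity"),
]

INDEX_NAMES = ("hazard", "exposure", "susceptibility", "scarcity")


def build_all_indices(ea_table: pd.DataFrame,
                      specs: list[VariableSpec] | None = None,
                      ) -> dict[str, RiskIndex]:
    """Build the four indices from a merged per-EA table that already
    contains every variable named in the specs (EA covariates plus zonal
    richness, bite counts, fragmentation metrics and travel time)."""
    specs = DEFAULT_SPECS if specs is None else specs
    indices: dict[str, RiskIndex] = {}
    for index_name in INDEX_NAMES:
        members = [s for s in specs if s.index_membership == index_name]
        if not members:
            continue
        names = [s.name for s in members]
        usable = ea_table.dropna(subset=names)
        dropped = len(ea_table) - len(usable)
        if dropped:
            warnings.warn(
                f"{dropped} EA(s) excluded from {index_name!r} "
                f"(missing values)")
        indices[index_name] = similarity_rank_index(usable, members,
                                                    index_name)
    return indices


def merge_ea_variables(eas: EATable, zonal_richness: pd.Series,
                       bite_count: pd.Series, travel_minutes: pd.Series,
                       fragmentation: pd.DataFrame) -> pd.DataFrame:
    """Assemble the per-EA variable table the four indices read from."""
    df = eas.table.copy()
    for series, col in ((zonal_richness, "zonal_richness"),
                        (bite_count, "bite_count"),
                        (travel_minutes, "travel_minutes")):
        aligned = series.reindex(df["ea_id"])
        if aligned.isna().all():
            raise ValueError(f"EA id mismatch for {col!r}")
        df[col] = aligned.to_numpy()
    df = df.merge(fragmentation, on="ea_id", how="left")
    return df
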