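"""Seeded k-medoids risk profiling scored by the Calinski-Harabasz
pseudo-F statistic.

Seeds are the top-ranked EA of each risk index (deduplicated by falling
back to the next rank), so the partition is fully deterministic. The
k-medoids loop is the alternating greedy heuristic: assign every EA to its
nearest medoid by Euclidean distance, then recompute each cluster's medoid
as the member minimizing total within-cluster distance, until labels
stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .risk_indices import RiskIndex


@dataclass
class FeatureMatrix:
    values: np.ndarray       # N x n_v, normalized index scores in [0, 1]
    variables: list[str]
    ea_ids: list[str]


@dataclass
class ClusterSolution:
    labels: pd.Series            # 1..n_c per EA id
    medoid_ids: list[str]
    pseudo_f: float
    r2_per_variable: pd.Series
    profiles: pd.DataFrame       # per-cluster median/q1/q3 per variable
    n_c: int
    n_iter: int
    objective: float
    degenerate: bool = False


def feature_matrix(indices: list[RiskIndex]) -> FeatureMatrix:
    """Join normalized scores of several indices on their common EA ids."""
    frames = [idx.scores().rename(idx.name) for idx in indices]
    joined = pd.concat(frames, axis=1, join="inner").dropna()
    if joined.empty:
        raise ValueError("no EA is present in every index")
    return FeatureMatrix(values=joined.to_numpy(dtype=float),
                         variables=list(joined.columns),
                         ea_ids=list(joined.index))


def assign_seeds(indices: list[RiskIndex], k: int | None = None) -> list[str]:
    """One seed per index: its rank-1 EA; duplicates fall through to that
    index's next rank.

    If k exceeds the number of indices, the extra seeds are chosen by
    deterministic farthest-point placement in the index-score space
    (maximizing the minimum distance to the seeds picked so far) —
    documented extension, the source method leaves this case open.
    """
    if k is None:
        k = len(indices)
    n = min(len(idx.table) for idx in indices)
    if k > n:
        raise ValueError("k exceeds the number of EAs")
    ranked = [idx.table.sort_values("rank")["ea_id"].tolist()
              for idx in indices]
    seeds: list[str] = []
    for order in ranked[:k]:
        j = 0
        while j < len(order) and order[j] in seeds:
            j += 1
        if j >= len(order):
            raise ValueError("not enough distinct EAs for the seed set")
        seeds.append(order[j])
    if len(seeds) < k:
        feats = feature_matrix(indices)
        X = feats.values
        pos = {e: i for i, e in enumerate(feats.ea_ids)}
        while len(seeds) < k:
            seed_x = X[[pos[s] for s in seeds if s in pos]]
            d = np.min(np.linalg.norm(X[:, None, :] - seed_x[None],
                                      axis=2), axis=1)
            for s in seeds:
                if s in pos:
                    d[pos[s]] = -1.0
            seeds.append(feats.ea_ids[int(np.argmax(d))])
    return seeds


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def kmedoids_partition(features: FeatureMatrix, seeds: list[str],
                       n_c: int | None = None,
                       max_iter: int = 100) -> ClusterSolution:
    """Alternating k-medoids from the given seed medoids; deterministic."""
    n_c = len(seeds) if n_c is None else n_c
    if n_c != len(seeds):
        raise ValueError("n_c must equal the number of seeds")
    if n_c < 2:
        raise ValueError("need at least 2 clusters")
    X = features.values
    n = X.shape[0]
    if n <= n_c:
        raise ValueError("need more EAs than clusters")
    id_pos = {e: i for i, e in enumerate(features.ea_ids)}
    try:
        medoids = [id_pos[s] for s in seeds]
    except KeyError as err:
        raise KeyError(f"seed EA {err} not in the feature matrix") from err

    d = np.sqrt(_pairwise_sq(X))
    labels = np.full(n, -1)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels = np.argmin(d[:, medoids], axis=1)
        # medoid points always stay in their own cluster
        for ci, m in enumerate(medoids):
            new_labels[m] = ci
        for ci in range(n_c):
            if not np.any(new_labels == ci):  # re-seed with the farthest EA
                far = int(np.argmax(np.min(d[:, medoids], axis=1)))
                warnings.warn(f"cluster {ci + 1} emptied; re-seeded")
                medoids[ci] = far
                new_labels[far] = ci
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for ci in range(n_c):
            members = np.flatnonzero(labels == ci)
            within = d[np.ix_(members, members)].sum(axis=1)
            medoids[ci] = int(members[np.argmin(within)])

    objective = float(d[np.arange(n), np.asarray(medoids)[labels]].sum())
    labels_1based = pd.Series(labels + 1, index=features.ea_ids,
                              name="cluster")
    r2 = cluster_r2(features, labels_1based)
    f, degenerate = calinski_harabasz(features, labels_1based,
                                      return_flag=True)
    return ClusterSolution(
        labels=labels_1based,
        medoid_ids=[features.ea_ids[m] for m in medoids],
        pseudo_f=f,
        r2_per_variable=r2,
        profiles=cluster_profiles(features, labels_1based),
        n_c=n_c, n_iter=n_iter, objective=objective, degenerate=degenerate)


def _sums_of_squares(X: np.ndarray, labels: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-variable within-cluster and total sums of squares."""
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum(axis=0)
    ssw = np.zeros(X.shape[1])
    for ci in np.unique(labels):
        members = X[labels == ci]
        ssw += ((members - members.mean(axis=0)) ** 2).sum(axis=0)
    return ssw, sst


def calinski_harabasz(features: FeatureMatrix, labels: pd.Series,
                      return_flag: bool = False):
    """Pseudo-F = (R^2 / (n_c - 1)) / ((1 - R^2) / (n - n_c)) with
    R^2 = 1 - SSW/SST pooled over all variables.

    Equal to the classical between/within variance-ratio form. A zero
    pooled within-cluster sum of squares is degenerate (perfect
    separation) and returns +inf, flagged.
    """
    X = features.values
    lab = labels.to_numpy()
    n = X.shape[0]
    n_c = len(np.unique(lab))
    if n_c < 2:
        raise ValueError("need at least 2 clusters")
    ssw, sst = _sums_of_squares(X, lab)
    tot_ssw, tot_sst = float(ssw.sum()), float(sst.sum())
    if tot_sst == 0.0:
        raise ValueError("total sum of squares is zero")
    r2 = 1.0 - tot_ssw / tot_sst
    if tot_ssw == 0.0:
        f = float("inf")
        return (f, True) if return_flag else f
    f = (r2 / (n_c - 1)) / ((1.0 - r2) / (n - n_c))
    return (f, False) if return_flag else f


def cluster_r2(features: FeatureMatrix, labels: pd.Series) -> pd.Series:
    """Per-variable R^2 = 1 - SSW_k/SST_k; constant variables get 0."""
    ssw, sst = _sums_of_squares(features.values, labels.to_numpy())
    out = {}
    for k, name in enumerate(features.variables):
        if sst[k] == 0.0:
            warnings.warn(f"variable {name!r} constant; R^2 set to 0")
            out[name] = 0.0
        else:
            out[name] = 1.0 - ssw[k] / sst[k]
    return pd.Series(out, name="r2")


def cluster_profiles(features: FeatureMatrix,
                     labels: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame(features.values, columns=features.variables,
                      index=features.ea_ids)
    df["cluster"] = labels.to_numpy()
    prof = df.groupby("cluster").agg(
        ["median", lambda s: s.quantile(0.25), lambda s: s.quantile(0.75),
         "size"])
    prof.columns = [f"{var}_{stat}" for var, stat in zip(
        prof.columns.get_level_values(0),
        ["median", "q1", "q3", "n"] * len(features.variables))]
    return prof.reset_index()


def run_analysis(indices: dict[str, RiskIndex],
                 include_scarcity: bool = True, n_c: int = 4,
                 sweep: tuple[int, int] | None = None) -> ClusterSolution:
    """Cluster EAs on the risk indices.

    ``include_scarcity=False`` reproduces the bite-risk analysis (hazard,
    exposure, susceptibility); ``True`` adds the scarcity index for the
    outcome analysis. An optional ``sweep=(k_lo, k_hi)`` attaches a
    pseudo-F profile over cluster counts.
    """
    names = ["hazard", "exposure", "susceptibility"]
    if include_scarcity:
        names.append("scarcity")
    missing = [nm for nm in names if nm not in indices]
    if missing:
        raise KeyError(f"missing index/indices: {missing}")
    chosen = [indices[nm] for nm in names]
    features = feature_matrix(chosen)
    solution = kmedoids_partition(features, assign_seeds(chosen, k=n_c))
    if sweep is not None:
        lo, hi = sweep
        profile = {}
        for k in range(lo, hi + 1):
            sol_k = kmedoids_partition(features, assign_seeds(chosen, k=k))
            profile[k] = sol_k.pseudo_f
        solution.pseudo_f_sweep = pd.Series(profile, name="pseudo_f")
    return solution
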