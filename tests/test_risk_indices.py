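import numpy as np
import pandas as pd
import pytest

from serprisk.grid import GridLayer
from serprisk.risk_indices import (
    HIGHER,
    LOWER,
    VariableSpec,
    build_all_indices,
    build_worst_case,
    cosine_similarity,
    landscape_metrics,
    similarity_rank_index,
    zscore_columns,
)


# ---------------------------------------------------------------------------
# z-transform


def test_symmetric_pair():
    z, _, _ = zscore_columns(pd.DataFrame({"x": [1.0, 3.0]}))
    np.testing.assert_allclose(z["x"].to_numpy(), [-1.0, 1.0])


def test_idempotent_on_standardized(rng):
    x = rng.normal(size=100)
    x = (x - x.mean()) / x.std()
    z, _, _ = zscore_columns(pd.DataFrame({"x": x}))
    np.testing.assert_allclose(z["x"].to_numpy(), x, atol=1e-12)


def test_roundtrip(rng):
    df = pd.DataFrame(rng.normal(size=(50, 4)) * [1, 10, 100, 0.1] + 5,
                      columns=list("abcd"))
    z, means, sds = zscore_columns(df)
    back = z * sds + means
    np.testing.assert_allclose(back.to_numpy(), df.to_numpy(), atol=1e-9)


def test_population_sd_zero_mean_unit_sd(rng):
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    z, _, _ = zscore_columns(df)
    assert np.all(np.abs(z.mean()) < 1e-10)
    np.testing.assert_allclose(z.std(ddof=0), 1.0)


def test_constant_column_error():
    df = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
    with pytest.raises(ValueError, match="flat"):
        zscore_columns(df)


# ---------------------------------------------------------------------------
# worst case


def test_all_higher_is_worse_takes_maxima(rng):
    df = pd.DataFrame(rng.random((10, 3)), columns=list("abc"))
    specs = [VariableSpec(c, HIGHER, "hazard") for c in "abc"]
    ref = build_worst_case(df, specs)
    pd.testing.assert_series_equal(ref.raw, df.max(), check_names=False)


def test_single_ea_reference_is_that_row():
    df = pd.DataFrame({"a": [2.0], "b": [5.0]})
    specs = [VariableSpec("a", HIGHER, "h"), VariableSpec("b", LOWER, "h")]
    ref = build_worst_case(df, specs)
    assert ref.raw["a"] == 2.0 and ref.raw["b"] == 5.0


def test_mixed_orientation_hand_enumeration():
    df = pd.DataFrame({
        "up": [0.1, 0.9, 0.4, 0.2, 0.6],
        "down": [10.0, 3.0, 8.0, 1.0, 5.0],
    })
    specs = [VariableSpec("up", HIGHER, "h"), VariableSpec("down", LOWER, "h")]
    ref = build_worst_case(df, specs)
    assert ref.raw["up"] == pytest.approx(0.9)     # max over column
    assert ref.raw["down"] == pytest.approx(1.0)   # min over column
    # standardized with population sd of the EA columns
    assert ref.standardized["up"] == pytest.approx(
        (0.9 - df["up"].mean()) / df["up"].std(ddof=0))


def test_missing_variable_error():
    df = pd.DataFrame({"a": [1.0, 2.0]})
    with pytest.raises(KeyError):
        build_worst_case(df, [VariableSpec("zzz", HIGHER, "h")])


# ---------------------------------------------------------------------------
# cosine


def test_self_similarity():
    assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_orthogonal():
    assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)


def test_worked_value():
    expected = 32.0 / (np.sqrt(14.0) * np.sqrt(77.0))
    assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
        expected, abs=1e-6)
    assert expected == pytest.approx(0.974632, abs=1e-6)


def test_zero_vector_error():
    with pytest.raises(ValueError):
        cosine_similarity([0, 0], [1, 2])


def test_length_mismatch():
    with pytest.raises(ValueError):
        cosine_similarity([1, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# similarity-rank index


def _random_table(rng, n=20, p=3):
    df = pd.DataFrame(rng.normal(size=(n, p)),
                      columns=[f"v{i}" for i in range(p)])
    df.insert(0, "ea_id", [f"EA{i:03d}" for i in range(n)])
    return df


def _oracle_ranks(df, specs):
    """Brute-force: z-score by hand, cosine every EA against the
    standardized worst case, sort exhaustively."""
    names = [s.name for s in specs]
    X = df[names].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Z = (X - mu) / sd
    ref = np.array([
        (X[:, j].max() if s.orientation == HIGHER else X[:, j].min())
        for j, s in enumerate(specs)])
    ref_z = (ref - mu) / sd
    sims = [float(z @ ref_z / (np.linalg.norm(z) * np.linalg.norm(ref_z)))
            for z in Z]
    order = sorted(range(len(sims)),
                   key=lambda i: (-sims[i], df["ea_id"].iloc[i]))
    ranks = np.empty(len(sims), dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    return ranks


def test_worst_case_row_gets_rank_one(rng):
    df = _random_table(rng, n=10)
    specs = [VariableSpec(c, HIGHER, "h") for c in ["v0", "v1", "v2"]]
    worst = {c: df[c].max() for c in ["v0", "v1", "v2"]}
    df.loc[0, ["v0", "v1", "v2"]] = [worst["v0"], worst["v1"], worst["v2"]]
    idx = similarity_rank_index(df, specs, "h")
    row = idx.table[idx.table["ea_id"] == df["ea_id"].iloc[0]].iloc[0]
    assert row["rank"] == 1 and row["score"] == 1.0


def test_two_eas_scores_zero_one(rng):
    df = _random_table(rng, n=2)
    specs = [VariableSpec(c, HIGHER, "h") for c in ["v0", "v1", "v2"]]
    idx = similarity_rank_index(df, specs, "h")
    assert sorted(idx.table["score"]) == [0.0, 1.0]


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    df = _random_table(rng, n=20, p=4)
    specs = [VariableSpec("v0", HIGHER, "h"), VariableSpec("v1", LOWER, "h"),
             VariableSpec("v2", HIGHER, "h"), VariableSpec("v3", LOWER, "h")]
    idx = similarity_rank_index(df, specs, "h")
    np.testing.assert_array_equal(idx.table["rank"].to_numpy(),
                                  _oracle_ranks(df, specs))


def test_rank_permutation_and_score_bounds(rng):
    df = _random_table(rng, n=37)
    specs = [VariableSpec(c, HIGHER, "h") for c in ["v0", "v1", "v2"]]
    idx = similarity_rank_index(df, specs, "h")
    assert sorted(idx.table["rank"]) == list(range(1, 38))
    assert idx.table["score"].min() == 0.0
    assert idx.table["score"].max() == 1.0


def test_scale_invariance(rng):
    df = _random_table(rng, n=25)
    specs = [VariableSpec(c, HIGHER, "h") for c in ["v0", "v1", "v2"]]
    base = similarity_rank_index(df, specs, "h")
    scaled = df.copy()
    scaled["v1"] = scaled["v1"] * 1234.5
    again = similarity_rank_index(scaled, specs, "h")
    np.testing.assert_array_equal(base.table["rank"].to_numpy(),
                                  again.table["rank"].to_numpy())


def test_single_variable_monotone(rng):
    df = _random_table(rng, n=15, p=1)
    idx = similarity_rank_index(
        df, [VariableSpec("v0", HIGHER, "scarcity")], "scarcity")
    merged = df.merge(idx.table, on="ea_id")
    order_by_raw = merged.sort_values("v0", ascending=False)
    assert (np.diff(order_by_raw["score"].to_numpy()) <= 0).all()


# ---------------------------------------------------------------------------
# fragmentation metrics


def _single_ea(labels_shape):
    from serprisk.synthetic_landscape import EATable

    table = pd.DataFrame({
        "ea_id": ["EA0000"],
        "row0": [0], "row1": [labels_shape[0]],
        "col0": [0], "col1": [labels_shape[1]],
    })
    return EATable(table=table, labels=np.zeros(labels_shape, dtype=int),
                   cell_size=500.0)


def test_single_class_zero_metrics():
    eas = _single_ea((4, 4))
    lc = GridLayer(np.zeros((4, 4)), cell_size=500.0)
    m = landscape_metrics(lc, eas).iloc[0]
    assert m["shannon"] == 0.0 and m["edge_density"] == 0.0


def test_fifty_fifty_shannon():
    eas = _single_ea((2, 2))
    lc = GridLayer(np.array([[0, 0], [1, 1]]), cell_size=500.0)
    m = landscape_metrics(lc, eas).iloc[0]
    assert m["shannon"] == pytest.approx(np.log(2))


def test_checkerboard_oracle():
    eas = _single_ea((4, 4))
    board = np.indices((4, 4)).sum(axis=0) % 2
    lc = GridLayer(board, cell_size=500.0)
    m = landscape_metrics(lc, eas).iloc[0]
    # exhaustive 4-adjacency enumeration: 12 horizontal + 12 vertical
    # unlike pairs
    edges = 0
    for i in range(4):
        for j in range(4):
            if j + 1 < 4 and board[i, j] != board[i, j + 1]:
                edges += 1
            if i + 1 < 4 and board[i, j] != board[i + 1, j]:
                edges += 1
    assert edges == 24
    assert m["edge_density"] == pytest.approx(24 * 500.0 / (16 * 500.0 ** 2))
    assert m["shannon"] == pytest.approx(np.log(2))


# ---------------------------------------------------------------------------
# the four indices


def test_max_hazard_inputs_score_one(rng):
    n = 12
    df = pd.DataFrame({
        "ea_id": [f"EA{i:03d}" for i in range(n)],
        "zonal_richness": rng.random(n) * 10,
        "bite_count": rng.integers(0, 30, n).astype(float),
    })
    df.loc[3, "zonal_richness"] = df["zonal_richness"].max() + 1
    df.loc[3, "bite_count"] = df["bite_count"].max() + 1
    specs = [VariableSpec("zonal_richness", HIGHER, "hazard"),
             VariableSpec("bite_count", HIGHER, "hazard")]
    built = build_all_indices(df, specs)
    row = built["hazard"].table.set_index("ea_id").loc["EA003"]
    assert row["rank"] == 1 and row["score"] == 1.0


def test_scarcity_single_variable_follows_travel_time(rng):
    n = 15
    df = pd.DataFrame({
        "ea_id": [f"EA{i:03d}" for i in range(n)],
        "travel_minutes": rng.random(n) * 200,
    })
    built = build_all_indices(
        df, [VariableSpec("travel_minutes", HIGHER, "scarcity")])
    merged = df.merge(built["scarcity"].table, on="ea_id")
    by_time = merged.sort_values("travel_minutes", ascending=False)
    assert (np.diff(by_time["score"].to_numpy()) <= 0).all()


def test_urban_susceptibility_below_rural(default_pipeline):
    arch = default_pipeline.bundle["eas"].table.set_index(
        "ea_id")["archetype"]
    scores = default_pipeline.indices["susceptibility"].scores()
    urban = scores[arch.reindex(scores.index) == "urban"]
    rural = scores[arch.reindex(scores.index) == "rural_poor"]
    assert urban.median() < rural.median()
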