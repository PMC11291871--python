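"""GPM normalization, grouped rank-sum comparisons, co-occurrence network."""

import numpy as np
import pandas as pd
import pytest

from magflux import (
    GeneCountTable,
    SampleInfo,
    TableError,
    aggregate_genes,
    compare_groups,
    cooccurrence_network,
    gpm_normalize,
)
from magflux.genes import GpmTable, significance_code


def make_counts(counts: dict, lengths: list[int]) -> GeneCountTable:
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(lengths))])
    return GeneCountTable(df, pd.Series(lengths, index=df.index))


def test_single_gene_normalizes_to_one_million():
    gpm = gpm_normalize(make_counts({"A": [17]}, [250]))
    assert gpm.gpm.loc["g0", "A"] == 1e6


def test_two_gene_hand_example():
    # counts (10, 10), lengths (100, 200) -> rates (0.1, 0.05)
    gpm = gpm_normalize(make_counts({"A": [10, 10]}, [100, 200]))
    np.testing.assert_allclose(gpm.gpm["A"], [2e6 / 3, 1e6 / 3])
    assert round(gpm.gpm.loc["g0", "A"], 2) == 666666.67
    assert round(gpm.gpm.loc["g1", "A"], 2) == 333333.33


def test_gpm_invariant_to_count_scaling_and_length_rescaling():
    base = make_counts({"A": [10, 30, 5]}, [100, 300, 700])
    doubled = make_counts({"A": [20, 60, 10]}, [100, 300, 700])
    halved_lengths = make_counts({"A": [10, 30, 5]}, [50, 150, 350])
    ref = gpm_normalize(base).gpm
    pd.testing.assert_frame_equal(gpm_normalize(doubled).gpm, ref)
    pd.testing.assert_frame_equal(gpm_normalize(halved_lengths).gpm, ref)


def test_gpm_columns_sum_to_one_million_on_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(20):
        counts = rng.integers(0, 500, size=(30, 5))
        lengths = rng.integers(300, 3000, size=30)
        table = GeneCountTable(
            pd.DataFrame(counts, index=[f"g{i}" for i in range(30)],
                         columns=list("abcde")),
            pd.Series(lengths, index=[f"g{i}" for i in range(30)]),
        )
        sums = gpm_normalize(table).gpm.sum(axis=0)
        np.testing.assert_allclose(sums, 1e6, rtol=1e-9)


def test_zero_read_sample_becomes_all_zero_column():
    gpm = gpm_normalize(make_counts({"A": [5, 5], "B": [0, 0]}, [100, 100]))
    assert (gpm.gpm["B"] == 0).all()
    assert gpm.gpm["A"].sum() == 1e6


def test_aggregate_sums_members_and_drops_ungrouped():
    gpm = GpmTable(
        pd.DataFrame({"A": [10.0, 20.0, 5.0]}, index=["g0", "g1", "g2"]), complete=False
    )
    agg = aggregate_genes(gpm, {"g0": "ko1", "g1": "ko1"})
    assert agg.gpm.loc["ko1", "A"] == 30.0
    assert list(agg.gpm.index) == ["ko1"]


def test_aggregate_identity_grouping_and_partial_cover_bound():
    counts = make_counts({"A": [10, 20, 30]}, [100, 100, 100])
    gpm = gpm_normalize(counts)
    ident = aggregate_genes(gpm, {g: g.upper() for g in gpm.gene_ids})
    np.testing.assert_allclose(ident.gpm.to_numpy(), gpm.gpm.to_numpy())
    partial = aggregate_genes(gpm, {"g0": "grp", "g2": "grp"})
    assert partial.gpm["A"].sum() <= 1e6 + 1e-6


def test_aggregate_empty_grouping_is_an_error():
    gpm = GpmTable(pd.DataFrame({"A": [1.0]}, index=["g0"]), complete=False)
    with pytest.raises(TableError, match="empty"):
        aggregate_genes(gpm, {})


def _groups(n_a=3, n_b=3):
    samples = [SampleInfo(f"w{i}", "seawater", "bottom") for i in range(n_a)]
    samples += [SampleInfo(f"d{i}", "sediment", "bottom") for i in range(n_b)]
    return samples


def test_identical_groups_give_p_one():
    gpm = GpmTable(
        pd.DataFrame([[5.0] * 6], index=["g0"],
                     columns=["w0", "w1", "w2", "d0", "d1", "d2"]),
        complete=False,
    )
    (cmp,) = compare_groups(gpm, _groups(), [("bottom_seawater", "bottom_sediment")])
    assert cmp.p_raw == 1.0
    assert cmp.significance_code == ""


def test_extreme_three_versus_three_has_exact_p_point_one():
    gpm = GpmTable(
        pd.DataFrame([[1.0, 2.0, 3.0, 10.0, 20.0, 30.0]], index=["g0"],
                     columns=["w0", "w1", "w2", "d0", "d1", "d2"]),
        complete=False,
    )
    (cmp,) = compare_groups(gpm, _groups(), [("bottom_seawater", "bottom_sediment")])
    assert cmp.p_raw == pytest.approx(0.1)  # 2 of the 20 rank arrangements
    assert cmp.significance_code == "*" if cmp.p_adj_bh < 0.05 else cmp.significance_code in {".", ""}


def test_bonferroni_is_m_times_smallest_p():
    rows = {
        "g0": [1.0, 2.0, 3.0, 10.0, 20.0, 30.0],
        "g1": [5.0, 6.0, 4.0, 5.5, 6.5, 4.5],
        "g2": [1.0, 1.5, 1.2, 1.1, 1.6, 1.3],
    }
    gpm = GpmTable(
        pd.DataFrame.from_dict(rows, orient="index",
                               columns=["w0", "w1", "w2", "d0", "d1", "d2"]),
        complete=False,
    )
    result = compare_groups(gpm, _groups(), [("bottom_seawater", "bottom_sediment")])
    q = min(c.p_raw for c in result)
    best = min(result, key=lambda c: c.p_raw)
    assert best.p_adj_bonferroni == pytest.approx(min(1.0, len(result) * q))
    assert all(c.p_adj_bonferroni >= c.p_raw for c in result)


def test_bh_adjustment_is_monotone_step_up():
    rng = np.random.default_rng(12)
    data = rng.lognormal(1, 1, size=(40, 8))
    gpm = GpmTable(
        pd.DataFrame(data, index=[f"g{i}" for i in range(40)],
                     columns=[f"w{i}" for i in range(4)] + [f"d{i}" for i in range(4)]),
        complete=False,
    )
    result = compare_groups(gpm, _groups(4, 4), [("bottom_seawater", "bottom_sediment")])
    by_raw = sorted(result, key=lambda c: c.p_raw)
    adj = [c.p_adj_bh for c in by_raw]
    assert all(a <= b + 1e-15 for a, b in zip(adj, adj[1:]))


def test_small_groups_are_skipped_with_warning():
    gpm = GpmTable(
        pd.DataFrame([[1.0, 2.0, 3.0]], index=["g0"], columns=["w0", "d0", "d1"]),
        complete=False,
    )
    samples = [SampleInfo("w0", "seawater", "bottom"),
               SampleInfo("d0", "sediment", "bottom"),
               SampleInfo("d1", "sediment", "bottom")]
    assert compare_groups(gpm, samples, [("bottom_seawater", "bottom_sediment")]) == []


def test_unknown_group_label_is_an_error():
    gpm = GpmTable(pd.DataFrame([[1.0]], index=["g0"], columns=["w0"]), complete=False)
    with pytest.raises(TableError, match="unknown group"):
        compare_groups(gpm, [SampleInfo("w0", "seawater", "bottom")],
                       [("bottom_seawater", "lake")])


def test_significance_codes_follow_fdr_thresholds():
    assert significance_code(0.0005) == "***"
    assert significance_code(0.005) == "**"
    assert significance_code(0.02) == "*"
    assert significance_code(0.07) == "."
    assert significance_code(0.2) == ""


def presence_frame(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


def test_network_hand_examples():
    presence = presence_frame(
        {
            "gA": [1, 1, 1, 0],  # MAG set {0,1,2}
            "gB": [0, 1, 1, 1],  # MAG set {1,2,3}: level 2/4 = 0.5 > 0.3
            "gC": [1, 1, 1, 0],  # identical to gA: level 1
            "gD": [0, 0, 0, 1],
        }
    )
    graph = cooccurrence_network(presence, threshold=0.3)
    assert graph.has_edge("gA", "gB") and graph["gA"]["gB"]["weight"] == 0.5
    assert graph["gA"]["gC"]["weight"] == 1.0
    assert not graph.has_edge("gA", "gD")  # disjoint sets, level 0


def test_network_isolated_and_empty_genes():
    presence = presence_frame({"gA": [1, 0], "gB": [0, 1], "gNone": [0, 0]})
    graph = cooccurrence_network(presence)
    assert set(graph.nodes) == {"gA", "gB", "gNone"}
    assert graph.number_of_edges() == 0


def test_network_invariant_to_mag_column_order():
    rng = np.random.default_rng(5)
    presence = pd.DataFrame(
        rng.integers(0, 2, size=(15, 10)),
        index=[f"g{i}" for i in range(15)],
        columns=[f"m{j}" for j in range(10)],
    )
    g1 = cooccurrence_network(presence)
    shuffled = presence[presence.columns[rng.permutation(10)]]
    g2 = cooccurrence_network(shuffled)
    assert set(g1.edges) == set(g2.edges)


def test_network_rejects_non_binary_matrix():
    with pytest.raises(TableError, match="binary"):
        cooccurrence_network(presence_frame({"g": [0, 2]}))
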