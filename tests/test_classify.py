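"""Permutation null, Monte-Carlo vs exhaustive classification, precedence."""

import numpy as np
import pandas as pd
import pytest

from magflux import (
    AbundanceTable,
    OriginMap,
    RunConfig,
    TableError,
    classify_pairs,
    classify_pairs_exhaustive,
    count_arrangements,
    permute_origins,
    summarize_habitat_pair,
    two_habitat_scenario,
    simulate_communities,
)
from magflux.classify import EXHAUSTIVE_GUARD, classification_records


def test_permutation_preserves_per_sample_origin_counts():
    rng = np.random.default_rng(0)
    origins = OriginMap({f"t{i}": f"s{i % 3}" for i in range(12)})
    permuted = permute_origins(origins, rng)
    assert permuted.origin_counts() == origins.origin_counts()
    assert set(permuted) == set(origins)


def test_two_element_permutation_is_a_fair_coin():
    rng = np.random.default_rng(1)
    origins = OriginMap({"m1": "S1", "m2": "S2"})
    swapped = sum(permute_origins(origins, rng)["m1"] == "S2" for _ in range(400))
    assert abs(swapped / 400 - 0.5) < 3 * 0.5 / 20  # 3 binomial SEs


def test_single_label_multiset_permutes_to_identity():
    rng = np.random.default_rng(2)
    origins = OriginMap({"a": "S1", "b": "S1", "c": "S1"})
    assert permute_origins(origins, rng).mapping == origins.mapping


def test_arrangement_counts():
    assert count_arrangements(OriginMap({"a": "A", "b": "B"})) == 2
    six_split = OriginMap({f"t{i}": ("A" if i < 3 else "B") for i in range(6)})
    assert count_arrangements(six_split) == 20  # binomial(6, 3)


def test_exhaustive_guard_refuses_large_instances():
    origins = OriginMap({f"t{i}": f"s{i}" for i in range(12)})  # 12! arrangements
    table = AbundanceTable(
        pd.DataFrame(
            np.eye(12), index=[f"t{i}" for i in range(12)], columns=[f"s{i}" for i in range(12)]
        )
    )
    assert count_arrangements(origins) > EXHAUSTIVE_GUARD
    with pytest.raises(TableError, match="Monte-Carlo"):
        classify_pairs_exhaustive(table, origins)


def test_identical_origins_give_single_arrangement_and_others():
    df = pd.DataFrame({"A": [3.0, 1.0], "B": [1.0, 2.0]}, index=["x", "y"])
    origins = OriginMap({"x": "A", "y": "A"})
    (pair,) = classify_pairs_exhaustive(AbundanceTable(df), origins)
    assert pair.n_perm == 1
    assert pair.exceed_f == pair.exceed_m_high == pair.exceed_m_low == 0.0
    assert pair.label == "Others"


def test_disjoint_support_is_isolated():
    # each taxon abundant only in its origin: observed M = 0, null M > 0
    n = 4
    vals = np.kron(np.eye(2), np.ones((n, 1))) * 10.0
    df = pd.DataFrame(vals, index=[f"t{i}" for i in range(2 * n)], columns=["A", "B"])
    table = AbundanceTable(df)
    origins = OriginMap({f"t{i}": ("A" if i < n else "B") for i in range(2 * n)})
    (pair,) = classify_pairs_exhaustive(table, origins)
    assert pair.mixture == 0.0
    assert pair.label == "Isolated"


def test_monte_carlo_is_reproducible_and_seed_sensitive(micro_table):
    origins = OriginMap({"m1": "S1", "m2": "S1", "m3": "S2"})
    cfg = RunConfig(seed=11, n_perm=199)
    a = classify_pairs(micro_table, origins, cfg)
    b = classify_pairs(micro_table, origins, cfg)
    assert classification_records(a) == classification_records(b)
    c = classify_pairs(micro_table, origins, RunConfig(seed=12, n_perm=199))
    assert a[0].label in {"Isolated", "Transmitted", "Mixed", "Others"}
    assert any(
        x["exceed_f"] != y["exceed_f"]
        for x, y in zip(classification_records(a), classification_records(c))
    )


@pytest.mark.parametrize("seed", [101, 202, 303])
def test_monte_carlo_converges_to_exhaustive(seed):
    rng = np.random.default_rng(seed)
    n_taxa, n_samples = 7, 3
    vals = rng.lognormal(1.0, 1.0, size=(n_taxa, n_samples))
    df = pd.DataFrame(vals, index=[f"t{i}" for i in range(n_taxa)],
                      columns=[f"s{j}" for j in range(n_samples)])
    table = AbundanceTable(df)
    origins = OriginMap({f"t{i}": f"s{rng.integers(n_samples)}" for i in range(n_taxa)})
    if len(set(origins.mapping.values())) < 2:
        origins = OriginMap({**origins.mapping, "t0": "s0", "t1": "s1"})
    exact = classify_pairs_exhaustive(table, origins)
    mc = classify_pairs(table, origins, RunConfig(seed=seed, n_perm=9999))
    for e, m in zip(exact, mc):
        for attr in ("exceed_f", "exceed_m_high", "exceed_m_low"):
            p = getattr(e, attr)
            se = np.sqrt(p * (1 - p) / 9999)
            assert abs(getattr(m, attr) - p) <= 3 * se + 1e-12


def test_label_precedence_transmitted_beats_mixed():
    """A pair engineered to clear both the Transmitted and Mixed thresholds
    must be labelled Transmitted."""
    df = pd.DataFrame(
        {
            "A": [1.0, 1.0, 0.0, 0.0, 0.0, 0.0],
            "B": [6.0, 6.0, 1.0, 0.0, 0.0, 0.0],
            "C": [0.0, 0.0, 0.0, 0.01, 0.01, 0.01],
        },
        index=[f"t{i}" for i in range(6)],
    )
    table = AbundanceTable(df)
    origins = OriginMap(
        {"t0": "A", "t1": "A", "t2": "B", "t3": "C", "t4": "C", "t5": "C"}
    )
    result = classify_pairs_exhaustive(table, origins, level=0.8)
    pair_ab = next(c for c in result if (c.sample_a, c.sample_b) == ("A", "B"))
    assert pair_ab.exceed_f >= 0.8 and pair_ab.exceed_m_high >= 0.8
    assert pair_ab.label == "Transmitted"
    assert pair_ab.net_source == "A"


def test_pair_with_no_origin_taxa_on_either_side_is_others():
    df = pd.DataFrame(
        {"A": [5.0, 6.0], "B": [1.0, 2.0], "C": [0.5, 0.5]}, index=["x", "y"]
    )
    origins = OriginMap({"x": "A", "y": "A"})
    result = classify_pairs(AbundanceTable(df), origins, RunConfig(seed=0, n_perm=49))
    pair_bc = next(c for c in result if (c.sample_a, c.sample_b) == ("B", "C"))
    assert pair_bc.label == "Others"


def test_signed_f_option_changes_the_statistic(micro_table):
    origins = OriginMap({"m1": "S1", "m2": "S1", "m3": "S2"})
    cfg = RunConfig(seed=5, n_perm=199)
    default = classify_pairs(micro_table, origins, cfg)
    signed = classify_pairs(micro_table, origins, cfg, use_signed_f=True)
    assert default[0].exceed_f != signed[0].exceed_f or default[0].label == signed[0].label


def test_stratified_permutation_respects_strata():
    scenario = two_habitat_scenario(0.5, 0.0, seed=4, n_samples=2, taxa_per_sample=10)
    table, samples, truth = simulate_communities(scenario)
    cfg = RunConfig(seed=4, n_perm=99)
    result = classify_pairs(table, truth.origins, cfg, samples=samples, stratify_by="zone")
    assert len(result) == 6
    with pytest.raises(TableError, match="metadata"):
        classify_pairs(table, truth.origins, cfg, stratify_by="zone")


def test_transmitted_monotone_in_transmission_fraction():
    """Raising the one-way transmission fraction never loses the Transmitted
    habitat call (checked over shared seeds)."""
    rates = []
    for tau in (0.0, 0.25, 0.5):
        hits = 0
        for seed in range(8):
            table, samples, truth = simulate_communities(
                two_habitat_scenario(tau, 0.0, seed=900 + seed)
            )
            res = classify_pairs(table, truth.origins, RunConfig(seed=900 + seed, n_perm=199))
            summary = summarize_habitat_pair(res, samples, "bottom_seawater", "slope_seawater")
            hits += summary.regime == "Transmitted" and summary.net_source == "bottom_seawater"
        rates.append(hits)
    assert rates[0] <= rates[1] <= rates[2]


def test_habitat_summary_requires_cross_pairs(zone_samples):
    with pytest.raises(TableError, match="no sample pairs"):
        summarize_habitat_pair([], zone_samples, "slope_seawater", "bottom_seawater")
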