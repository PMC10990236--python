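"""Group-difference tests, descriptive stability and leave-one-out."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from endogene import (assign_roles, descriptive_stability, dunn_test,
                      group_location_tests, leave_one_out_evaluation)
from endogene.errors import ContractError
from endogene.panel import MEANREF
from endogene.simdata import SimConfig, simulate_cq

from .conftest import make_table


# ---------------------------------------------------------------------------
# exact Mann-Whitney oracle by enumeration of group assignments
# ---------------------------------------------------------------------------

def exact_mwu_p(a, b):
    """Two-sided MWU p by enumerating all C(m+n, m) label assignments."""
    pooled = list(a) + list(b)
    m = len(a)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:m])) - m * (m + 1) / 2

    us = []
    for combo in itertools.combinations(range(len(pooled)), m):
        u = float(np.sum(ranks[list(combo)])) - m * (m + 1) / 2
        us.append(u)
    us = np.asarray(us)
    # two-sided: twice the smaller tail, capped at 1
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


def analyte_result(results, name):
    return next(r for r in results if r.analyte == name)


def test_mwu_on_separated_triples_is_point_one():
    table = make_table([[v, 0] for v in [1, 2, 3, 4, 5, 6]],
                       ["A"] * 3 + ["B"] * 3, genes=["R1", "X"])
    panel = assign_roles(table, ["X"])
    res = analyte_result(group_location_tests(table, panel, subset=["R1"]), "R1")
    assert res.test == "wilcoxon-mann-whitney"
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.flagged is False


def test_mwu_matches_enumeration_for_small_groups(rng):
    for m, n in [(2, 2), (3, 3), (3, 4), (4, 4), (2, 4)]:
        for _ in range(5):
            a = rng.normal(0, 1, m)
            b = rng.normal(0.5, 1, n)
            table = make_table([[v, 0.0] for v in list(a) + list(b)],
                               ["A"] * m + ["B"] * n, genes=["R1", "X"])
            panel = assign_roles(table, ["X"])
            res = analyte_result(
                group_location_tests(table, panel, subset=["R1"]), "R1")
            assert res.p_value == pytest.approx(exact_mwu_p(a, b), abs=1e-12)


def test_identical_groups_are_not_flagged():
    table = make_table([[v, 0] for v in [5, 6, 7, 5, 6, 7]],
                       ["A"] * 3 + ["B"] * 3, genes=["R1", "X"])
    panel = assign_roles(table, ["X"])
    res = analyte_result(group_location_tests(table, panel, subset=["R1"]), "R1")
    assert res.p_value == pytest.approx(1.0, abs=0.05)
    assert not res.flagged


def test_three_identical_groups_give_null_kruskal():
    table = make_table([[5.0, 0]] * 9, ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
                       genes=["R1", "X"])
    panel = assign_roles(table, ["X"])
    res = analyte_result(group_location_tests(table, panel, subset=["R1"]), "R1")
    assert res.test == "kruskal-wallis"
    assert res.statistic == 0.0 and res.p_value == 1.0
    assert res.posthoc is not None and (res.posthoc["p"] == 1.0).all()


def test_posthoc_only_with_three_groups(two_group_table):
    panel = assign_roles(two_group_table, ["T1"])
    results = group_location_tests(two_group_table, panel)
    assert {r.analyte for r in results} == {"R1", "R2", "R3", MEANREF}
    assert all(r.posthoc is None for r in results)


def test_single_group_is_a_contract_error():
    table = make_table([[20.0, 21.0]] * 4, ["A"] * 4)
    panel = assign_roles(table, [])
    with pytest.raises(ContractError, match="2 groups"):
        group_location_tests(table, panel)


def test_dunn_against_hand_computed_ranks():
    # groups {1,2,3}, {4,5,6}, {7,8,9}: no ties, N=9, mean ranks 2, 5, 8
    # var = (N(N+1)/12)(1/3+1/3) = 7.5*2/3 = 5 -> z = 3/sqrt(5) per step
    res = dunn_test([np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                     np.array([7.0, 8, 9])], ["a", "b", "c"])
    z_step = 3.0 / math.sqrt(5.0)
    got = {(r.group_a, r.group_b): r.z for r in res.itertuples()}
    assert got[("a", "b")] == pytest.approx(-z_step)
    assert got[("a", "c")] == pytest.approx(-2 * z_step)
    assert got[("b", "c")] == pytest.approx(-z_step)
    expected_p = 2 * stats.norm.sf(z_step)
    row = res[(res.group_a == "a") & (res.group_b == "b")].iloc[0]
    assert row.p == pytest.approx(expected_p)


def test_dunn_tie_correction_reduces_variance():
    # with ties the rank variance shrinks, so |z| grows vs the uncorrected z
    tied = [np.array([1.0, 1, 2]), np.array([3.0, 3, 4]), np.array([5.0, 6, 7])]
    res = dunn_test(tied, ["a", "b", "c"])
    pooled = np.concatenate(tied)
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12 * (n - 1))
    var = (n * (n + 1) / 12 - tie_term) * (2 / 3)
    expect = (ranks[:3].mean() - ranks[3:6].mean()) / math.sqrt(var)
    row = res[(res.group_a == "a") & (res.group_b == "b")].iloc[0]
    assert row.z == pytest.approx(expect)


# ---------------------------------------------------------------------------
# descriptive stability statistics
# ---------------------------------------------------------------------------

def brute_force_descriptive(values, groups):
    vals = np.asarray(values, dtype=float)
    mu_g = vals.mean()
    sigma_g = vals.std(ddof=1)
    smsd = ssdd = 0.0
    for grp in dict.fromkeys(groups):
        gv = vals[[i for i, g in enumerate(groups) if g == grp]]
        smsd += (gv.mean() - mu_g) ** 2
        sd_i = gv.std(ddof=1) if len(gv) > 1 else 0.0
        ssdd += (sd_i - sigma_g) ** 2
    return sigma_g, smsd, ssdd


def test_hand_computable_fixture():
    # gene with group values {20,20} and {22,22}
    table = make_table([[20.0], [20.0], [22.0], [22.0]], ["A", "A", "B", "B"],
                       genes=["R1"])
    panel = assign_roles(table, [])
    out = descriptive_stability(table, panel).set_index("analyte")
    row = out.loc["R1"]
    assert row["sum.mean.square.diff"] == pytest.approx(2.0, abs=1e-12)
    assert row["sum.SD.square.diff"] == pytest.approx(8.0 / 3.0, abs=1e-12)
    assert row["Standard.Deviation"] == pytest.approx(
        math.sqrt(4.0 / 3.0), abs=1e-12)


def test_constant_gene_has_zero_statistics():
    table = make_table([[21.0]] * 6, ["A"] * 3 + ["B"] * 3, genes=["R1"])
    panel = assign_roles(table, [])
    row = descriptive_stability(table, panel).set_index("analyte").loc["R1"]
    assert (row == 0.0).all()


def test_single_group_sums_vanish():
    table = make_table([[20.0], [21.0], [23.0]], ["A"] * 3, genes=["R1"])
    panel = assign_roles(table, [])
    row = descriptive_stability(table, panel).set_index("analyte").loc["R1"]
    assert row["sum.mean.square.diff"] == pytest.approx(0.0, abs=1e-12)
    assert row["sum.SD.square.diff"] == pytest.approx(0.0, abs=1e-12)


def test_descriptive_matches_brute_force_on_random_tables(rng):
    for _ in range(100):
        n_groups = int(rng.integers(1, 4))
        sizes = rng.integers(2, 6, size=n_groups)
        groups = [f"g{i}" for i in range(n_groups) for _ in range(sizes[i])]
        values = rng.normal(22, 2, size=len(groups))
        table = make_table([[v] for v in values], groups, genes=["R1"])
        panel = assign_roles(table, [])
        row = descriptive_stability(table, panel).set_index("analyte").loc["R1"]
        sd, smsd, ssdd = brute_force_descriptive(values, groups)
        assert row["Standard.Deviation"] == pytest.approx(sd, abs=1e-10)
        assert row["sum.mean.square.diff"] == pytest.approx(smsd, abs=1e-10)
        assert row["sum.SD.square.diff"] == pytest.approx(ssdd, abs=1e-10)


def test_shift_invariance_and_quadratic_scaling(rng):
    values = rng.normal(22, 1.5, size=12)
    groups = ["A"] * 6 + ["B"] * 6
    base = brute_force_descriptive(values, groups)
    for gene_vals in [values + 7.5]:
        shifted = brute_force_descriptive(gene_vals, groups)
        assert shifted[1] == pytest.approx(base[1])
        assert shifted[2] == pytest.approx(base[2])
    table = make_table([[v] for v in values * 3.0], groups, genes=["R1"])
    panel = assign_roles(table, [])
    row = descriptive_stability(table, panel).set_index("analyte").loc["R1"]
    assert row["sum.mean.square.diff"] == pytest.approx(9.0 * base[1])


# ---------------------------------------------------------------------------
# leave-one-out evaluation
# ---------------------------------------------------------------------------

def test_leave_one_out_enumerates_subsets(two_group_table):
    panel = assign_roles(two_group_table, ["T1"])
    out = leave_one_out_evaluation(two_group_table, panel)
    assert set(out["subset"]) == {"R1+R2+R3", "R2+R3", "R1+R3", "R1+R2"}
    assert list(out["rank"]) == [1, 2, 3, 4]


def test_single_reference_gene_returns_itself():
    table = make_table([[20.0, 28.0]] * 3 + [[20.3, 29.0]] * 3,
                       ["A"] * 3 + ["B"] * 3, genes=["R1", "T"])
    panel = assign_roles(table, ["T"])
    out = leave_one_out_evaluation(table, panel)
    assert list(out["subset"]) == ["R1"]


def test_gene_with_group_effect_is_identified_by_leave_one_out():
    # Gene1 carries a 1.5 Cq intergroup shift; dropping it should win.
    # Small per-sample loading effect: MeanRef does not cancel it, and a
    # large one would drown the 1.5/4 Cq MeanRef shift this test isolates.
    effects = np.zeros((4, 2))
    effects[0, 1] = 1.5
    table, _ = simulate_cq(SimConfig(n_genes=4, group_sizes=(15, 15),
                                     group_effects=effects, noise_sd=0.2,
                                     sample_effect_sd=0.1, seed=7))
    panel = assign_roles(table, [])
    out = leave_one_out_evaluation(table, panel)
    assert out.iloc[0]["left_out"] == "Gene1"
    assert out.iloc[0]["meanref_p"] > 0.05
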