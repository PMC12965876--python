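"""Attribution tests: signed variable importance and variation partitioning
against an independent linear-system oracle."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from conftest import glm_frame
from oracles import partition_direct_solve
from soildriver.attribution import attribute_all, variation_partition, vip
from soildriver.glm import fit_glm, two_stage_selection


def random_grouped_frame(rng, n=200, k_groups=3, per_group=2, noise=1.0):
    cols, groups = {}, {}
    letters = "ABCD"[:k_groups]
    beta_parts = []
    for g in letters:
        names = [f"{g.lower()}{j}" for j in range(per_group)]
        groups[g] = names
        for name in names:
            cols[name] = rng.standard_normal(n)
        beta_parts.append(sum(cols[m] for m in names) * rng.uniform(0.02, 0.08))
    eta = 4.0 + sum(beta_parts)
    df = pd.DataFrame(cols)
    df["y"] = np.exp(eta) + rng.normal(0, noise * np.exp(4.0) * 0.05, n)
    return df, groups


class TestVIP:
    def test_importance_is_self_consistent_with_coefficients(self, rng):
        df = glm_frame(rng, n=300, k=4, beta=[0.08, -0.04, 0.02, 0.0])
        fit = fit_glm(df, "y", ["x1", "x2", "x3", "x4"])
        table = vip(fit)
        for term in fit.terms:
            expected = abs(fit.params[term] / fit.bse[term])
            assert table.loc[term, "importance"] == pytest.approx(expected, abs=1e-12)

    def test_ranks_and_signs_follow_t_statistics(self, rng):
        n = 4000
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        y = np.exp(4 + 0.04 * x1 - 0.02 * x2) + rng.normal(0, 5, n)
        fit = fit_glm(pd.DataFrame({"x1": x1, "x2": x2, "y": y}), "y", ["x1", "x2"])
        table = vip(fit)
        assert table.loc["x1", "rank"] == 1 and table.loc["x2", "rank"] == 2
        assert table.loc["x1", "sign"] == "+" and table.loc["x2", "sign"] == "-"

    def test_factor_term_summarized_by_max_component(self, rng):
        n = 500
        eco = rng.choice(["a", "b", "c"], n)
        x = rng.standard_normal(n)
        y = np.exp(4 + 0.1 * (eco == "c") + 0.03 * x) + rng.normal(0, 3, n)
        df = pd.DataFrame({"eco": pd.Categorical(eco), "x1": x, "y": y})
        fit = fit_glm(df, "y", ["eco", "x1"])
        table = vip(fit)
        comp = np.abs(fit.params[["eco_b", "eco_c"]] / fit.bse[["eco_b", "eco_c"]])
        assert table.loc["eco", "importance"] == pytest.approx(comp.max(), abs=1e-12)


class TestPartition:
    def test_single_group_decomposition(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=1)
        part = variation_partition(df, "y", {"A": groups["A"]})
        fit = fit_glm(df, "y", groups["A"])
        assert part.unique["A"] == pytest.approx(fit.r2, abs=1e-12)
        assert part.residual == pytest.approx(1 - fit.r2, abs=1e-12)

    def test_two_group_textbook_identities(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=2)
        part = variation_partition(df, "y", groups)
        rA = part.r2[frozenset("A")]
        rB = part.r2[frozenset("B")]
        rAB = part.r2[frozenset("AB")]
        assert part.unique["A"] == pytest.approx(rAB - rB, abs=1e-10)
        assert part.fractions[frozenset("AB")] == pytest.approx(rA + rB - rAB, abs=1e-10)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_direct_linear_system_oracle(self, k):
        rng = np.random.default_rng(7 + k)
        for rep in range(5):
            df, groups = random_grouped_frame(rng, n=150, k_groups=k, per_group=1)
            part = variation_partition(df, "y", groups)
            oracle = partition_direct_solve(part.r2, sorted(groups))
            for subset, frac in part.fractions.items():
                assert frac == pytest.approx(oracle[subset], abs=1e-10)

    def test_fractions_plus_residual_sum_to_one(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=4, per_group=1)
        part = variation_partition(df, "y", groups)
        total = sum(part.fractions.values()) + part.residual
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_unique_equals_full_minus_reduced(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=3)
        part = variation_partition(df, "y", groups)
        for g in groups:
            reduced = {h: t for h, t in groups.items() if h != g}
            rest = variation_partition(df, "y", reduced)
            assert part.unique[g] == pytest.approx(
                part.full_r2 - rest.full_r2, abs=1e-10)

    def test_permutation_invariance_of_group_labels(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=3)
        base = variation_partition(df, "y", groups)
        for perm in permutations(groups):
            relabeled = {f"G{i}": groups[g] for i, g in enumerate(perm)}
            part = variation_partition(df, "y", relabeled)
            mapping = {f"G{i}": g for i, g in enumerate(perm)}
            for subset, frac in part.fractions.items():
                original = frozenset(mapping[g] for g in subset)
                assert frac == pytest.approx(base.fractions[original], abs=1e-10)

    def test_orthogonal_groups_have_vanishing_shared_fractions(self):
        # near-linear link (small coefficients), orthogonalized columns
        rng = np.random.default_rng(99)
        shared_max = []
        for rep in range(20):
            n = 5000
            q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
            x = q * np.sqrt(n)
            eta = 4.0 + 0.03 * x[:, 0] + 0.03 * x[:, 1] + 0.03 * x[:, 2]
            df = pd.DataFrame(x, columns=["a0", "b0", "c0"])
            df["y"] = np.exp(eta) + rng.normal(0, 2.0, n)
            part = variation_partition(df, "y", {"A": ["a0"], "B": ["b0"], "C": ["c0"]})
            shared = [f for s, f in part.fractions.items() if len(s) > 1]
            shared_max.append(np.max(np.abs(shared)))
        assert np.mean(shared_max) < 0.02

    def test_empty_group_contributes_zero(self, rng):
        df, groups = random_grouped_frame(rng, k_groups=2)
        part = variation_partition(df, "y", {**groups, "C": []})
        assert part.unique["C"] == 0.0
        assert "C" not in {g for s in part.fractions for g in s}

    def test_negative_shared_fractions_pass_through(self, rng):
        # suppressor configuration: x2 correlated with x1 but not with y
        n = 500
        x1 = rng.standard_normal(n)
        x2 = x1 + 0.3 * rng.standard_normal(n)
        y = np.exp(4 + 0.1 * (x1 - x2)) + rng.normal(0, 2, n)
        df = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        part = variation_partition(df, "y", {"A": ["x1"], "B": ["x2"]})
        assert part.fractions[frozenset("AB")] < 0  # not clipped


class TestAttributeAll:
    def test_stacked_outputs_and_partition_identity(self, rng):
        n = 300
        soil = rng.standard_normal((n, 2))
        pest = rng.standard_normal((n, 2))
        df = pd.DataFrame(np.column_stack([soil, pest]),
                          columns=["s1", "s2", "p1", "p2"])
        for name, coef in [("m1", 0.08), ("m2", 0.0)]:
            df[name] = np.exp(4 + coef * pest[:, 0] + 0.06 * soil[:, 0]) \
                + rng.normal(0, 3, n)
        models = {
            name: two_stage_selection(df, name, ["s1", "s2"], [], ["p1", "p2"],
                                      ecosystem_term=None)
            for name in ("m1", "m2")
        }
        partitions, vips = attribute_all(models, df)
        # partition identity per metric: regions + residual sum to 1 (rows for
        # groups absent from a model carry exactly 0, so they do not disturb it)
        for name in ("m1", "m2"):
            sub = partitions[partitions["metric"] == name]
            assert sub["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
            assert "residual" in set(sub["subset"])
            for g in ("pesticides", "soil", "climate", "ecosystem"):
                assert any(g in s for s in sub["subset"])
        assert set(vips["metric"]) <= {"m1", "m2"}
        assert {"importance", "sign", "group", "rank"} <= set(vips.columns)
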