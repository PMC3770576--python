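"""Covariate-adjusted contrast testing and permutation correction."""

import itertools
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from oracles import exhaustive_group_f_pvalue
from mtscan import (
    ScanConfig,
    adjusted_group_test,
    bonferroni_per_test_alpha,
    build_network,
    enumerate_contrasts,
    find_planted_contrast,
    partition_individuals,
    permutation_scan,
    resolve_ambiguities,
    scan_both_models,
    score_ancestry,
    second_round_scan,
    single_variant_scan,
)
from mtscan.treescan import _permutation_indices, _scan_engine


@pytest.fixture(scope="module")
def planted_scan(small_sim):
    net = build_network(small_sim.haplotypes, variants=small_sim.matrix.variants)
    score_ancestry(net)
    resolve_ambiguities(net)
    contrasts = enumerate_contrasts(net, small_sim.haplotypes)
    return net, contrasts


class TestAdjustedGroupTest:
    def test_equals_squared_pooled_t(self):
        y = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        g = np.array([0.0, 0, 0, 1, 1, 1])
        f, p = adjusted_group_test(y, g, None)
        t = stats.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert f == pytest.approx(150.0, abs=1e-9)
        assert f == pytest.approx(t.statistic**2, abs=1e-9)
        assert t.statistic == pytest.approx(12.247, abs=1e-3)
        assert p == pytest.approx(t.pvalue, abs=1e-12)

    def test_equal_means_give_zero_f(self):
        y = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array([0.0, 0, 0, 1, 1, 1])
        f, p = adjusted_group_test(y, g, None)
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_covariate_absorbs_confounded_signal(self, rng):
        # y is exactly the age covariate; groups differ only through age
        age = rng.normal(70, 5, size=40)
        g = (age > np.median(age)).astype(float)
        f, p = adjusted_group_test(age, g, age[:, None])
        assert f == pytest.approx(0.0, abs=1e-6)

    def test_matches_statsmodels_partial_f(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 60
        C = rng.normal(size=(n, 2))
        g = rng.integers(0, 2, size=n).astype(float)
        y = 0.5 * C[:, 0] + 0.8 * g + rng.normal(size=n)
        f, p = adjusted_group_test(y, g, C)
        X = sm.add_constant(np.column_stack([C, g]))
        fit = sm.OLS(y, X).fit()
        assert f == pytest.approx(fit.tvalues[-1] ** 2, rel=1e-9)
        assert p == pytest.approx(fit.pvalues[-1], rel=1e-9)

    def test_collinear_group_rejected(self):
        y = np.arange(6.0)
        g = np.array([0.0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError, match="collinear"):
            adjusted_group_test(y, g, g[:, None])


class TestPartitionIndividuals:
    def test_missing_phenotype_excluded(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        subjects = small_sim.subjects.copy()
        c = contrasts[0]
        victim = sorted(c.individuals_a)[0]
        subjects.loc[victim, "y"] = np.nan
        ids_a, ids_b = partition_individuals(
            c, small_sim.haplotypes, subjects, "y", ("age", "sex")
        )
        assert victim not in ids_a and victim not in ids_b
        assert len(ids_a) == len(c.individuals_a) - 1
        assert len(ids_b) == len(c.individuals_b)

    def test_planted_clade_tally(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        pc = find_planted_contrast(contrasts, small_sim.truth)
        assert pc is not None
        ids_a, ids_b = partition_individuals(
            pc, small_sim.haplotypes, small_sim.subjects, "y", ("age", "sex")
        )
        clade = small_sim.truth.clade_ids
        assert set(ids_a) == clade or set(ids_b) == clade


class TestPermutationScan:
    def test_single_contrast_corrected_equals_nominal(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        cfg = ScanConfig(n_permutations=500, seed=3, nominal_p="permutation")
        rep = permutation_scan(contrasts[:1], small_sim.subjects, cfg)
        (r,) = rep.results
        assert r.corrected_p == pytest.approx(r.nominal_p, abs=1e-12)

    def test_duplicated_contrasts_share_pvalues(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        c = contrasts[0]
        dup = replace(c) if hasattr(c, "__dataclass_fields__") else c
        cfg = ScanConfig(n_permutations=500, seed=3, nominal_p="permutation")
        rep = permutation_scan([c, dup], small_sim.subjects, cfg)
        r1, r2 = rep.results
        assert r1.nominal_p == r2.nominal_p
        assert r1.corrected_p == r2.corrected_p
        # duplicated family is effectively one test
        assert r1.corrected_p == pytest.approx(r1.nominal_p, abs=1e-12)

    def test_seeded_determinism(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        cfg = ScanConfig(n_permutations=300, seed=11)
        rep1 = permutation_scan(contrasts, small_sim.subjects, cfg)
        rep2 = permutation_scan(contrasts, small_sim.subjects, cfg)
        assert [
            (r.contrast_id, r.f_statistic, r.nominal_p, r.corrected_p)
            for r in rep1.results
        ] == [
            (r.contrast_id, r.f_statistic, r.nominal_p, r.corrected_p)
            for r in rep2.results
        ]

    def test_corrected_at_least_nominal_and_stepdown_monotone(
        self, small_sim, planted_scan
    ):
        _, contrasts = planted_scan
        for mode in ("analytic", "permutation"):
            cfg = ScanConfig(n_permutations=300, seed=2, nominal_p=mode)
            rep = permutation_scan(contrasts, small_sim.subjects, cfg)
            assert rep.results
            for r in rep.results:
                assert 0.0 <= r.nominal_p <= 1.0
                assert r.corrected_p >= r.nominal_p - 1e-15
            by_p = sorted(rep.results, key=lambda r: r.nominal_p)
            corr = [r.corrected_p for r in by_p]
            assert all(a <= b + 1e-15 for a, b in zip(corr, corr[1:]))
            if mode == "analytic":
                by_f = sorted(rep.results, key=lambda r: -r.f_statistic)
                corr_f = [r.corrected_p for r in by_f]
                assert all(a <= b + 1e-15 for a, b in zip(corr_f, corr_f[1:]))

    def test_planted_contrast_found(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        cfg = ScanConfig(n_permutations=500, seed=4)
        reports = scan_both_models(contrasts, small_sim.subjects, cfg)
        pc = find_planted_contrast(contrasts, small_sim.truth)
        for rep in reports.values():
            best = min(rep.results, key=lambda r: r.nominal_p)
            assert best.contrast_id == pc.contrast_id
            assert rep.result(pc.contrast_id).corrected_p <= 0.05

    def test_min_group_filter_reports_skip(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        cfg = ScanConfig(n_permutations=200, seed=1, min_group=1000)
        rep = permutation_scan(contrasts, small_sim.subjects, cfg)
        assert not rep.results
        assert len(rep.skipped) == len(contrasts)
        assert all("min-group" in reason for _, reason in rep.skipped)

    def test_every_contrast_tested_or_skipped(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        cfg = ScanConfig(n_permutations=200, seed=1, min_group=10)
        rep = permutation_scan(contrasts, small_sim.subjects, cfg)
        seen = {r.contrast_id for r in rep.results} | {c for c, _ in rep.skipped}
        assert seen == {c.contrast_id for c in contrasts}

    def test_exhaustive_reduction_to_classical_permutation_test(self, rng):
        """With no covariates and all n! permutations, the nominal p matches
        the classical two-sample permutation test."""
        for _ in range(5):
            n_a, n_b = 3, 4
            y = rng.normal(size=n_a + n_b)
            g = np.array([1.0] * n_a + [0.0] * n_b)
            n = len(y)
            X = np.ones((n, 1))
            perm_idx = np.array(list(itertools.permutations(range(n))))
            cfg = ScanConfig(n_permutations=len(perm_idx), seed=0, nominal_p="permutation")
            F_obs, p_obs, _ = _scan_engine(y, X, g[:, None], cfg, perm_idx)
            classical = exhaustive_group_f_pvalue(y, n_a, F_obs[0])
            assert p_obs[0] == pytest.approx(classical, abs=2.0 / len(perm_idx))


class TestSecondRound:
    def test_single_haplotype_side_unsplittable(self, small_sim, planted_scan):
        _, contrasts = planted_scan
        singles = [c for c in contrasts if len(c.side_a) == 1]
        assert singles
        cfg = ScanConfig(n_permutations=200, seed=0)
        rep = second_round_scan(singles[0], contrasts, small_sim.subjects, cfg)
        reasons = dict(rep.skipped)
        key = f"{singles[0].contrast_id}/A"
        assert key in reasons and "unsplittable" in reasons[key]

    def test_equal_submeans_conditional_p_near_one(self):
        """Two sub-haplotypes with identical phenotype means inside the
        focal side give a conditional p close to 1."""
        import pandas as pd

        from conftest import make_haplotypes
        from mtscan.network import Contrast

        haps = make_haplotypes(["00", "01", "11"], counts=[6, 7, 10])
        ids = sorted(set().union(*[h.members for h in haps]))
        rng = np.random.default_rng(0)
        side = frozenset(haps[0].members | haps[1].members)
        y = {}
        for i in ids:
            y[i] = 5.0 if i in side else 0.0  # identical values within the side
        subjects = pd.DataFrame(
            {
                "individual_id": ids,
                "age": rng.normal(75, 7, len(ids)),
                "sex": rng.choice(["male", "female"], len(ids)),
                "apoe4": rng.integers(0, 2, len(ids)),
                "y": [y[i] for i in ids],
            }
        ).set_index("individual_id", drop=False)
        sig = Contrast(
            contrast_id="C001",
            branch_ids=[1],
            resolution_id="R0",
            side_a=frozenset({"H001", "H002"}),
            side_b=frozenset({"H003"}),
            individuals_a=side,
            individuals_b=frozenset(haps[2].members),
        )
        sub = Contrast(
            contrast_id="C002",
            branch_ids=[2],
            resolution_id="R0",
            side_a=frozenset({"H001"}),
            side_b=frozenset({"H002", "H003"}),
            individuals_a=frozenset(haps[0].members),
            individuals_b=frozenset(haps[1].members | haps[2].members),
        )
        cfg = ScanConfig(n_permutations=500, seed=9, min_group=5)
        rep = second_round_scan(sig, [sig, sub], subjects, cfg)
        conditional = [r for r in rep.results if r.model_tag == "conditional_A"]
        assert conditional
        assert conditional[0].nominal_p > 0.9

    def test_nested_effect_recovered(self):
        """A sub-clade boost on top of a clade shift is localized by the
        conditional scan."""
        import pandas as pd

        from conftest import make_haplotypes
        from mtscan.network import Contrast

        rng = np.random.default_rng(5)
        haps = make_haplotypes(["00", "01", "11"], counts=[15, 15, 30])
        side = frozenset(haps[0].members | haps[1].members)
        boost = frozenset(haps[0].members)
        ids = sorted(set().union(*[h.members for h in haps]))
        yv = []
        for i in ids:
            base = 2.0 if i in side else 0.0
            base += 3.0 if i in boost else 0.0
            yv.append(base + rng.normal(0, 1))
        subjects = pd.DataFrame(
            {
                "individual_id": ids,
                "age": rng.normal(75, 7, len(ids)),
                "sex": rng.choice(["male", "female"], len(ids)),
                "apoe4": rng.integers(0, 2, len(ids)),
                "y": yv,
            }
        ).set_index("individual_id", drop=False)
        sig = Contrast(
            contrast_id="C001",
            branch_ids=[1],
            resolution_id="R0",
            side_a=frozenset({"H001", "H002"}),
            side_b=frozenset({"H003"}),
            individuals_a=side,
            individuals_b=frozenset(haps[2].members),
        )
        sub = Contrast(
            contrast_id="C002",
            branch_ids=[2],
            resolution_id="R0",
            side_a=frozenset({"H001"}),
            side_b=frozenset({"H002", "H003"}),
            individuals_a=boost,
            individuals_b=frozenset(haps[1].members | haps[2].members),
        )
        cfg = ScanConfig(n_permutations=500, seed=3, min_group=5)
        rep = second_round_scan(sig, [sig, sub], subjects, cfg)
        cond = [r for r in rep.results if r.model_tag == "conditional_A"]
        assert cond and cond[0].nominal_p < 0.01


class TestSingleVariantScan:
    def test_planted_site_has_smallest_p(self, small_sim):
        truth = small_sim.truth
        site = truth.edge_site[truth.planted_child]
        table = single_variant_scan(
            small_sim.matrix,
            small_sim.subjects,
            "y",
            covariates=("age", "sex", "apoe4_count"),
        )
        best = table.loc[table["p_value"].idxmin()]
        planted_pos = small_sim.matrix.variants[site].rcrs_position
        assert best["rcrs_position"] == planted_pos

    def test_monomorphic_site_reported_absent(self, small_sim):
        import pandas as pd

        matrix = small_sim.matrix
        calls = matrix.calls.copy()
        calls[:, 0] = 0
        from mtscan import GenotypeMatrix

        m2 = GenotypeMatrix(matrix.individual_ids, matrix.variants, calls)
        table = single_variant_scan(m2, small_sim.subjects, "y")
        row = table.iloc[0]
        assert pd.isna(row["p_value"]) and "monomorphic" in row["note"]

    def test_per_test_alpha_matches_printed_value(self):
        assert bonferroni_per_test_alpha(138, 0.05) == pytest.approx(0.0003)
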