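import numpy as np
import pytest

from traitrank.genome import parental_population, simulate_f2
from traitrank.traits import (
    SCENARIO_POSITIONS,
    ScenarioConfig,
    TraitArchitecture,
    assign_control_loci,
    build_architectures,
    genotypic_contribution,
    genotypic_value,
    realized_heritability,
    simulate_phenotypes,
)


class TestControlLociAssignment:
    def test_principal_trait_covers_groups_1_to_5(self, default_map):
        loci = assign_control_loci("PT1", 1, default_map)
        assert len(loci) == 40
        assert set(default_map.group_of(loci)) == {1, 2, 3, 4, 5}
        # all eight candidates per group
        assert loci[:8].tolist() == [10, 20, 30, 40, 50, 60, 70, 80]

    def test_null_trait_is_disjoint_from_principal(self, default_map):
        pt1 = assign_control_loci("PT1", 1, default_map)
        pt2 = assign_control_loci("PT2", 1, default_map)
        assert len(pt2) == 40
        assert set(default_map.group_of(pt2)) == {6, 7, 8, 9, 10}
        assert not set(pt1) & set(pt2)

    def test_shared_trait_overlaps_principal_by_20_in_scenario_1(self, default_map):
        pt1 = assign_control_loci("PT1", 1, default_map)
        pt5 = assign_control_loci("PT5", 1, default_map)
        assert len(pt5) == 40
        assert len(set(pt1) & set(pt5)) == 20  # 4 loci in each of groups 1-5

    @pytest.mark.parametrize("scenario,first_group", [
        (1, [10, 20, 30, 40]), (2, [50, 60, 70, 80]),
        (3, [10, 20, 70, 80]), (4, [30, 40, 50, 60]),
    ])
    def test_scenario_positions(self, default_map, scenario, first_group):
        loci = assign_control_loci("PT3", scenario, default_map)
        assert loci[:4].tolist() == first_group
        assert len(loci) == 40

    def test_partial_layout_trait(self, default_map):
        # PT9 uses 4 loci on group 1, all 8 on groups 6-9, 4 on group 10
        loci = assign_control_loci("PT9", 1, default_map)
        groups, counts = np.unique(default_map.group_of(loci), return_counts=True)
        assert dict(zip(groups.tolist(), counts.tolist())) == {1: 4, 6: 8, 7: 8, 8: 8, 9: 8, 10: 4}

    def test_unknown_trait_and_scenario_rejected(self, default_map):
        with pytest.raises(ValueError):
            assign_control_loci("PT99", 1, default_map)
        with pytest.raises(ValueError):
            ScenarioConfig(5)

    def test_all_traits_have_40_loci_in_every_scenario(self, default_map):
        for sc in SCENARIO_POSITIONS:
            for tid in (f"PT{i}" for i in range(1, 12)):
                assert len(assign_control_loci(tid, sc, default_map)) == 40


class TestGenotypicModel:
    def test_contribution_per_genotype_class(self):
        assert genotypic_contribution(1, 1, 0.5) == 1.0
        assert genotypic_contribution(0, 1, 0.5) == 0.5
        assert genotypic_contribution(-1, 1, 0.5) == -1.0
        with pytest.raises(ValueError):
            genotypic_contribution(2)

    def test_constant_weight_all_homozygous(self):
        # all 40 loci AA with weight p: additive 40p, epistatic 39p
        p = 0.3
        arch = TraitArchitecture("PT1", np.arange(40), np.full(40, p), 0.5, mu=0.0)
        assert genotypic_value(np.ones(40, dtype=int), arch) == pytest.approx(79 * p)

    def test_zero_weights_leave_only_mean(self):
        arch = TraitArchitecture("PT1", np.arange(40), np.zeros(40), 0.5, mu=100.0)
        assert genotypic_value(np.zeros(40, dtype=int), arch) == pytest.approx(100.0)

    def test_two_locus_hand_computation(self):
        # p=(0.5,0.2), genotypes (AA,aa): 0.5*1 + 0.2*(-1) + 0.5*1*(-1) = -0.2
        arch = TraitArchitecture("PT1", np.array([1, 2]), np.array([0.5, 0.2]), 0.5, mu=0.0)
        assert genotypic_value(np.array([1, -1]), arch) == pytest.approx(-0.2)

    def test_length_mismatch_rejected(self):
        arch = TraitArchitecture("PT1", np.arange(40), np.full(40, 0.5), 0.5)
        with pytest.raises(ValueError):
            genotypic_value(np.ones(39, dtype=int), arch)


class TestSimulatePhenotypes:
    def test_error_variance_follows_heritability(self, default_table):
        # sigma_e^2 = (1 - h2) sigma_g^2 / h2
        for tid, h2 in (("PT1", 0.5), ("PT5", 0.8), ("PT3", 0.3)):
            ratio = default_table.sigma_e2[tid] / default_table.sigma_g2[tid]
            assert ratio == pytest.approx((1 - h2) / h2)

    def test_phenotype_decomposition_identity(self, default_table):
        total = default_table.genotypic_values + default_table.errors
        assert np.allclose(total.to_numpy(), default_table.phenotypes.to_numpy())

    def test_noiseless_limit(self, default_map):
        geno = simulate_f2(default_map, 100, seed=1)
        arch = build_architectures(1, default_map, seed=1, trait_ids=("PT1",))
        arch["PT1"].h2 = 1.0
        table = simulate_phenotypes(geno, arch, seed=2)
        assert np.allclose(table.phenotypes["PT1"], table.genotypic_values["PT1"])
        assert realized_heritability(table, "PT1") == pytest.approx(1.0)

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError):
            TraitArchitecture("PT1", np.arange(40), np.full(40, 0.5), 0.0)

    def test_monomorphic_population_rejected(self, default_map):
        geno = parental_population(default_map, 50, "P1")
        arch = build_architectures(1, default_map, seed=1, trait_ids=("PT1",))
        with pytest.raises(ValueError, match="variance"):
            simulate_phenotypes(geno, arch, seed=0)

    def test_weight_scaling_leaves_heritability_unchanged(self, default_map):
        geno = simulate_f2(default_map, 300, seed=4)
        archs = build_architectures(1, default_map, seed=4, trait_ids=("PT1",), mu=0.0)
        scaled = build_architectures(1, default_map, seed=4, trait_ids=("PT1",), mu=0.0)
        scaled["PT1"].weights = scaled["PT1"].weights * 7.0
        h2_a = realized_heritability(simulate_phenotypes(geno, archs, seed=5), "PT1")
        h2_b = realized_heritability(simulate_phenotypes(geno, scaled, seed=5), "PT1")
        assert h2_a == pytest.approx(h2_b, abs=1e-12)


class TestHeritabilityRecovery:
    def test_mean_realized_h2_tracks_targets(self, default_map):
        # light version of the 200-replicate recovery check
        sums = {"PT1": 0.0, "PT3": 0.0, "PT5": 0.0}
        n_rep = 30
        for rep in range(n_rep):
            rng = np.random.default_rng([100, rep])
            geno = simulate_f2(default_map, 500, rng)
            archs = build_architectures(1, default_map, rng, trait_ids=tuple(sums))
            table = simulate_phenotypes(geno, archs, rng)
            for tid in sums:
                sums[tid] += realized_heritability(table, tid)
        assert sums["PT1"] / n_rep == pytest.approx(0.5, abs=0.05)
        assert sums["PT3"] / n_rep == pytest.approx(0.3, abs=0.05)
        assert sums["PT5"] / n_rep == pytest.approx(0.8, abs=0.05)

    def test_shared_architecture_orders_phenotypic_correlations(self, default_map):
        # corr(PT1, PT5) > corr(PT1, PT3): same shared loci, h2 0.8 vs 0.3
        c15, c13 = [], []
        for rep in range(15):
            rng = np.random.default_rng([200, rep])
            geno = simulate_f2(default_map, 500, rng)
            archs = build_architectures(1, default_map, rng)
            table = simulate_phenotypes(geno, archs, rng)
            Y = table.phenotypes
            c15.append(np.corrcoef(Y["PT1"], Y["PT5"])[0, 1])
            c13.append(np.corrcoef(Y["PT1"], Y["PT3"])[0, 1])
        assert np.mean(c15) > np.mean(c13)

    def test_disjoint_traits_have_near_zero_genetic_correlation(self, default_table):
        g = default_table.genotypic_values
        assert abs(np.corrcoef(g["PT1"], g["PT2"])[0, 1]) < 0.15
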