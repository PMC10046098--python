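"""Templates, X-linked gene dropping, trait generation, and the full pipeline."""

import numpy as np
import pytest

from xciskew import (
    MISSING,
    SimulationConfig,
    apply_missingness,
    dichotomize,
    drop_x_genotypes,
    kinship_matrix,
    pedigree_templates,
    simulate_mixed_dataset,
    simulate_quantitative,
)
from xciskew.pedigree import FEMALE, build_pedigree
from xciskew.simulate import instantiate_template, population_threshold


class TestTemplates:
    def test_sizes(self):
        assert tuple(t.size for t in pedigree_templates()) == (4, 10, 12)

    @pytest.mark.parametrize("copies,total", [(50, 1300), (200, 5200)])
    def test_total_members(self, copies, total):
        assert copies * sum(t.size for t in pedigree_templates()) == total

    def test_instantiation_valid_and_sex_ratio(self, rng):
        counts = {FEMALE: 0, "male": 0}
        for tmpl in pedigree_templates():
            for k in range(200):
                ped = instantiate_template(tmpl, f"{tmpl.name}{k}", rng)
                assert len(ped) == tmpl.size
                for m in ped.members:
                    counts[m.sex] += 1
        total = counts[FEMALE] + counts["male"]
        assert counts[FEMALE] / total == pytest.approx(0.5, abs=0.03)


class TestGeneDrop:
    def test_mother_het_father_d_daughter(self, rng):
        ped = build_pedigree(
            [("f", None, None, "male"), ("m", None, None, "female"),
             ("d", "f", "m", "female")]
        )
        hits = {"dd": 0, "Dd": 0}
        n = 0
        for _ in range(4000):
            g = drop_x_genotypes(ped, pf=0.5, pm=0.0, rng=rng)
            if g["m"] == "Dd":  # condition on the heterozygous mother
                hits[g["d"]] = hits.get(g["d"], 0) + 1
                n += 1
        assert set(hits) <= {"dd", "Dd"}
        assert hits["Dd"] / n == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_mother_homozygous_son_deterministic(self, rng):
        ped = build_pedigree(
            [("f", None, None, "male"), ("m", None, None, "female"),
             ("s", "f", "m", "male")]
        )
        for _ in range(200):
            g = drop_x_genotypes(ped, pf=1.0, pm=0.3, rng=rng)
            assert g["m"] == "DD" and g["s"] == "D"

    def test_founder_allele_frequency(self, rng):
        ped = build_pedigree([("fem", None, None, "female")])
        count = {"dd": 0, "Dd": 0, "DD": 0}
        n = 100_000
        for _ in range(n):
            count[drop_x_genotypes(ped, 0.3, 0.3, rng)["fem"]] += 1
        freq = (count["Dd"] + 2 * count["DD"]) / (2 * n)
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert freq == pytest.approx(0.3, abs=3 * se)

    def test_allele_frequency_conserved_across_generations(self, rng):
        """Gene dropping with pf = pm = p keeps the D frequency at p."""
        tmpl = pedigree_templates()[2]  # four generations
        p = 0.3
        dosage = []
        for k in range(3000):
            ped = instantiate_template(tmpl, f"t{k}", rng)
            g = drop_x_genotypes(ped, p, p, rng)
            for m in ped.members:
                if m.sex == FEMALE and not m.is_founder:
                    dosage.append({"dd": 0, "Dd": 1, "DD": 2}[g[m.id]])
        freq = np.mean(dosage) / 2.0
        se = np.std(dosage, ddof=1) / 2.0 / np.sqrt(len(dosage))
        assert freq == pytest.approx(p, abs=3 * se)


class TestQuantitative:
    def test_degenerate_mean(self, rng):
        cfg = SimulationConfig(beta0=0.5, beta=0.0, delta=0.0, sigma_g2=1e-12,
                               sigma_e2_by_genotype=(1.0, 1.0, 1.0))
        y, _ = simulate_quantitative(["dd"] * 10_000, 1.0, cfg, None, rng)
        se = y.std(ddof=1) / np.sqrt(len(y))
        assert y.mean() == pytest.approx(0.5, abs=3 * se)

    def test_sister_covariance(self, rng):
        ped = build_pedigree(
            [("f", None, None, "male"), ("m", None, None, "female"),
             ("s1", "f", "m", "female"), ("s2", "f", "m", "female")]
        )
        psi = kinship_matrix(ped).restrict(["s1", "s2"])
        cfg = SimulationConfig(beta=0.0, delta=0.0, sigma_g2=1.0,
                               sigma_e2_by_genotype=(1e-12, 1e-12, 1e-12))
        ys = np.array([
            simulate_quantitative(["dd", "dd"], 1.0, cfg, psi, rng)[0]
            for _ in range(10_000)
        ])
        cov = np.cov(ys.T)
        # 2 * sigma_g^2 * kinship(sibs) = 2 * 1 * 0.25
        assert cov[0, 1] == pytest.approx(0.5, abs=0.05)
        assert cov[0, 0] == pytest.approx(1.0, abs=0.06)

    def test_heteroscedastic_unrelated_variance(self, rng):
        cfg = SimulationConfig(beta=0.0, delta=0.0, sigma_g2=0.5,
                               sigma_e2_by_genotype=(1.0, 1.2, 1.0))
        y, _ = simulate_quantitative(["Dd"] * 20_000, 1.0, cfg, None, rng)
        assert y.var(ddof=1) == pytest.approx(1.7, rel=0.05)

    def test_unknown_genotype_rejected(self, rng):
        with pytest.raises(ValueError, match="cannot code"):
            simulate_quantitative([MISSING], 1.0, SimulationConfig(), None, rng)


class TestDichotomize:
    def test_prevalence_recovered(self, rng):
        cfg = SimulationConfig(prevalence=0.3)
        y, _ = simulate_quantitative(
            ["Dd"] * 100_000, 1.0, cfg, None, rng
        )
        thr = population_threshold(cfg, 1.0, [0.0, 1.0, 0.0])
        cases = dichotomize(y, 0.3, threshold=thr)
        se = np.sqrt(0.3 * 0.7 / len(y))
        assert cases.mean() == pytest.approx(0.3, abs=3 * se)

    def test_zero_prevalence_all_controls(self):
        assert dichotomize(np.arange(10.0), 0.0).sum() == 0

    def test_constant_trait_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            dichotomize(np.ones(50), 0.3)

    def test_affected_set_is_below_threshold(self, rng):
        y = rng.normal(size=500)
        cases = dichotomize(y, 0.3, threshold=0.1)
        assert np.array_equal(cases == 1.0, y < 0.1)


class TestMissingness:
    def test_zero_rate_unchanged(self, rng):
        g = np.array(["dd", "Dd", "DD"], dtype=object)
        assert list(apply_missingness(g, 0.0, rng)) == list(g)

    def test_full_rate_all_missing(self, rng):
        out = apply_missingness(np.array(["dd"] * 20, dtype=object), 1.0, rng)
        assert all(x == MISSING for x in out)

    def test_rate_recovered(self, rng):
        out = apply_missingness(np.array(["Dd"] * 10_000, dtype=object), 0.4, rng)
        frac = np.mean([x == MISSING for x in out])
        assert frac == pytest.approx(0.4, abs=3 * np.sqrt(0.4 * 0.6 / 10_000))


class TestMixedPipeline:
    def test_counts_and_structure(self):
        cfg = SimulationConfig(n_pedigrees_per_structure=5,
                               n_unrelated_females=30, seed=3)
        d = simulate_mixed_dataset(cfg)
        assert d.n_unrelated_females == 30
        assert d.nf == d.n_pedigree_females + 30
        phi = d.relatedness.values
        n_ped = d.n_pedigree_females
        assert np.array_equal(phi[n_ped:, n_ped:], np.eye(30))
        assert np.allclose(np.diag(phi), 1.0)

    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_pedigrees_per_structure=3,
                               n_unrelated_females=10, seed=11)
        d1 = simulate_mixed_dataset(cfg)
        d2 = simulate_mixed_dataset(cfg)
        assert d1.female_ids == d2.female_ids
        assert np.array_equal(d1.traits, d2.traits)
        assert list(d1.genotypes) == list(d2.genotypes)
        assert d1.gamma_truth == d2.gamma_truth

    def test_pedigree_only(self):
        cfg = SimulationConfig(n_pedigrees_per_structure=3,
                               n_unrelated_females=0, seed=5)
        d = simulate_mixed_dataset(cfg)
        assert d.n_unrelated_females == 0
        assert all(s == "pedigree" for s in d.source)

    def test_missingness_prunes_females(self):
        base = SimulationConfig(n_pedigrees_per_structure=20,
                                n_unrelated_females=0, seed=9)
        full = simulate_mixed_dataset(base)
        mr = SimulationConfig(n_pedigrees_per_structure=20,
                              n_unrelated_females=0, missing_rate=0.4, seed=9)
        pruned = simulate_mixed_dataset(mr)
        frac = pruned.n_pedigree_females / full.n_pedigree_females
        assert 0.45 < frac < 0.75  # ~60% retained on average

    def test_qualitative_case_fraction(self):
        cfg = SimulationConfig(n_pedigrees_per_structure=10,
                               n_unrelated_females=300,
                               trait_type="qualitative", seed=17)
        d = simulate_mixed_dataset(cfg)
        assert set(np.unique(d.traits)) <= {0.0, 1.0}
        assert d.traits.mean() == pytest.approx(0.3, abs=0.08)

    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(n_pedigrees_per_structure=2,
                               n_unrelated_females=5, seed=21)
        d = simulate_mixed_dataset(cfg)
        d.write(tmp_path)
        from xciskew import XCIDataset

        back = XCIDataset.read(tmp_path)
        assert back.female_ids == d.female_ids
        assert np.allclose(back.traits, d.traits)
        assert np.allclose(back.relatedness.values, d.relatedness.values)
        assert back.gamma_truth == pytest.approx(d.gamma_truth)
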