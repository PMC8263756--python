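"""Generator tests: determinism, planted structure, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from loyburden.config import SimulationConfig, CarrierGeneSpec, ConfigurationError, gigyf1_like_spec
from loyburden.synthetic import (simulate_cohort, simulate_exome, simulate_loy_inputs,
                                 simulate_phenotypes, simulate_binary_trait,
                                 planted_dosage_matrix)
from loyburden.synthetic.cohort import AlignmentError
from loyburden.vcfio import read_vcf


class TestCohort:
    def test_same_seed_identical(self, small_config):
        a = simulate_cohort(small_config)
        b = simulate_cohort(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effects_equal_prevalence_across_age_tertiles(self):
        cfg = SimulationConfig(n_individuals=6000, clone_age_log_odds_per_decade=0.0,
                               clone_smoking_log_odds=0.0, seed=5)
        coh = simulate_cohort(cfg)
        tert = pd.qcut(coh["age"], 3, labels=False, duplicates="drop")
        prev = coh.groupby(tert)["clone_present"].mean()
        p0 = cfg.clone_baseline_prevalence
        se = np.sqrt(p0 * (1 - p0) / (len(coh) / 3))
        assert np.all(np.abs(prev - p0) < 4 * se)

    def test_logistic_recovery_of_age_coefficient(self):
        # fit clone ~ age over replicates; the mean estimate recovers the
        # generating per-decade log-odds within Monte-Carlo error
        gen = 1.1
        est = []
        for rep in range(100):
            cfg = SimulationConfig(n_individuals=1200, seed=1000 + rep,
                                   clone_smoking_log_odds=0.0)
            coh = simulate_cohort(cfg)
            x = (coh["age"] - coh["age"].mean()) / 10.0
            X = sm.add_constant(x.to_numpy())
            fit = sm.GLM(coh["clone_present"].to_numpy(), X,
                         family=sm.families.Binomial()).fit()
            est.append(fit.params[1])
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - gen) < 4 * mc_se + 0.02

    def test_latent_fraction_increases_with_age(self):
        cfg = SimulationConfig(n_individuals=8000, seed=3)
        coh = simulate_cohort(cfg)
        young = coh[coh.age < 50]["clone_present"].mean()
        old = coh[coh.age > 60]["clone_present"].mean()
        assert old > young


class TestLoyInputs:
    def test_no_clone_no_noise_gives_zeros(self):
        cfg = SimulationConfig(n_individuals=50, lrr_probe_sd=0.0,
                               af_loy_noise_sd=0.0, clone_baseline_prevalence=1e-9,
                               clone_age_log_odds_per_decade=0.0,
                               clone_smoking_log_odds=0.0, seed=2)
        coh = simulate_cohort(cfg)
        coh["clone_present"] = 0
        coh["clone_fraction"] = 0.0
        loy = simulate_loy_inputs(coh, cfg)
        assert (loy["mlrr_y"] == 0).all()
        assert (loy["par_loy"] == 0).all()
        assert (loy["af_loy"] == 0).all()
        assert (loy["par_loyq"] == 0).all()

    def test_perfect_detector_calls_exactly_clones(self):
        cfg = SimulationConfig(n_individuals=2000, detection_sensitivity=1.0,
                               detection_false_positive_rate=0.0, seed=4)
        coh = simulate_cohort(cfg)
        loy = simulate_loy_inputs(coh, cfg)
        expected = (coh["clone_fraction"] > 0).astype(float)
        assert (loy["par_loy"] == expected).all()

    def test_af_and_mlrr_track_same_latent_fraction(self, small_config, small_cohort,
                                                    small_measures):
        from scipy.stats import spearmanr
        called = small_measures["par_loy"] == 1
        rho, _ = spearmanr(small_measures.loc[called, "af_loy"],
                           -small_measures.loc[called, "mlrr_y"])
        assert rho > 0

    def test_females_missing(self):
        cfg = SimulationConfig(n_individuals=300, prop_male=0.5, seed=6)
        coh = simulate_cohort(cfg)
        loy = simulate_loy_inputs(coh, cfg)
        females = coh["sex"] == "F"
        assert loy.loc[females.to_numpy(), "mlrr_y"].isna().all()

    def test_af_loy_missing_convention(self):
        cfg = SimulationConfig(n_individuals=300, af_loy_undetected="missing", seed=6)
        coh = simulate_cohort(cfg)
        loy = simulate_loy_inputs(coh, cfg)
        uncalled = loy["par_loy"] == 0
        assert loy.loc[uncalled, "af_loy"].isna().all()


class TestExome:
    def test_seed_determinism_byte_identical(self, small_config, small_cohort,
                                             tmp_path):
        sim1 = simulate_exome(small_cohort, small_config)
        sim2 = simulate_exome(small_cohort, small_config)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        from loyburden.vcfio import write_vcf
        write_vcf(str(p1), sim1.samples, sim1.sites)
        write_vcf(str(p2), sim2.samples, sim2.sites)
        assert p1.read_bytes() == p2.read_bytes()
        pd.testing.assert_frame_equal(sim1.annotations, sim2.annotations)

    def test_planted_frameshift_has_exact_carriers(self, small_sim, small_cohort):
        carriers = small_sim.truth_carriers
        fs_key = carriers.groupby("variant_key").size().idxmax()
        assert (carriers["variant_key"] == fs_key).sum() == 10
        # recount in the genotype arrays themselves
        site = next(s for s in small_sim.sites if s.key == fs_key)
        assert int((site.gt == 1).sum()) == 10
        assert carriers["iid"].nunique() == 40

    def test_qual_and_aq_in_range(self, small_sim):
        quals = np.array([s.qual for s in small_sim.sites])
        aqs = np.array([s.aq for s in small_sim.sites])
        assert quals.min() >= 20 and quals.max() <= 99
        assert aqs.min() >= 20 and aqs.max() <= 99

    def test_truth_matches_independent_text_parse(self, small_sim_paths, small_sim):
        """Brute-force recount of planted QC failures from the raw VCF text,
        with a parser written independently of the package reader."""
        n_samples = len(small_sim.samples)
        fails = {"fail_missingness": set(), "fail_maxdp": set(), "fail_gqfrac": set()}
        bed = [(c, s, e) for c, s, e in small_sim.bed]
        with open(small_sim_paths["vcf"]) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                chrom, pos, ref, alt = f[0], int(f[1]), f[3], f[4]
                key = f"{chrom}:{pos}:{ref}:{alt}"
                on_target = any(c == chrom and s <= pos - 1 < e for c, s, e in bed)
                biallelic = "," not in alt
                calls = f[9:]
                missing = 0
                dps, gqs = [], []
                for cell in calls:
                    gt, dp, gq, ad = cell.split(":")
                    if gt == "./.":
                        missing += 1
                        continue
                    adv = [int(x) for x in ad.split(",")]
                    if on_target and biallelic and sorted(gt.split("/")) == ["0", "1"]:
                        tot = adv[0] + adv[1]
                        if tot > 0 and (adv[1] / tot <= 0.25 or adv[1] / tot >= 0.8):
                            missing += 1  # imbalanced het excluded downstream
                            continue
                    dps.append(int(dp))
                    gqs.append(int(gq))
                n_called = n_samples - missing
                if missing / n_samples > 0.05:
                    fails["fail_missingness"].add(key)
                if n_called == 0 or max(dps) < 10:
                    fails["fail_maxdp"].add(key)
                if n_called > 0 and sum(g < 20 for g in gqs) / n_called > 0.20:
                    fails["fail_gqfrac"].add(key)
        truth = small_sim.truth_sites
        for col, got in fails.items():
            expected = set(truth.loc[truth[col], "variant_key"])
            assert got == expected, col

    def test_too_many_carriers_raises(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_individuals=20,
                             carrier_gene_specs=(gigyf1_like_spec(),))

    def test_roundtrip_through_reader(self, small_sim_paths, small_sim):
        samples, sites = read_vcf(small_sim_paths["vcf"])
        assert samples == small_sim.samples
        assert len(sites) == len(small_sim.sites)
        for a, b in zip(sites, small_sim.sites):
            assert a.key == b.key
            np.testing.assert_array_equal(a.gt, b.gt)
            np.testing.assert_array_equal(np.where(a.dp < 0, -1, a.dp),
                                          np.where(b.dp < 0, -1, b.dp))


class TestPhenotypes:
    def test_null_effect_equal_means(self, rng):
        cfg = SimulationConfig(n_individuals=4000, seed=8,
                               carrier_gene_specs=(CarrierGeneSpec(
                                   gene="G", n_carriers=200,
                                   effect_quantitative=0.0),))
        coh = simulate_cohort(cfg)
        ph = simulate_phenotypes(coh, "G", cfg)
        c = coh["carrier_G"] == 1
        diff = ph.loc[c.to_numpy(), "quant_trait"].mean() - \
            ph.loc[(~c).to_numpy(), "quant_trait"].mean()
        assert abs(diff) < 4 / np.sqrt(200)

    def test_noncarrier_sd_is_one_and_effect_on_that_scale(self):
        cfg = SimulationConfig(n_individuals=5000, seed=9,
                               carrier_gene_specs=(CarrierGeneSpec(
                                   gene="G", n_carriers=500,
                                   effect_quantitative=0.93),))
        coh = simulate_cohort(cfg)
        ph = simulate_phenotypes(coh, "G", cfg)
        nc = (coh["carrier_G"] == 0).to_numpy()
        assert ph.loc[nc, "quant_trait"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        diff = ph.loc[~nc, "quant_trait"].mean() - ph.loc[nc, "quant_trait"].mean()
        assert diff == pytest.approx(0.93, abs=4 / np.sqrt(500))

    def test_binary_baseline_prevalence(self):
        cfg = SimulationConfig(n_individuals=20000, seed=10,
                               binary_trait_baseline_prevalence=0.071)
        coh = simulate_cohort(cfg)
        ph = simulate_phenotypes(coh, np.zeros(len(coh)), cfg)
        prev = ph["binary_trait"].mean()
        assert prev == pytest.approx(0.071, abs=4 * np.sqrt(0.071 * 0.929 / 20000))

    def test_binary_or_recovery(self):
        # logistic fit recovers the generating odds ratio over replicates
        import statsmodels.api as sm
        logors = []
        for rep in range(30):
            rng = np.random.default_rng(300 + rep)
            cfg = SimulationConfig(n_individuals=8000, seed=300 + rep)
            coh = simulate_cohort(cfg)
            carrier = np.zeros(len(coh))
            carrier[rng.choice(len(coh), 60, replace=False)] = 1
            y = simulate_binary_trait(coh, carrier, odds_ratio=6.10,
                                      baseline_prevalence=0.071, rng=rng)
            X = sm.add_constant(carrier)
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            logors.append(fit.params[1])
        mean_or = np.exp(np.mean(logors))
        mc_se = np.std(logors, ddof=1) / np.sqrt(len(logors))
        assert np.log(6.10) == pytest.approx(np.mean(logors), abs=4 * mc_se)
        assert 4.5 < mean_or < 8.5

    def test_misaligned_carrier_raises(self, small_cohort, small_config):
        with pytest.raises(AlignmentError):
            simulate_phenotypes(small_cohort, np.zeros(7), small_config)


def test_planted_dosage_matrix_structure(rng):
    G, carrier = planted_dosage_matrix(rng, 5000)
    assert G.shape[1] == 27
    assert carrier.sum() == 40
    assert G.sum() == 40  # every carrier heterozygous at exactly one variant
    assert sorted(G.sum(axis=0), reverse=True)[:5] == [10, 2, 2, 2, 2]
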