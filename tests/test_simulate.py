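import itertools

import numpy as np
import pytest
from scipy.stats import kstest, ks_2samp

from multicoloc import (
    ClassificationCounts,
    SimScenario,
    builtin_scenario,
    classification_metrics,
    run_scenario_battery,
    simulate_ld,
    simulate_region,
    summarize_battery,
)
from multicoloc.simulate import load_scenario_file


class TestSimulateLd:
    def test_ar1_zero_is_identity(self):
        np.testing.assert_array_equal(simulate_ld("ar1", 5, rho=0.0), np.eye(5))

    def test_ar1_decay_closed_form(self):
        R = simulate_ld("ar1", 3, rho=0.9)
        assert R[0, 1] == pytest.approx(0.9)
        assert R[0, 2] == pytest.approx(0.81)
        np.testing.assert_allclose(R, R.T)

    def test_block_structure(self):
        R = simulate_ld("block", 6, rho=0.5, block_size=3)
        assert R[0, 2] == pytest.approx(0.5, abs=1e-9)
        assert R[0, 3] == pytest.approx(0.0, abs=1e-9)

    def test_haplotype_panel_recovers_panel_ld(self, rng):
        # correlated haplotypes via a latent AR(1) field, thresholded at
        # the allele frequency; the estimated LD must match the direct
        # correlation of the retained panel columns
        latent = rng.standard_normal((4000, 6)) @ np.linalg.cholesky(
            simulate_ld("ar1", 6, rho=0.8) + 1e-9 * np.eye(6)
        ).T
        panel = (latent < 0.0).astype(int)
        R = simulate_ld("haplotype_resample", haplotypes=panel)
        direct = np.corrcoef(panel.T)
        np.testing.assert_allclose(R, direct, atol=1e-6)

    def test_vcf_haplotype_panel(self, tmp_path):
        from multicoloc import load_haplotypes_vcf

        vcf = tmp_path / "panel.vcf"
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3",
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0",
            "1\t200\trs2\tA\tG\t.\tPASS\t.\tGT\t0|0\t1|0\t0|1",
        ]
        vcf.write_text("\n".join(lines) + "\n")
        panel = load_haplotypes_vcf(vcf)
        assert panel.shape == (6, 2)
        np.testing.assert_array_equal(panel[:, 0], [0, 1, 1, 1, 0, 0])
        np.testing.assert_array_equal(panel[:, 1], [0, 0, 1, 0, 0, 1])

    def test_maf_filter_drops_rare_variants(self, rng):
        panel = rng.integers(0, 2, size=(500, 3))
        panel[:, 1] = 0
        panel[:4, 1] = 1  # MAF below threshold
        R = simulate_ld("haplotype_resample", haplotypes=panel)
        assert R.shape == (2, 2)


class TestSimulateRegion:
    def test_seeded_determinism_bit_for_bit(self):
        scn = builtin_scenario("iii", Q=60, seed=42)
        r1, t1 = simulate_region(scn)
        r2, t2 = simulate_region(scn)
        assert r1.beta.tobytes() == r2.beta.tobytes()
        assert r1.se.tobytes() == r2.se.tobytes()
        assert t1.causal == t2.causal

    def test_null_trait_z_scores_are_standard_normal(self):
        scn = SimScenario(m=2, Q=400, ld_rho=0.0, sample_sizes=5000)
        region, _ = simulate_region(scn, rng=np.random.default_rng(3))
        z = region.z.ravel()
        assert kstest(z, "norm").pvalue > 0.01

    def test_z_covariance_tracks_ld(self):
        scn = SimScenario(m=1, Q=3, ld_rho=0.9, sample_sizes=5000)
        draws = []
        for stream in np.random.SeedSequence(8).spawn(800):
            region, _ = simulate_region(scn, rng=np.random.default_rng(stream))
            draws.append(region.z[0])
        corr = np.corrcoef(np.asarray(draws).T)
        assert corr[0, 1] == pytest.approx(0.9, abs=0.05)
        assert corr[0, 2] == pytest.approx(0.81, abs=0.05)

    def test_causal_variant_explains_stated_variance(self):
        """Individual-level path: the realized regression R^2 at the causal
        SNP (z^2 / (z^2 + n - 2)) averages to the planted 1%."""
        scn = SimScenario(
            m=1, Q=20, clusters=((0,),), sample_sizes=10000,
            method="individual", ld_rho=0.5,
        )
        r2 = []
        for stream in np.random.SeedSequence(21).spawn(200):
            rng = np.random.default_rng(stream)
            region, truth = simulate_region(scn, rng=rng)
            snp = truth.causal[0][0]
            z2 = region.z[0, snp] ** 2
            r2.append(z2 / (z2 + scn.sample_sizes - 2))
        assert np.mean(r2) == pytest.approx(0.01, abs=0.003)

    def test_full_overlap_induces_null_z_correlation(self):
        scn = SimScenario(
            m=2, Q=600, ld_rho=0.0, sample_sizes=8000,
            overlap_fraction=1.0, pheno_corr=0.5,
        )
        region, _ = simulate_region(scn, rng=np.random.default_rng(17))
        corr = np.corrcoef(region.z)[0, 1]
        assert corr == pytest.approx(0.5, abs=0.08)

    def test_direct_and_individual_paths_agree_in_distribution(self):
        """Causal- and null-SNP z marginals from the two generation paths
        are statistically indistinguishable at matched parameters
        (KS tests, alpha = 0.01, Bonferroni over the two SNPs tested)."""
        kw = dict(m=1, Q=8, clusters=((0,),), causal_snps=(2,),
                  sample_sizes=8000, ld_rho=0.7)
        z_direct, z_indiv = [], []
        for stream in np.random.SeedSequence(31).spawn(400):
            rng = np.random.default_rng(stream)
            region, _ = simulate_region(SimScenario(method="direct", **kw), rng=rng)
            z_direct.append(region.z[0])
            region, _ = simulate_region(SimScenario(method="individual", **kw), rng=rng)
            z_indiv.append(region.z[0])
        z_direct = np.asarray(z_direct)
        z_indiv = np.asarray(z_indiv)
        for snp in (2, 7):  # the causal SNP and a distal null SNP
            assert ks_2samp(z_direct[:, snp], z_indiv[:, snp]).pvalue > 0.005

    def test_copula_genotypes_keep_marginal_calibration(self):
        scn = SimScenario(
            m=1, Q=6, clusters=((0,),), sample_sizes=10000,
            method="individual", genotypes="copula", ld_rho=0.5,
        )
        r2 = []
        for stream in np.random.SeedSequence(77).spawn(100):
            region, truth = simulate_region(scn, rng=np.random.default_rng(stream))
            snp = truth.causal[0][0]
            z2 = region.z[0, snp] ** 2
            r2.append(z2 / (z2 + 10000 - 2))
        assert np.mean(r2) == pytest.approx(0.01, abs=0.004)

    def test_overlap_rejected_on_individual_path(self):
        scn = SimScenario(m=2, Q=10, method="individual",
                          overlap_fraction=0.5, pheno_corr=0.5, sample_sizes=500)
        with pytest.raises(ValueError, match="direct path"):
            simulate_region(scn, rng=np.random.default_rng(0))

    def test_invalid_variance_fraction_rejected(self):
        with pytest.raises(ValueError, match="variance fractions"):
            SimScenario(m=2, Q=10, variance_explained=0.5)


class TestClassificationMetrics:
    def test_direct_formula_example(self):
        counts = ClassificationCounts(tp=3, tn=5, fp=1, fn=1)
        assert counts.accuracy == pytest.approx(0.8)
        assert counts.tpr == pytest.approx(0.75)
        assert counts.fpr == pytest.approx(1 / 6)

    def test_perfect_recovery(self):
        truth = [{0, 1, 2}, {3, 4}]
        counts = classification_metrics(truth, truth, traits=range(5))
        assert counts.accuracy == 1.0
        assert counts.tpr == 1.0
        assert counts.fpr == 0.0

    def test_split_cluster_pair_enumeration(self):
        # truth {A,B,C},{D}; inferred {A,B},{C},{D}
        counts = classification_metrics([{0, 1, 2}], [{0, 1}], traits=range(4))
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 2, 3, 0)
        assert counts.accuracy == pytest.approx(4 / 6)

    def test_matches_pair_enumeration_oracle_on_random_partitions(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            labels_t = rng.integers(0, 4, size=n)
            labels_i = rng.integers(0, 4, size=n)
            truth = [set(np.flatnonzero(labels_t == g)) for g in range(4)]
            inferred = [set(np.flatnonzero(labels_i == g)) for g in range(4)]
            counts = classification_metrics(truth, inferred, traits=range(n))
            tp = tn = fp = fn = 0
            for a, b in itertools.combinations(range(n), 2):
                t = labels_t[a] == labels_t[b]
                i = labels_i[a] == labels_i[b]
                tp += t and i
                fp += i and not t
                fn += t and not i
                tn += not t and not i
            assert (counts.tp, counts.tn, counts.fp, counts.fn) == (tp, tn, fp, fn)


class TestScenarioBattery:
    def test_battery_rows_and_determinism(self):
        scns = {"iii": builtin_scenario("iii", Q=80)}
        df1 = run_scenario_battery(scns, replicates=3, seed=5, pc_values=(0.02,))
        df2 = run_scenario_battery(scns, replicates=3, seed=5, pc_values=(0.02,))
        assert df1.equals(df2)
        assert set(df1["filtered"]) == {False, True}
        assert len(df1) == 3 * 2

    def test_summary_deciles_stable_across_replicate_counts(self):
        """Internal consistency: decile summaries from a reduced replicate
        count agree with a doubled run within Monte-Carlo error."""
        scns = {"ii": builtin_scenario("ii", Q=100)}
        small = summarize_battery(run_scenario_battery(scns, 8, seed=11, pc_values=(0.02,)))
        large = summarize_battery(run_scenario_battery(scns, 16, seed=12, pc_values=(0.02,)))
        s = small[small.filtered].iloc[0]
        l = large[large.filtered].iloc[0]
        assert abs(s["accuracy_median"] - l["accuracy_median"]) <= 0.2

    def test_scenario_file_round_trip(self, tmp_path):
        path = tmp_path / "scn.yaml"
        path.write_text(
            "custom:\n  m: 4\n  Q: 30\n  clusters: [[0, 1, 2]]\n"
            "  sample_sizes: 5000\nbase: {builtin: ii, Q: 40}\n"
        )
        scns = load_scenario_file(path)
        assert scns["custom"].m == 4
        assert scns["custom"].clusters == ((0, 1, 2),)
        assert scns["base"].Q == 40
        region, truth = simulate_region(scns["custom"], rng=np.random.default_rng(1))
        assert region.m == 4
        assert truth.partition == [{0, 1, 2}]
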