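"""cis-dMeQTL machinery: trimming, pairing, scans, replication, filters."""

import numpy as np
import pandas as pd
import pytest

from methylong.dmeqtl import (
    GenotypeData,
    cis_pairs,
    compare_effect_sizes,
    delta_phenotype,
    discover_and_replicate,
    iqr_trim,
    iqr_trim_matrix,
    probe_snp_filter,
    scan_additive,
)
from methylong.stats import prop_test_one_sample


def _geno(dosage, positions=None, chrom="chr1"):
    dosage = np.asarray(dosage)
    n_samples, n_snps = dosage.shape
    rng = np.random.default_rng(0)
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chrom": chrom,
            "pos": positions if positions is not None
            else np.arange(1, n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
            "maf": np.clip(dosage.mean(axis=0) / 2, 0.05, 0.5),
        }
    )
    return GenotypeData(
        dosage=dosage,
        sample_ids=[f"c{i}" for i in range(n_samples)],
        snps=snps,
    )


class TestDeltaPhenotype:
    def _mats(self, n_probes=4, n_children=6, shift=0.0):
        probes = [f"p{i}" for i in range(n_probes)]
        cols1 = [f"c{j}_T1" for j in range(n_children)]
        cols2 = [f"c{j}_T2" for j in range(n_children)]
        rng = np.random.default_rng(1)
        base = rng.uniform(0.2, 0.8, size=(n_probes, n_children))
        t1 = pd.DataFrame(base, index=probes, columns=cols1)
        t2 = pd.DataFrame(base + shift, index=probes, columns=cols2)
        design = pd.DataFrame(
            {"child_id": [f"c{j}" for j in range(n_children)],
             "sample_t1": cols1, "sample_t2": cols2}
        ).set_index("child_id", drop=False)
        return t1, t2, design

    def test_identical_matrices_give_zero(self):
        t1, t2, design = self._mats(shift=0.0)
        assert np.allclose(delta_phenotype(t1, t2, design), 0.0)

    def test_constant_shift_propagates(self):
        t1, t2, design = self._mats(shift=0.1)
        assert np.allclose(delta_phenotype(t1, t2, design), 0.1)

    def test_missing_timepoint_raises(self):
        t1, t2, design = self._mats()
        with pytest.raises(ValueError, match="c2"):
            delta_phenotype(t1, t2.drop(columns=["c2_T2"]), design)


class TestIqrTrim:
    def test_hand_computed_bounds(self):
        mask, bounds = iqr_trim([1, 2, 3, 4, 100])
        assert bounds.lower == pytest.approx(-4.0)
        assert bounds.upper == pytest.approx(10.0)
        assert list(mask) == [True, True, True, True, False]

    def test_constant_vector_keeps_everything(self):
        mask, bounds = iqr_trim([5.0] * 10)
        assert mask.all()
        assert bounds.lower == bounds.upper == 5.0

    def test_gaussian_tail_mass_below_half_percent(self):
        rng = np.random.default_rng(2)
        mask, _ = iqr_trim(rng.standard_normal(10_000))
        assert (~mask).mean() < 0.005

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError):
            iqr_trim([1.0, 2.0, 3.0])

    def test_matrix_variant_matches_per_row(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame(rng.standard_normal((5, 50)))
        m = iqr_trim_matrix(vals)
        for i in range(5):
            row_mask, _ = iqr_trim(vals.iloc[i])
            assert np.array_equal(m.iloc[i].to_numpy(), row_mask)


class TestCisPairs:
    def _frames(self):
        snps = pd.DataFrame(
            {"snp_id": ["s1", "s2", "s3", "s4"],
             "chrom": ["chr1", "chr1", "chr1", "chr2"],
             "pos": [500_000, 750_000, 750_001, 500_000]}
        )
        probes = pd.DataFrame(
            {"probe_id": ["pA"], "chrom": ["chr1"], "pos": [500_000]}
        )
        return snps, probes

    def test_window_membership(self):
        snps, probes = self._frames()
        pairs = cis_pairs(snps, probes, window=250_000)
        got = set(pairs["snp_id"])
        assert got == {"s1", "s2"}  # distance 0 and exactly 250 kb included
        d = pairs.set_index("snp_id")["distance"]
        assert d["s1"] == 0 and d["s2"] == 250_000
        # 250,001 bp away and the other chromosome are both excluded
        assert "s3" not in got and "s4" not in got


class TestScanAdditive:
    def test_matches_textbook_ols(self):
        rng = np.random.default_rng(4)
        n = 80
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = 0.05 * g + rng.normal(0, 0.05, size=n)
        pheno = pd.DataFrame([y], index=["pA"],
                             columns=[f"c{i}" for i in range(n)])
        geno = _geno(g[:, None])
        res = scan_additive(pheno, geno, pd.DataFrame(
            {"snp_id": ["rs0"], "probe_id": ["pA"], "distance": [0]}))
        X = np.column_stack([np.ones(n), g])
        coef, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = float(res_ss[0]) / (n - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.loc[0, "beta"] == pytest.approx(coef[1], abs=1e-10)
        assert res.loc[0, "se"] == pytest.approx(se, abs=1e-10)

    def test_effect_recovery_average_bias(self):
        """500 replicate probes, per-allele effect 0.02 at MAF 0.3, n=200:
        averaged bias below 0.002."""
        rng = np.random.default_rng(5)
        n, reps = 200, 500
        g = rng.binomial(2, 0.3, size=n).astype(float)
        Y = 0.02 * g + rng.normal(0, 0.05, size=(reps, n))
        pheno = pd.DataFrame(Y, index=[f"p{i}" for i in range(reps)],
                             columns=[f"c{i}" for i in range(n)])
        geno = _geno(g[:, None])
        pairs = pd.DataFrame({"snp_id": "rs0",
                              "probe_id": pheno.index, "distance": 0})
        res = scan_additive(pheno, geno, pairs)
        errors = res["beta"] - 0.02
        assert np.abs(errors).max() < 0.05
        assert abs(errors.mean()) < 0.002

    def test_permuted_dosages_give_uniform_p(self):
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        n, reps = 150, 5000
        g = rng.binomial(2, 0.3, size=n).astype(float)
        Y = rng.normal(0, 0.05, size=(reps, n))
        pheno = pd.DataFrame(Y, index=[f"p{i}" for i in range(reps)],
                             columns=[f"c{i}" for i in range(n)])
        geno = _geno(rng.permutation(g)[:, None])
        pairs = pd.DataFrame({"snp_id": "rs0",
                              "probe_id": pheno.index, "distance": 0})
        res = scan_additive(pheno, geno, pairs)
        assert sps.kstest(res["p"], "uniform").pvalue > 0.01

    def test_constant_dosage_flagged_untestable(self):
        pheno = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["pA"],
                             columns=["c0", "c1", "c2", "c3"])
        geno = _geno(np.ones((4, 1)))
        res = scan_additive(pheno, geno, pd.DataFrame(
            {"snp_id": ["rs0"], "probe_id": ["pA"], "distance": [0]}))
        assert bool(res.loc[0, "untestable"])
        assert np.isnan(res.loc[0, "p"])


def _sim_disc_rep(rng, n_pairs, n_causal, n_disc, n_rep, effect_range=(0.02, 0.08),
                  maf_range=(0.2, 0.5), noise=0.04):
    """Two discovery cohorts + one replication set with planted pairs."""
    mafs = rng.uniform(*maf_range, size=n_pairs)
    effects = np.zeros(n_pairs)
    effects[:n_causal] = rng.uniform(*effect_range, size=n_causal) * rng.choice(
        [-1, 1], size=n_causal
    )
    scans = []
    for n in (n_disc, n_disc, n_rep):
        G = rng.binomial(2, mafs, size=(n, n_pairs)).astype(float)
        Y = effects * G + rng.normal(0, noise, size=(n, n_pairs))
        pheno = pd.DataFrame(Y.T, index=[f"p{i}" for i in range(n_pairs)],
                             columns=[f"c{i}" for i in range(n)])
        geno = _geno(G, positions=np.arange(1, n_pairs + 1) * 1000)
        pairs = pd.DataFrame({"snp_id": [f"rs{i}" for i in range(n_pairs)],
                              "probe_id": pheno.index, "distance": 0})
        scans.append(scan_additive(pheno, geno, pairs))
    return scans, effects


class TestDiscoverAndReplicate:
    def test_single_cohort_meta_is_identity(self):
        rng = np.random.default_rng(7)
        scans, _ = _sim_disc_rep(rng, 50, 5, 100, 50)
        out = discover_and_replicate([scans[0]], scans[2])
        assert np.allclose(out["beta"], scans[0]["beta"])
        assert np.allclose(out["se"], scans[0]["se"])

    def test_planted_pairs_end_replicated(self):
        """Planted effects >= 0.02 at MAF >= 0.2 with discovery n=200 and
        replication n=100: at least 90% of planted pairs survive both
        stages."""
        rng = np.random.default_rng(8)
        scans, effects = _sim_disc_rep(rng, 2000, 200, 200, 100)
        out = discover_and_replicate(scans[:2], scans[2])
        planted = effects != 0
        assert out.loc[planted, "replicated"].mean() >= 0.9

    def test_all_null_discovery_count_within_binomial_band(self):
        rng = np.random.default_rng(9)
        scans, _ = _sim_disc_rep(rng, 3000, 0, 100, 50)
        out = discover_and_replicate(scans[:2], scans[2])
        # BH at 0.05 under a global null: P(any rejection) <= 0.05, so
        # a couple of runs' worth of slack means zero is the norm
        assert out["significant"].sum() <= 3

    def test_mismatched_universe_raises(self):
        rng = np.random.default_rng(10)
        scans, _ = _sim_disc_rep(rng, 20, 2, 50, 30)
        bad = scans[1].iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            discover_and_replicate([scans[0], bad], scans[2])


class TestProbeSnpFilter:
    def _setup(self, rng, r2_partner=True):
        n = 200
        g_in = rng.binomial(2, 0.3, size=n).astype(float)
        g_indep = rng.binomial(2, 0.3, size=n).astype(float)
        g_dup = g_in.copy()
        dosage = np.column_stack([g_in, g_indep, g_dup])
        # probe pA at pos 10_000, body = [9_950, 9_999]
        positions = [9_970, 200_000, 150_000]
        geno = _geno(dosage, positions=positions)
        manifest = pd.DataFrame(
            {"probe_id": ["pA"], "chrom": ["chr1"], "pos": [10_000],
             "interval_start": [9_950], "interval_end": [9_999]}
        ).set_index("probe_id", drop=False)
        return geno, manifest

    def test_in_probe_and_perfect_ld_removed_independent_kept(self):
        rng = np.random.default_rng(11)
        geno, manifest = self._setup(rng)
        pairs = pd.DataFrame({"snp_id": ["rs0", "rs1", "rs2"],
                              "probe_id": "pA", "distance": 0})
        kept, removed = probe_snp_filter(pairs, manifest, geno)
        reasons = removed.set_index("snp_id")["reason"]
        assert reasons["rs0"] == "in_probe"
        assert reasons["rs2"] == "ld_with_probe"  # duplicated dosage, r2 = 1
        assert list(kept["snp_id"]) == ["rs1"]

    def test_independent_snps_rarely_removed(self):
        """Null LD: independent SNPs (expected r2 ~ 1/n) survive the
        filter in at least 99% of replicates at n=200."""
        rng = np.random.default_rng(12)
        n, reps = 200, 300
        removed_count = 0
        g_in = rng.binomial(2, 0.3, size=n).astype(float)
        for _ in range(reps):
            g = rng.binomial(2, 0.3, size=n).astype(float)
            geno = _geno(np.column_stack([g_in, g]), positions=[9_970, 200_000])
            manifest = pd.DataFrame(
                {"probe_id": ["pA"], "chrom": ["chr1"], "pos": [10_000],
                 "interval_start": [9_950], "interval_end": [9_999]}
            ).set_index("probe_id", drop=False)
            pairs = pd.DataFrame({"snp_id": ["rs1"], "probe_id": "pA",
                                  "distance": 0})
            kept, removed = probe_snp_filter(pairs, manifest, geno)
            removed_count += len(removed)
        assert removed_count / reps < 0.01

    def test_filter_monotone_in_in_probe_set(self):
        """Moving a SNP into the probe body never rescues a removed pair."""
        rng = np.random.default_rng(13)
        geno, manifest = self._setup(rng)
        pairs = pd.DataFrame({"snp_id": ["rs0", "rs1", "rs2"],
                              "probe_id": "pA", "distance": 0})
        kept_before, _ = probe_snp_filter(pairs, manifest, geno)
        geno.snps.loc[1, "pos"] = 9_960  # rs1 now also in the probe body
        kept_after, _ = probe_snp_filter(pairs, manifest, geno)
        assert set(kept_after["snp_id"]) <= set(kept_before["snp_id"])

    def test_missing_interval_raises(self):
        rng = np.random.default_rng(14)
        geno, manifest = self._setup(rng)
        with pytest.raises(KeyError):
            probe_snp_filter(
                pd.DataFrame({"snp_id": ["rs0"], "probe_id": "pA"}),
                manifest.drop(columns=["interval_start", "interval_end"]),
                geno,
            )


class TestCompareEffectSizes:
    def _frames(self, by, bo):
        ids = [f"q{i}" for i in range(len(by))]
        young = pd.DataFrame({"snp_id": ids, "probe_id": ids, "beta": by})
        old = pd.DataFrame({"snp_id": ids, "probe_id": ids, "beta": bo})
        return young, old

    def test_magnitude_classes(self):
        young, old = self._frames([0.032, 0.05, -0.05, 0.04],
                                  [0.058, -0.05, -0.02, 0.04])
        out, summary = compare_effect_sizes(young, old)
        assert list(out["effect_class"]) == [
            "weaker_at_young", "different_direction", "stronger_at_young", "tie",
        ]
        assert summary["n_same_direction"] == 2

    def test_headline_split_arithmetic(self):
        """The printed 725 stronger / 2,623 weaker split of 3,348
        same-direction pairs gives 21.7%/78.3% and z near 32.8."""
        from methylong.formatting import format_percent

        assert format_percent(725, 3348) == 21.7
        assert format_percent(2623, 3348) == 78.3
        z, p = prop_test_one_sample(2623, 3348, 0.5)
        assert z == pytest.approx(32.8, abs=0.05)
        assert p < 1e-200

    def test_classes_partition_pairs(self):
        rng = np.random.default_rng(15)
        by = rng.normal(size=100)
        bo = rng.normal(size=100)
        out, summary = compare_effect_sizes(*self._frames(by, bo))
        assert sum(summary["counts"].values()) == 100
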