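"""Calibration and recovery experiments over the synthetic study.

These harnesses quantify what the pipeline delivers under known truth:
null calibration of the age-differential scan, planted age-effect
recovery, dMeQTL discovery/replication/filtering against the truth
manifest, deconvolution accuracy, and control-PC selection operating
characteristics. They are the basis of the acceptance checks and are
reusable for benchmarking parameter choices.
"""

from __future__ import annotations

import time

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import dmeqtl as dmeqtl_mod
from . import preprocess as pre_mod
from .adms import test_age_dms
from .pipeline import AnalysisParams, PipelineConfig, run_pipeline
from .simulate import SimConfig, generate_study
from .stats import bonferroni_threshold, pca_permutation_select

GENOME_WIDE_P = bonferroni_threshold(0.05, 439_306)


def _adjust_one_set(study, params, cset, random_state):
    """Deconvolve, select control PCs and residualize one comparison set."""
    design = study.design[study.design["comparison_set"] == cset]
    cols = list(design["sample_t1"]) + list(design["sample_t2"])
    beta = study.betas[cset]
    props = pre_mod.deconvolve_matrix(beta[cols], study.cell_reference)
    ctrl = study.control[cols]
    cov = study.samples.loc[cols, ["cohort", "sex", "batch", "array_position"]].copy()
    cov["array_position"] = cov["array_position"].astype(str)
    cov = pd.concat([cov, props], axis=1)
    sel = pca_permutation_select(
        ctrl.to_numpy().T, n_perm=params.pca_n_perm, alpha=params.pca_alpha,
        max_components=params.pca_max_components, random_state=random_state,
    )
    pcs = pd.DataFrame(
        sel.scores, index=beta[cols].columns,
        columns=[f"control_pc{k + 1}" for k in range(sel.n_selected)],
    )
    adj = pre_mod.build_adjusted_matrix(beta[cols], None, cov, precomputed_pcs=pcs)
    return adj, design


def null_calibration(
    seed: int,
    n_seeds: int = 20,
    n_probes: int = 20_000,
    n_children_per_cohort: int = 150,
    pca_n_perm: int = 100,
) -> dict:
    """All-null studies: p-value uniformity and genome-wide false hits.

    Runs the young-set age-differential scan on studies with every
    planted effect zeroed. Reports the Kolmogorov-Smirnov uniformity p
    of the first seed's scan and, across seeds, how many runs produce
    zero probes below the genome-wide threshold.
    """
    params = AnalysisParams(pca_n_perm=pca_n_perm)
    ks_p = None
    zero_hit_runs = 0
    for k in range(n_seeds):
        cfg = SimConfig(
            n_probes=n_probes, n_children_per_cohort=n_children_per_cohort,
            n_snps=200, frac_da=0.0, frac_ia=0.0, n_causal_meqtl=0,
            n_smoking_cpgs=0, n_asthma_cpgs=0, seed=(seed + 7919 * k) % (2**31),
        )
        study = generate_study(cfg)
        adj, design = _adjust_one_set(study, params, "young", random_state=seed)
        scan = test_age_dms(adj.values, design)
        if ks_p is None:
            ks_p = float(sps.kstest(scan["p"], "uniform").pvalue)
        zero_hit_runs += int((scan["p"] < GENOME_WIDE_P).sum() == 0)
    return dict(
        ks_uniform_p=ks_p,
        n_seeds=n_seeds,
        n_runs_zero_genomewide_hits=zero_hit_runs,
        frac_runs_zero_genomewide_hits=zero_hit_runs / n_seeds,
    )


def age_effect_recovery(
    seed: int,
    n_probes: int = 20_000,
    n_children_per_cohort: int = 125,
    pca_n_perm: int = 100,
) -> dict:
    """Bias and genome-wide power for planted decreasing age effects.

    125 children per cohort give 250 pairs per comparison set. Bias is
    the mean difference between the estimated and planted change at
    decreasing-age probes; power is the fraction of those probes passing
    the genome-wide threshold in the young-set scan.
    """
    cfg = SimConfig(
        n_probes=n_probes, n_children_per_cohort=n_children_per_cohort,
        n_snps=200, n_causal_meqtl=0, seed=seed,
    )
    study = generate_study(cfg)
    params = AnalysisParams(pca_n_perm=pca_n_perm)
    adj, design = _adjust_one_set(study, params, "young", random_state=seed)
    scan = test_age_dms(adj.values, design)
    truth = study.truth.age_effect
    da = truth.index[truth["young"] < 0]
    est = scan.loc[da, "delta"]
    bias = float((est - truth.loc[da, "young"]).mean())
    power = float((scan.loc[da, "p"] < GENOME_WIDE_P).mean())
    return dict(
        n_pairs=len(design), n_planted_da=len(da),
        mean_true_effect=float(truth.loc[da, "young"].mean()),
        mean_estimated_effect=float(est.mean()),
        bias=bias, genomewide_power=power,
    )


def dmeqtl_recovery(
    seed: int,
    n_probes: int = 4_000,
    n_snps: int = 2_000,
    n_children_per_cohort: int = 150,
    n_causal: int = 150,
    pca_n_perm: int = 100,
) -> dict:
    """Discovery FDR, replication of planted pairs, and the probe-SNP filter.

    The change-score scan runs on the planted a-DMS universe with the
    usual two-cohort discovery meta + young-set replication. Empirical
    FDR counts significant pairs absent from the truth manifest;
    replication is assessed on clean planted pairs with per-allele
    change effects >= 0.02 and MAF >= 0.2. The probe-SNP filter is
    evaluated on planted in-probe/LD pairs (should all go) and on clean
    pairs (should essentially all stay).
    """
    cfg = SimConfig(
        n_probes=n_probes, n_snps=n_snps, n_causal_meqtl=n_causal,
        n_children_per_cohort=n_children_per_cohort, seed=seed,
    )
    study = generate_study(cfg)
    params = AnalysisParams(pca_n_perm=pca_n_perm)
    truth = study.truth
    planted_probes = truth.age_effect.index[
        (truth.age_effect != 0).any(axis=1)
    ]
    probe_pos = study.manifest.loc[planted_probes, ["probe_id", "chrom", "pos"]]
    pairs = dmeqtl_mod.cis_pairs(study.genotypes.snps, probe_pos,
                                 window=params.cis_window)

    adj_old, design_old = _adjust_one_set(study, params, "old", random_state=seed)
    adj_young, design_young = _adjust_one_set(study, params, "young",
                                              random_state=seed)

    def _delta(adj, design):
        return dmeqtl_mod.delta_phenotype(adj.values, adj.values, design).loc[
            planted_probes
        ]

    discovery = []
    for cohort in design_old["cohort"].unique():
        d = design_old[design_old["cohort"] == cohort]
        delta = _delta(adj_old, d)
        mask = dmeqtl_mod.iqr_trim_matrix(delta)
        discovery.append(dmeqtl_mod.scan_additive(delta, study.genotypes,
                                                  pairs, mask))
    delta_y = _delta(adj_young, design_young)
    mask_y = dmeqtl_mod.iqr_trim_matrix(delta_y)
    replication = dmeqtl_mod.scan_additive(delta_y, study.genotypes, pairs, mask_y)
    table = dmeqtl_mod.discover_and_replicate(
        discovery, replication, fdr_level=params.fdr_level, p_rep=params.p_rep
    )

    causal = truth.causal_pairs
    true_keys = set(
        zip(causal.loc[causal["d_effect_old"] != 0, "snp_id"],
            causal.loc[causal["d_effect_old"] != 0, "probe_id"])
    )
    keys = list(zip(table["snp_id"], table["probe_id"]))
    is_true = np.array([k in true_keys for k in keys])
    sig = table["significant"].to_numpy()
    n_sig = int(sig.sum())
    false_disc = int((sig & ~is_true).sum())
    fdr = false_disc / n_sig if n_sig else 0.0
    mc_se = np.sqrt(0.05 * 0.95 / n_sig) if n_sig else 0.0

    snp_maf = study.genotypes.snps.set_index("snp_id")["maf"]
    clean = causal[
        (causal["artifact"] == "clean")
        & (causal["d_effect_old"].abs() >= 0.02)
        & (causal["snp_id"].map(snp_maf) >= 0.2)
    ]
    tbl = table.set_index(["snp_id", "probe_id"])
    clean_keys = [
        k for k in zip(clean["snp_id"], clean["probe_id"]) if k in tbl.index
    ]
    replicated_frac = float(tbl.loc[clean_keys, "replicated"].mean())

    artifact = causal[causal["artifact"] != "clean"]
    art_pairs = artifact[["snp_id", "probe_id"]].assign(distance=0)
    _, art_removed = dmeqtl_mod.probe_snp_filter(
        art_pairs, study.manifest, study.genotypes, r2_max=params.r2_max
    )
    clean_pairs = causal.loc[causal["artifact"] == "clean",
                             ["snp_id", "probe_id"]].assign(distance=0)
    kept_clean, removed_clean = dmeqtl_mod.probe_snp_filter(
        clean_pairs, study.manifest, study.genotypes, r2_max=params.r2_max
    )
    return dict(
        n_pairs_tested=len(table),
        n_significant=n_sig,
        empirical_fdr=fdr,
        fdr_bound=0.05 + 2 * float(mc_se),
        n_clean_planted_evaluable=len(clean_keys),
        replicated_frac_planted=replicated_frac,
        artifact_filter_removed_frac=float(len(art_removed) / len(art_pairs)),
        clean_filter_removed_frac=float(len(removed_clean) / len(clean_pairs)),
    )


def deconvolution_check(seed: int, n_samples: int = 50,
                        n_probes: int = 500) -> dict:
    """Recovery of Dirichlet mixtures from 500-probe reference profiles."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_probes=2_000, n_children_per_cohort=5, n_snps=100,
                    n_causal_meqtl=0, seed=seed)
    study = generate_study(cfg)
    ref = study.cell_reference.iloc[:, :n_probes]
    true_mix = rng.dirichlet(np.full(6, 2.0), size=n_samples)
    A = ref.to_numpy().T  # probes x types
    obs = A @ true_mix.T + rng.normal(0, 0.01, size=(A.shape[0], n_samples))
    errs = []
    for j in range(n_samples):
        est = pre_mod.deconvolve_celltypes(obs[:, j], ref)
        errs.append(est.to_numpy() - true_mix[j])
    errs = np.array(errs)
    return dict(
        n_samples=n_samples,
        max_abs_error=float(np.abs(errs).max()),
        mean_abs_error=float(np.abs(errs).mean()),
    )


def pc_selection_check(
    seed: int,
    n_null_reps: int = 100,
    n_factor_reps: int = 50,
    n: int = 200,
    p: int = 600,
    n_perm: int = 200,
    alpha: float = 0.005,
) -> dict:
    """Operating characteristics of the permutation PC selection.

    Under iid noise no PC should be selected; under a rank-1 factor with
    ten times the noise variance PC1 should always be selected.
    """
    rng = np.random.default_rng(seed)
    null_zero = 0
    for _ in range(n_null_reps):
        X = rng.standard_normal((n, p))
        sel = pca_permutation_select(X, n_perm=n_perm, alpha=alpha,
                                     max_components=1)
        null_zero += int(sel.n_selected == 0)
    factor_found = 0
    for _ in range(n_factor_reps):
        f = rng.standard_normal(n)
        load = np.sqrt(10.0) * rng.choice([-1.0, 1.0], size=p)
        X = np.outer(f, load) + rng.standard_normal((n, p))
        sel = pca_permutation_select(X, n_perm=n_perm, alpha=alpha,
                                     max_components=1)
        factor_found += int(sel.n_selected >= 1)
    return dict(
        frac_null_zero_selected=null_zero / n_null_reps,
        frac_factor_pc1_selected=factor_found / n_factor_reps,
        n_null_reps=n_null_reps,
        n_factor_reps=n_factor_reps,
    )


def demo_pipeline_run(seed: int, out_dir: str,
                      pca_n_perm: int = 200) -> dict:
    """File-backed end-to-end run at the demo scale; returns headline counts."""
    cfg = PipelineConfig(
        out_dir=out_dir,
        sim=SimConfig(seed=0),  # demo scale: 20k probes, 5k SNPs, 150/cohort
        params=AnalysisParams(pca_n_perm=pca_n_perm),
        seed=seed,
    )
    t0 = time.time()
    report = run_pipeline(cfg)
    runtime = time.time() - t0
    out = dict(runtime_seconds=float(runtime))
    for stage in ("adms", "dmeqtl", "assoc"):
        for k, v in report.sections.get(stage, {}).items():
            if isinstance(v, (int, float)):
                out[f"{stage}.{k}"] = v
    return out
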