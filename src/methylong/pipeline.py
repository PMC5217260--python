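"""End-to-end orchestration: simulate -> preprocess -> a-DMS -> dMeQTL ->
exposure/disease association -> enrichment -> report.

Each stage persists its outputs as TSV under the run directory and
records an input hash, so rerunning a completed stage with unchanged
inputs is a no-op. A single config seed feeds every stage through named
substreams. The summary report reproduces all headline counts and
percentages from its own stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import adms as adms_mod
from . import assoc as assoc_mod
from . import dmeqtl as dmeqtl_mod
from . import enrichment as enrich_mod
from . import preprocess as pre_mod
from .formatting import format_percent
from .simulate import SimConfig, SimStudy, generate_study, load_study, \
    write_outputs

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "adms", "dmeqtl", "assoc", "enrich", "report")


def summarize_fractions(counts: dict) -> dict:
    """Named (numerator, denominator) pairs -> one-decimal percentages.

    Percentages are 100*num/den rounded half away from zero to one
    decimal (two significant digits below 1%).
    """
    out = {}
    for name, (num, den) in counts.items():
        if den == 0:
            raise ZeroDivisionError(f"zero denominator for '{name}'")
        out[name] = format_percent(num, den)
    return out


@dataclass
class AnalysisParams:
    """Thresholds of the analysis; defaults follow the study design."""

    alpha: float = 0.05                 # family-wise level for the a-DMS scan
    fdr_level: float = 0.05             # discovery FDR for dMeQTL
    p_rep: float = 0.05                 # nominal replication threshold
    cis_window: int = 250_000
    r2_max: float = 0.2                 # LD ceiling for SNP-under-probe filter
    detection_p_threshold: float = 0.01
    detection_max_fail: float = 0.10
    concordance_r_min: float = 0.9
    maf_max: float = 0.10
    pca_n_perm: int = 10_000
    pca_alpha: float = 1e-4
    pca_max_components: int = 10
    gene_window: int = 100_000
    smoking_p_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_level", "p_rep", "pca_alpha",
                     "detection_p_threshold", "detection_max_fail",
                     "smoking_p_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.cis_window <= 0 or self.gene_window <= 0:
            raise ValueError("windows must be positive")
        if not 0 <= self.r2_max <= 1:
            raise ValueError("r2_max must lie in [0, 1]")
        if not 0 < self.concordance_r_min <= 1:
            raise ValueError("concordance_r_min must lie in (0, 1]")


@dataclass
class PipelineConfig:
    out_dir: str
    data_dir: str | None = None         # input data; defaults to out_dir/data
    sim: SimConfig | None = None        # present -> the simulate stage runs
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        params = raw.pop("params", {})
        cfg = cls(
            **{k: v for k, v in raw.items() if k in
               {"out_dir", "data_dir", "seed", "log_level"}}
        )
        if sim is not None:
            if "meqtl_beta_range" in sim:
                sim["meqtl_beta_range"] = tuple(sim["meqtl_beta_range"])
            if "cohorts" in sim:
                sim["cohorts"] = tuple(tuple(c) for c in sim["cohorts"])
            cfg.sim = SimConfig(**sim)
        cfg.params = AnalysisParams(**params)
        return cfg

    def substream(self, name: str) -> int:
        """Deterministic per-stage seed below 2**31 derived from the config seed."""
        return (int(self.seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31)


# ---------------------------------------------------------------------------
# stage bookkeeping (hash-checked resumability)
# ---------------------------------------------------------------------------

def _dir_digest(directory: str, extra: str = "") -> str:
    """Digest of a data directory: per-file name, size and leading bytes.

    Hashing only each file's first 64 KiB keeps the check cheap on large
    matrices while still catching any regeneration or parameter change.
    """
    h = hashlib.md5()
    h.update(extra.encode())
    for name in sorted(os.listdir(directory)):
        p = os.path.join(directory, name)
        if not os.path.isfile(p):
            continue
        h.update(name.encode())
        h.update(str(os.path.getsize(p)).encode())
        with open(p, "rb") as fh:
            h.update(fh.read(1 << 16))
    return h.hexdigest()


class _StageState:
    def __init__(self, out_dir: str) -> None:
        self.path = os.path.join(out_dir, ".stage_state.json")
        self.state = {}
        if os.path.exists(self.path):
            with open(self.path) as fh:
                self.state = json.load(fh)

    def is_done(self, stage: str, digest: str, outputs: list[str]) -> bool:
        rec = self.state.get(stage)
        return (
            rec is not None
            and rec.get("digest") == digest
            and all(os.path.exists(p) for p in outputs)
        )

    def mark(self, stage: str, digest: str) -> None:
        self.state[stage] = {"digest": digest}
        with open(self.path, "w") as fh:
            json.dump(self.state, fh, indent=1)


def _write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# in-memory analysis steps (the stages are thin file wrappers over these)
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    adjusted: dict                      # set -> AdjustedMatrix
    pc_only: dict                       # set -> AdjustedMatrix (control PCs only)
    cell_props: pd.DataFrame            # sample x cell type
    kept_probes: list
    kept_design: pd.DataFrame           # children surviving QC
    qc: pre_mod.QCReport


def preprocess_study(study: SimStudy, params: AnalysisParams,
                     random_state: int = 0) -> PreprocessResult:
    manifest = study.manifest
    design, samples = study.design, study.samples

    keep_samples, _, qc = pre_mod.sample_qc(
        study.detection_p, params.detection_p_threshold, params.detection_max_fail
    )
    keep_set = set(keep_samples)

    # paired-sample concordance on the SNP-fingerprint panel probes
    panel = manifest.index[manifest["snp_panel"]]
    bad_children = {
        row.child_id for row in design.itertuples()
        if row.sample_t1 not in keep_set or row.sample_t2 not in keep_set
    }
    for cset, beta in study.betas.items():
        d = design[design["comparison_set"] == cset]
        conc = pre_mod.pair_concordance_check(
            beta.loc[panel, d["sample_t1"]].set_axis(d.index, axis=1),
            beta.loc[panel, d["sample_t2"]].set_axis(d.index, axis=1),
            params.concordance_r_min,
        )
        for child in conc.index[conc["mixup"]]:
            bad_children.add(child)
            qc.samples_removed.append((design.loc[child, "sample_t1"], "pair_mixup"))
            qc.samples_removed.append((design.loc[child, "sample_t2"], "pair_mixup"))

    kept_design = design[~design.index.isin(bad_children)]
    kept_probes, probe_qc = pre_mod.probe_filter(manifest, maf_max=params.maf_max)
    qc = qc.merged(probe_qc)

    # cell proportions from the raw betas on the reference probes
    props_by_set = []
    for cset, beta in study.betas.items():
        props_by_set.append(pre_mod.deconvolve_matrix(beta, study.cell_reference))
    cell_props = pd.concat(props_by_set)

    adjusted, pc_only = {}, {}
    for cset, beta in study.betas.items():
        d = kept_design[kept_design["comparison_set"] == cset]
        cols = list(d["sample_t1"]) + list(d["sample_t2"])
        sub = beta.loc[kept_probes, cols]
        ctrl = study.control[cols]
        cov = samples.loc[cols, ["cohort", "sex", "batch", "array_position"]].copy()
        cov["array_position"] = cov["array_position"].astype(str)
        cov = pd.concat([cov, cell_props.loc[cols]], axis=1)
        sel = pre_mod.pca_permutation_select(
            ctrl.to_numpy().T, n_perm=params.pca_n_perm, alpha=params.pca_alpha,
            max_components=params.pca_max_components, random_state=random_state,
        )
        pcs = pd.DataFrame(
            sel.scores, index=sub.columns,
            columns=[f"control_pc{k + 1}" for k in range(sel.n_selected)],
        )
        adjusted[cset] = pre_mod.build_adjusted_matrix(
            sub, None, cov, precomputed_pcs=pcs
        )
        pc_only[cset] = pre_mod.build_adjusted_matrix(
            sub, None, None, precomputed_pcs=pcs
        )
    return PreprocessResult(
        adjusted=adjusted, pc_only=pc_only, cell_props=cell_props,
        kept_probes=list(kept_probes), kept_design=kept_design, qc=qc,
    )


@dataclass
class AdmsResult:
    scans: dict                         # set -> per-probe scan table
    records: pd.DataFrame
    summary: adms_mod.DMSSummary


def run_adms(pre: PreprocessResult) -> AdmsResult:
    scans = {}
    for cset, adj in pre.adjusted.items():
        d = pre.kept_design[pre.kept_design["comparison_set"] == cset]
        scans[cset] = adms_mod.test_age_dms(adj.values, d)
    records, summary = adms_mod.classify_consistency(
        scans["young"], scans["old"], n_tests=len(pre.kept_probes)
    )
    return AdmsResult(scans=scans, records=records, summary=summary)


@dataclass
class DmeqtlResult:
    table: pd.DataFrame                 # discovery+replication per pair
    filtered: pd.DataFrame              # pairs surviving the probe-SNP filter
    removed: pd.DataFrame
    effect_compare: pd.DataFrame
    summary: dict


def run_dmeqtl(study: SimStudy, pre: PreprocessResult, adms_res: AdmsResult,
               params: AnalysisParams) -> DmeqtlResult:
    manifest = study.manifest
    geno = study.genotypes
    consistent = adms_res.records.index[
        adms_res.records["class"].isin(["da", "ia"])
    ]
    probe_pos = manifest.loc[consistent, ["probe_id", "chrom", "pos"]]
    pairs = dmeqtl_mod.cis_pairs(geno.snps, probe_pos, window=params.cis_window)
    if pairs.empty:
        empty = pairs.assign(beta=[], se=[], p=[], q=[])
        return DmeqtlResult(pairs, pairs, pairs, pairs,
                            dict(n_pairs=0, n_significant=0, n_replicated=0,
                                 n_filtered=0))

    def _delta_by_child(cset, design_sub):
        adj = pre.adjusted[cset].values
        return dmeqtl_mod.delta_phenotype(adj, adj, design_sub).loc[consistent]

    old_design = pre.kept_design[pre.kept_design["comparison_set"] == "old"]
    young_design = pre.kept_design[pre.kept_design["comparison_set"] == "young"]
    discovery = []
    for cohort in old_design["cohort"].unique():
        d = old_design[old_design["cohort"] == cohort]
        delta = _delta_by_child("old", d)
        mask = dmeqtl_mod.iqr_trim_matrix(delta)
        discovery.append(dmeqtl_mod.scan_additive(delta, geno, pairs, mask))
    delta_y = _delta_by_child("young", young_design)
    mask_y = dmeqtl_mod.iqr_trim_matrix(delta_y)
    replication = dmeqtl_mod.scan_additive(delta_y, geno, pairs, mask_y)

    table = dmeqtl_mod.discover_and_replicate(
        discovery, replication, fdr_level=params.fdr_level, p_rep=params.p_rep
    )
    replicated = table[table["replicated"]]
    filtered, removed = dmeqtl_mod.probe_snp_filter(
        replicated, manifest, geno, r2_max=params.r2_max
    )

    # cross-sectional MeQTL at the two shared-age timepoints (old set)
    def _levels(design_sub, col):
        adj = pre.adjusted["old"].values
        lev = adj[design_sub[col]]
        return lev.set_axis(design_sub["child_id"], axis=1).loc[consistent]

    keep_pairs = filtered[["snp_id", "probe_id", "distance"]].reset_index(drop=True)
    cs4 = dmeqtl_mod.scan_additive(_levels(old_design, "sample_t1"), geno, keep_pairs)
    cs8 = dmeqtl_mod.scan_additive(_levels(old_design, "sample_t2"), geno, keep_pairs)
    ok = (~cs4["untestable"] & ~cs8["untestable"]).to_numpy()
    compare, cmp_summary = dmeqtl_mod.compare_effect_sizes(
        cs4[ok].reset_index(drop=True), cs8[ok].reset_index(drop=True)
    )

    n_sig = int(table["significant"].sum())
    n_rep = int(table["replicated"].sum())
    summary = dict(
        n_pairs=len(table),
        n_testable=int(np.isfinite(table["p"]).sum()),
        n_significant=n_sig,
        n_replicated=n_rep,
        n_removed_probe_snp=len(removed),
        n_filtered=len(filtered),
        n_probes_with_qtl=int(filtered["probe_id"].nunique()),
        n_snps=int(filtered["snp_id"].nunique()),
        effect_compare=cmp_summary,
    )
    if n_sig:
        summary["pct_replicated"] = format_percent(n_rep, n_sig)
        summary["pct_filtered_of_significant"] = format_percent(len(filtered), n_sig)
    return DmeqtlResult(
        table=table, filtered=filtered, removed=removed,
        effect_compare=compare, summary=summary,
    )


@dataclass
class AssocResultSet:
    smoking: dict                       # set -> per-probe table
    asthma: dict                        # age label -> per-probe table
    summary: dict


def run_assoc(study: SimStudy, pre: PreprocessResult, adms_res: AdmsResult,
              params: AnalysisParams) -> AssocResultSet:
    consistent = adms_res.records.index[
        adms_res.records["class"].isin(["da", "ia"])
    ]
    design = pre.kept_design
    smoking, tallies = {}, {}
    for cset in ("young", "old"):
        d = design[design["comparison_set"] == cset]
        adj = pre.adjusted[cset].values
        delta = dmeqtl_mod.delta_phenotype(adj, adj, d).loc[consistent]
        expo = d.set_index("child_id")[
            ["maternal_smoking", "maternal_age", "parity", "maternal_education"]
        ]
        res = assoc_mod.test_exposure_on_delta(delta, expo)
        smoking[cset] = res
        n_neg, n_pos, n_tot = assoc_mod.direction_tally(
            res, params.smoking_p_threshold
        )
        tallies[cset] = dict(
            n_negative=n_neg, n_positive=n_pos, n_nominal=n_tot,
            pct_negative=assoc_mod.negative_fraction_percent(n_neg, n_tot),
        )

    old_design = design[design["comparison_set"] == "old"]
    asthma = {}
    for label, col in (("age4", "sample_t1"), ("age8", "sample_t2")):
        cols = list(old_design[col])
        levels = pre.pc_only["old"].values[cols].loc[consistent]
        dd = study.samples.loc[cols, ["cohort", "sex", "batch", "array_position"]].copy()
        dd["array_position"] = dd["array_position"].astype(str)
        dd["asthma"] = old_design.set_index(col)["asthma"].reindex(cols).to_numpy()
        dd = pd.concat([dd, pre.cell_props.loc[cols]], axis=1)
        # asthma first is irrelevant to the fit; the scan reports its term
        asthma[label] = assoc_mod.test_disease_assoc(levels, dd)

    summary = dict(
        smoking={cset: tallies[cset] for cset in tallies},
        smoking_hits={
            cset: int((smoking[cset]["q"] < params.fdr_level).sum())
            for cset in smoking
        },
        asthma_hits={lab: int((asthma[lab]["q"] < params.fdr_level).sum())
                     for lab in asthma},
    )
    return AssocResultSet(smoking=smoking, asthma=asthma, summary=summary)


@dataclass
class EnrichResult:
    rows: pd.DataFrame
    disease: dict
    nearest_gene: pd.Series
    summary: dict


def run_enrich(study: SimStudy, pre: PreprocessResult, adms_res: AdmsResult,
               params: AnalysisParams) -> EnrichResult:
    manifest = study.manifest
    background = [
        p for p in pre.kept_probes if not manifest.loc[p, "is_cph"]
    ]
    bg_index = pd.Index(background)
    rec = adms_res.records
    sets = {
        "da": [p for p in rec.index[rec["class"] == "da"] if p in bg_index],
        "ia": [p for p in rec.index[rec["class"] == "ia"] if p in bg_index],
    }

    tracks = []
    for cat in pd.unique(manifest["island_relation"]):
        tracks.append(enrich_mod.AnnotationTrack(
            name=f"island:{cat}", membership=manifest["island_relation"] == cat))
    for cat in pd.unique(manifest["gene_region"]):
        tracks.append(enrich_mod.AnnotationTrack(
            name=f"region:{cat}", membership=manifest["gene_region"] == cat))
    for state, df in study.chromatin.items():
        tracks.append(enrich_mod.combine_blood_states(df, name=f"state:{state}"))

    rows = []
    for set_name, probes in sets.items():
        if not probes:
            continue
        for track in tracks:
            r = enrich_mod.enrichment_test(probes, background, track, set_name)
            rows.append(dataclasses.asdict(r))
    rows = pd.DataFrame(rows)

    nearest = enrich_mod.annotate_nearest_gene(
        manifest.loc[background, ["probe_id", "chrom", "pos"]],
        study.gene_models, window=params.gene_window,
    )
    universe_genes = sorted(set(nearest.dropna()))
    adms_probes = sets["da"] + sets["ia"]
    set_genes = sorted(set(nearest.reindex(adms_probes).dropna()))
    disease_genes = study.gene_models.loc[
        study.gene_models["disease"].astype(bool), "gene_id"
    ]
    if set_genes and universe_genes:
        disease = enrich_mod.disease_gene_enrichment(
            set_genes, universe_genes, disease_genes
        )
    else:
        disease = dict(n_set=0, n_rest=len(universe_genes), p=1.0,
                       frac_set_pct=0.0, frac_rest_pct=0.0, odds_ratio=np.nan,
                       table=(0, 0, 0, 0))
    summary = dict(
        n_background=len(background),
        n_da=len(sets["da"]), n_ia=len(sets["ia"]),
        n_universe_genes=len(universe_genes), n_set_genes=len(set_genes),
        disease_p=disease["p"],
        disease_frac_set_pct=disease["frac_set_pct"],
        disease_frac_rest_pct=disease["frac_rest_pct"],
    )
    return EnrichResult(rows=rows, disease=disease, nearest_gene=nearest,
                        summary=summary)


# ---------------------------------------------------------------------------
# file-backed pipeline
# ---------------------------------------------------------------------------

@dataclass
class SummaryReport:
    """Per-stage counts; every percentage recomputes from its own counts."""

    sections: dict

    def to_text(self) -> str:
        lines = ["methylong pipeline summary", "=" * 30]
        for stage, entries in self.sections.items():
            lines.append(f"[{stage}]")
            for k, v in entries.items():
                lines.append(f"  {k} = {v}")
        return "\n".join(lines) + "\n"

    def flat(self) -> pd.DataFrame:
        rows = []
        for stage, entries in self.sections.items():
            for k, v in entries.items():
                rows.append((stage, k, v))
        return pd.DataFrame(rows, columns=["stage", "key", "value"])


def _flatten(prefix: str, obj, into: dict) -> None:
    if isinstance(obj, dict):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, into)
    else:
        into[prefix] = obj


def run_pipeline(config: PipelineConfig, until: str = "report") -> SummaryReport:
    """Execute stages in order (optionally stopping after ``until``);
    any stage failure aborts naming the stage."""
    if until not in STAGES:
        raise ValueError(f"unknown stage '{until}'")
    os.makedirs(config.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    state = _StageState(config.out_dir)
    data_dir = config.data_dir or os.path.join(config.out_dir, "data")

    stage = "simulate"
    try:
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=config.substream("simulate"))
            digest = hashlib.md5(repr(sim_cfg).encode()).hexdigest()
            marker = os.path.join(data_dir, "manifest.tsv")
            if state.is_done(stage, digest, [marker]):
                logger.info("stage simulate up to date; skipping")
            else:
                study = generate_study(sim_cfg)
                write_outputs(study, data_dir)
                state.mark(stage, digest)
        if until == "simulate":
            return SummaryReport(sections={"simulate": {"data_dir": data_dir}})
        if not os.path.exists(os.path.join(data_dir, "manifest.tsv")):
            raise FileNotFoundError(f"no study data under {data_dir}")

        stage = "analysis"
        analysis_digest = _dir_digest(data_dir, extra=repr(config.params))
        report_path = os.path.join(config.out_dir, "report.json")
        if state.is_done("analysis", analysis_digest, [report_path]):
            logger.info("analysis stages up to date; skipping recompute")
            with open(report_path) as fh:
                return SummaryReport(sections=json.load(fh))

        study = load_study(data_dir)
        params = config.params
        report_sections: dict = {}

        stage = "preprocess"
        pre = preprocess_study(study, params, random_state=config.substream(stage))
        pdir = os.path.join(config.out_dir, "preprocess")
        os.makedirs(pdir, exist_ok=True)
        for cset, adj in pre.adjusted.items():
            adj.values.to_csv(os.path.join(pdir, f"adjusted_{cset}.tsv"),
                              sep="\t", float_format="%.6g")
        pre.cell_props.to_csv(os.path.join(pdir, "cell_proportions.tsv"), sep="\t")
        qc_rows = (
            [(s, "sample", r) for s, r in pre.qc.samples_removed]
            + [(p, "probe", r) for p, r in pre.qc.probes_removed]
        )
        pd.DataFrame(qc_rows, columns=["id", "kind", "reason"]).to_csv(
            os.path.join(pdir, "qc_report.tsv"), sep="\t", index=False)
        counts = pre.qc.counts()
        report_sections["preprocess"] = {
            "n_children_kept": len(pre.kept_design),
            "n_probes_kept": len(pre.kept_probes),
            **{f"removed_{k}": v for k, v in counts.items()},
            **{f"n_control_pcs_{cset}": pre.adjusted[cset].n_control_pcs
               for cset in pre.adjusted},
        }

        if until == "preprocess":
            return SummaryReport(sections=report_sections)

        stage = "adms"
        adms_res = run_adms(pre)
        adir = os.path.join(config.out_dir, "adms")
        os.makedirs(adir, exist_ok=True)
        adms_res.records.to_csv(os.path.join(adir, "dms_records.tsv"),
                                sep="\t", index=False)
        s = adms_res.summary
        report_sections["adms"] = {
            "bonferroni_threshold": s.threshold,
            "n_significant_both": s.n_significant,
            "n_da": s.n_da, "n_ia": s.n_ia,
            "n_inconsistent": s.n_inconsistent,
            "n_consistent": s.n_consistent,
            "pct_da": s.pct_da, "pct_ia": s.pct_ia,
            "pct_inconsistent": s.pct_inconsistent,
        }

        if until == "adms":
            return SummaryReport(sections=report_sections)

        stage = "dmeqtl"
        qtl = run_dmeqtl(study, pre, adms_res, params)
        qdir = os.path.join(config.out_dir, "dmeqtl")
        os.makedirs(qdir, exist_ok=True)
        qtl.table.to_csv(os.path.join(qdir, "dmeqtl_all_pairs.tsv"),
                         sep="\t", index=False)
        qtl.filtered.to_csv(os.path.join(qdir, "dmeqtl_filtered.tsv"),
                            sep="\t", index=False)
        qtl.effect_compare.to_csv(os.path.join(qdir, "effect_compare.tsv"),
                                  sep="\t", index=False)
        qtl_flat: dict = {}
        _flatten("", qtl.summary, qtl_flat)
        report_sections["dmeqtl"] = qtl_flat

        if until == "dmeqtl":
            return SummaryReport(sections=report_sections)

        stage = "assoc"
        asc = run_assoc(study, pre, adms_res, params)
        sdir = os.path.join(config.out_dir, "assoc")
        os.makedirs(sdir, exist_ok=True)
        for cset, df in asc.smoking.items():
            df.to_csv(os.path.join(sdir, f"smoking_{cset}.tsv"), sep="\t", index=False)
        for lab, df in asc.asthma.items():
            df.to_csv(os.path.join(sdir, f"asthma_{lab}.tsv"), sep="\t", index=False)
        asc_flat: dict = {}
        _flatten("", asc.summary, asc_flat)
        report_sections["assoc"] = asc_flat

        if until == "assoc":
            return SummaryReport(sections=report_sections)

        stage = "enrich"
        enr = run_enrich(study, pre, adms_res, params)
        edir = os.path.join(config.out_dir, "enrich")
        os.makedirs(edir, exist_ok=True)
        enr.rows.to_csv(os.path.join(edir, "enrichment.tsv"), sep="\t", index=False)
        enr.nearest_gene.rename("gene_id").rename_axis("probe_id").reset_index().to_csv(
            os.path.join(edir, "nearest_gene.tsv"), sep="\t", index=False)
        enr_flat: dict = {}
        _flatten("", enr.summary, enr_flat)
        report_sections["enrich"] = enr_flat

        if until == "enrich":
            return SummaryReport(sections=report_sections)

        stage = "report"
        report = SummaryReport(sections=report_sections)
        report.flat().to_csv(os.path.join(config.out_dir, "report.tsv"),
                             sep="\t", index=False)
        with open(os.path.join(config.out_dir, "report.txt"), "w") as fh:
            fh.write(report.to_text())
        _write_json(report_sections, os.path.join(config.out_dir, "report.json"))
        state.mark("analysis", analysis_digest)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
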