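"""Synthetic two-timepoint methylation study generator.

Emulates the statistical structure of a paired longitudinal blood-
methylation design: four birth cohorts forming two disjoint comparison
sets ("young": ages 0 -> 4/5, "old": ages 4 -> 8), beta values arising
from cell-type mixtures plus planted age, cis-genotype, exposure and
disease effects, a chip-level technical factor mirrored in negative
control probes, and a complete ground-truth manifest for recovery
testing.

Noise is applied on the logit scale and inverse-transformed so betas
respect their [0, 1] bounds; both samples of a child share a chip, as
on a real array layout, which is what makes control-probe correction
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import GenotypeData, ensure_dir, read_matrix_tsv, read_table_tsv, \
    read_vcf, write_matrix_tsv, write_table_tsv, write_vcf

CELL_TYPES = ("monocytes", "b_cells", "nk_cells", "cd4_t", "cd8_t", "granulocytes")
#: Rough blood mixing proportions used as the Dirichlet mean.
_CELL_BASE = np.array([0.08, 0.08, 0.06, 0.15, 0.08, 0.55])
_DIRICHLET_CONC = 60.0

CHROMATIN_STATES = (
    "DNase", "Enh", "EnhBiv", "TssA", "TssBiv", "Tx", "TxWk", "H3K9me3", "H3K27ac",
)
_STATE_BASE_RATE = {
    "DNase": 0.15, "Enh": 0.12, "EnhBiv": 0.04, "TssA": 0.10, "TssBiv": 0.05,
    "Tx": 0.15, "TxWk": 0.20, "H3K9me3": 0.08, "H3K27ac": 0.12,
}
N_BLOOD_CELLTYPES = 27

ISLAND_RELATIONS = ("Island", "Shore", "Shelf", "OpenSea")
_ISLAND_BASE = np.array([0.31, 0.23, 0.10, 0.36])
GENE_REGIONS = ("TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "Intergenic")
_REGION_BASE = np.array([0.13, 0.10, 0.12, 0.06, 0.33, 0.04, 0.22])

#: Length of the probe body upstream of the target site (bp); SNPs in
#: this interval can distort the measured signal.
PROBE_INTERVAL_BP = 50
CIS_WINDOW_BP = 250_000

_N_SNP_PANEL = 65


@dataclass
class SimConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_children_per_cohort: int = 150
    cohorts: tuple = (
        ("young_a", "young"),
        ("young_b", "young"),
        ("old_a", "old"),
        ("old_b", "old"),
    )
    n_probes: int = 20_000
    n_control_probes: int = 613
    n_snps: int = 5_000
    frac_da: float = 0.05
    frac_ia: float = 0.03
    effect_mean_da: float = 0.05
    effect_mean_ia: float = 0.05
    n_causal_meqtl: int = 100
    meqtl_beta_range: tuple = (0.02, 0.08)
    frac_age_varying_meqtl: float = 0.5
    smoking_prevalence: float = 0.25
    n_smoking_cpgs: int = 30
    smoking_effect: float = -0.02
    asthma_prevalence: float = 0.12
    n_asthma_cpgs: int = 5
    asthma_effect: float = 0.03
    n_cell_types: int = 6
    tech_factor_sd: float = 0.15
    noise_sd: float = 0.035
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_children_per_cohort", "n_probes", "n_control_probes", "n_snps",
            "n_cell_types",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "frac_da", "frac_ia", "frac_age_varying_meqtl",
            "smoking_prevalence", "asthma_prevalence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.frac_da + self.frac_ia > 1.0:
            raise ValueError("frac_da + frac_ia must not exceed 1")
        if self.n_cell_types != len(CELL_TYPES):
            raise ValueError(f"generator models exactly {len(CELL_TYPES)} cell types")
        sets = {s for _, s in self.cohorts}
        if sets != {"young", "old"}:
            raise ValueError("cohorts must cover both 'young' and 'old' sets")


@dataclass
class IntensityPair:
    """Methylated/unmethylated probe intensities with offset alpha."""

    M: float
    U: float
    alpha: float = 100.0

    def __post_init__(self) -> None:
        if self.M < 0 or self.U < 0 or self.alpha < 0:
            raise ValueError("intensities and alpha must be non-negative")


def beta_from_intensities(x: IntensityPair) -> float:
    """Methylation fraction M / (U + M + alpha), in [0, 1)."""
    total = x.U + x.M + x.alpha
    if total <= 0:
        raise ValueError("M + U + alpha must be positive")
    return x.M / total


@dataclass
class SimTruth:
    """Planted ground truth, the oracle for every recovery test."""

    age_effect: pd.DataFrame          # probe x {young, old} signed delta-beta
    causal_pairs: pd.DataFrame        # snp, probe, effects, artifact class
    smoking_probes: pd.Series         # probe -> effect on young-set delta
    asthma_probes: pd.Series          # probe -> effect on level
    cell_profiles: pd.DataFrame       # cell type x probe reference means
    sample_mixtures: pd.DataFrame     # sample x cell type proportions
    tech_loadings: dict               # target/control loadings, chip factors


@dataclass
class SimStudy:
    """Everything the pipeline consumes, plus the truth manifest."""

    config: SimConfig
    betas: dict                       # set -> probes x samples DataFrame
    design: pd.DataFrame              # one row per child (paired design)
    samples: pd.DataFrame             # one row per sample
    control: pd.DataFrame             # control probes x all samples
    detection_p: pd.DataFrame         # probes x all samples
    genotypes: GenotypeData           # children x SNPs
    manifest: pd.DataFrame            # per-probe annotation
    cell_reference: pd.DataFrame      # cell type x reference probes
    gene_models: pd.DataFrame         # gene_id, chrom, tss, disease
    chromatin: dict = field(default_factory=dict)  # state -> probe x 27 bool
    truth: SimTruth | None = None


# ---------------------------------------------------------------------------
# generation internals
# ---------------------------------------------------------------------------

def _make_manifest(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    P = cfg.n_probes
    probe_ids = np.array([f"cg{i:08d}" for i in range(P)])
    chrom_pool = ["chr1", "chr2", "chr3", "chr4", "chr5", "chr6"]
    n_x = max(1, int(round(0.02 * P)))
    n_auto = P - n_x
    # contiguous blocks per chromosome keep positions sorted within chrom
    sizes = np.full(len(chrom_pool), n_auto // len(chrom_pool))
    sizes[: n_auto % len(chrom_pool)] += 1
    chroms = np.concatenate(
        [np.repeat(c, s) for c, s in zip(chrom_pool, sizes)] + [np.repeat("chrX", n_x)]
    )
    pos = np.empty(P, dtype=np.int64)
    for c in chrom_pool + ["chrX"]:
        idx = np.where(chroms == c)[0]
        pos[idx] = 1000 + np.cumsum(rng.integers(500, 5000, size=idx.size))
    island = rng.choice(ISLAND_RELATIONS, size=P, p=_ISLAND_BASE)
    region = rng.choice(GENE_REGIONS, size=P, p=_REGION_BASE)
    is_cph = rng.random(P) < 0.007
    multi_map = rng.random(P) < 0.01
    snp_panel = np.zeros(P, dtype=bool)
    panel_idx = rng.choice(np.where(~is_cph & (chroms != "chrX"))[0],
                           size=_N_SNP_PANEL, replace=False)
    snp_panel[panel_idx] = True
    target_maf = np.zeros(P)
    has_snp = rng.random(P) < 0.03
    target_maf[has_snp] = rng.uniform(0.0, 0.25, size=int(has_snp.sum()))
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": pos - 1,          # BED: 0-based half-open target site
            "end": pos,
            "probe_id": probe_ids,
            "pos": pos,                # 1-based target coordinate
            "island_relation": island,
            "gene_region": region,
            "is_cph": is_cph,
            "multi_map": multi_map,
            "snp_panel": snp_panel,
            "target_maf": target_maf,
            "interval_start": pos - PROBE_INTERVAL_BP,  # 1-based inclusive
            "interval_end": pos - 1,
        }
    ).set_index(pd.Index(probe_ids, name="probe_id"), drop=False)


def _make_children(cfg: SimConfig, rng: np.random.Generator):
    design_rows, sample_rows = [], []
    ages = {"young": (0, 4), "old": (4, 8)}
    for cohort, cset in cfg.cohorts:
        n = cfg.n_children_per_cohort
        sex = rng.integers(0, 2, size=n)
        m_age = np.round(rng.normal(30, 4.5, size=n), 1)
        parity = rng.poisson(0.9, size=n)
        m_edu = rng.choice(["low", "mid", "high"], size=n, p=[0.25, 0.45, 0.30])
        smoke = (rng.random(n) < cfg.smoking_prevalence).astype(int)
        asthma = (rng.random(n) < cfg.asthma_prevalence).astype(int)
        # bisulphite-kit batches are study-wide lots shared across cohorts
        batch = rng.choice(["kit_b1", "kit_b2", "kit_b3"], size=n)
        a1, a2 = ages[cset]
        for j in range(n):
            child = f"{cohort}_C{j:04d}"
            chip = f"{cohort}_chip{j // 6:03d}"
            design_rows.append(
                dict(child_id=child, cohort=cohort, comparison_set=cset,
                     sample_t1=f"{child}_T1", sample_t2=f"{child}_T2",
                     sex=int(sex[j]), maternal_age=float(m_age[j]),
                     parity=int(parity[j]), maternal_education=m_edu[j],
                     maternal_smoking=int(smoke[j]), asthma=int(asthma[j]))
            )
            for tp, age in (("t1", a1), ("t2", a2)):
                sample_rows.append(
                    dict(sample_id=f"{child}_T{1 if tp == 't1' else 2}",
                         child_id=child, cohort=cohort, comparison_set=cset,
                         timepoint=tp, age=age, chip=chip,
                         array_position=0,
                         batch=batch[j], sex=int(sex[j]))
                )
    design = pd.DataFrame(design_rows).set_index("child_id", drop=False)
    samples = pd.DataFrame(sample_rows).set_index("sample_id", drop=False)
    # samples land on their chip in random well order; positions must not
    # align with timepoint or the position covariate would span the age
    # contrast
    pos = np.empty(len(samples), dtype=int)
    for _, idx in samples.groupby("chip").indices.items():
        pos[idx] = 1 + rng.permutation(12)[: len(idx)]
    samples["array_position"] = pos
    return design, samples


def _make_cell_profiles(cfg, rng, base: np.ndarray, manifest: pd.DataFrame):
    P = cfg.n_probes
    informative = rng.random(P) < 0.25
    profiles = np.tile(base, (len(CELL_TYPES), 1))
    dev = rng.normal(0.0, 0.12, size=(len(CELL_TYPES), P))
    profiles[:, informative] += dev[:, informative]
    profiles = np.clip(profiles, 0.02, 0.98)
    prof = pd.DataFrame(profiles,
                        index=pd.Index(list(CELL_TYPES), name="cell_type"),
                        columns=manifest["probe_id"].to_numpy())
    return prof, informative


def _pick_reference_probes(rng, manifest, informative, exclude_idx) -> list:
    """Cell-type-discriminating, age-stable probes for deconvolution.

    Planted age-effect probes are excluded: a reference panel drifting
    with age would not separate composition change from methylation
    change, and reference panels are selected for cell specificity.
    """
    pool = np.where(informative)[0]
    pool = np.setdiff1d(pool, np.asarray(exclude_idx, dtype=int))
    n_ref = min(500, pool.size)
    chosen = rng.choice(pool, size=n_ref, replace=False)
    return list(manifest["probe_id"].to_numpy()[chosen])


def _plant_age_effects(cfg, rng, manifest, base):
    eligible = (
        (manifest["chrom"] != "chrX")
        & ~manifest["is_cph"] & ~manifest["multi_map"] & ~manifest["snp_panel"]
        & (manifest["target_maf"] <= 0.10)
        & (base > 0.25) & (base < 0.75)
    ).to_numpy()
    n_da = int(round(cfg.frac_da * cfg.n_probes))
    n_ia = int(round(cfg.frac_ia * cfg.n_probes))
    pool = np.where(eligible)[0]
    if n_da + n_ia > pool.size:
        raise ValueError("not enough eligible probes for requested effect fractions")
    chosen = rng.choice(pool, size=n_da + n_ia, replace=False)
    da_idx, ia_idx = chosen[:n_da], chosen[n_da:]
    age_effect = pd.DataFrame(
        0.0, index=manifest["probe_id"], columns=["young", "old"]
    )
    for cset in ("young", "old"):
        if n_da:
            mag = np.abs(rng.normal(cfg.effect_mean_da, 0.3 * cfg.effect_mean_da, n_da))
            age_effect.iloc[da_idx, age_effect.columns.get_loc(cset)] = -mag
        if n_ia:
            mag = np.abs(rng.normal(cfg.effect_mean_ia, 0.3 * cfg.effect_mean_ia, n_ia))
            age_effect.iloc[ia_idx, age_effect.columns.get_loc(cset)] = mag
    return age_effect, da_idx, ia_idx


def _place_snps(cfg, rng, manifest, adms_idx):
    """SNP positions: causal SNPs near planted probes, some inside probe
    bodies (plus LD partners), the rest anchored at random probes."""
    P = cfg.n_probes
    n_inprobe = min(30, cfg.n_snps // 50)
    n_inprobe_adms = n_inprobe // 2
    n_ld = min(10, n_inprobe_adms)
    n_clean_causal = cfg.n_causal_meqtl
    if n_clean_causal + n_inprobe + n_ld > cfg.n_snps:
        raise ValueError("n_snps too small for requested causal/artifact SNPs")

    chrom = np.empty(cfg.n_snps, dtype=object)
    pos = np.zeros(cfg.n_snps, dtype=np.int64)
    probe_pos = manifest["pos"].to_numpy()
    probe_chrom = manifest["chrom"].to_numpy()
    auto = np.where(probe_chrom != "chrX")[0]
    if adms_idx.size == 0:
        # all-null study: anchor "causal" geometry at arbitrary autosomal
        # probes (the planted effects themselves are zero-count anyway)
        adms_idx = auto
    n_inprobe_adms = min(n_inprobe_adms, adms_idx.size)
    n_ld = min(n_ld, n_inprobe_adms)

    cursor = 0
    # clean causal SNPs: within the cis window of a planted a-DMS probe,
    # outside its probe body
    causal_probe_idx = rng.choice(adms_idx, size=n_clean_causal, replace=True)
    for k, pi in enumerate(causal_probe_idx):
        offset = int(rng.integers(200, 240_000)) * int(rng.choice([-1, 1]))
        chrom[cursor + k] = probe_chrom[pi]
        pos[cursor + k] = max(1, probe_pos[pi] + offset)
    clean_causal = np.arange(cursor, cursor + n_clean_causal)
    cursor += n_clean_causal

    # in-probe SNPs: half hosted by planted probes, half by random probes
    host_adms = rng.choice(adms_idx, size=n_inprobe_adms, replace=False)
    host_rand = rng.choice(auto, size=n_inprobe - n_inprobe_adms, replace=False)
    hosts = np.concatenate([host_adms, host_rand])
    for k, pi in enumerate(hosts):
        chrom[cursor + k] = probe_chrom[pi]
        pos[cursor + k] = probe_pos[pi] - int(rng.integers(1, PROBE_INTERVAL_BP + 1))
    inprobe = np.arange(cursor, cursor + n_inprobe)
    inprobe_hosts = hosts
    cursor += n_inprobe

    # LD partners of planted-probe in-probe SNPs, outside the probe body
    ld_of = rng.choice(n_ld, size=n_ld, replace=False)  # partner i tags inprobe[ld_of[i]]
    for k in range(n_ld):
        pi = host_adms[ld_of[k]]
        offset = int(rng.integers(2_000, 100_000)) * int(rng.choice([-1, 1]))
        chrom[cursor + k] = probe_chrom[pi]
        pos[cursor + k] = max(1, probe_pos[pi] + offset)
    ld_partners = np.arange(cursor, cursor + n_ld)
    cursor += n_ld

    # background SNPs anchored at random probes
    anchors = rng.choice(auto, size=cfg.n_snps - cursor, replace=True)
    offs = rng.integers(-300_000, 300_000, size=anchors.size)
    chrom[cursor:] = probe_chrom[anchors]
    pos[cursor:] = np.maximum(1, probe_pos[anchors] + offs)

    placement = dict(
        clean_causal=clean_causal, causal_probe_idx=causal_probe_idx,
        inprobe=inprobe, inprobe_hosts=inprobe_hosts,
        inprobe_adms=inprobe[:n_inprobe_adms], adms_hosts=host_adms,
        ld_partners=ld_partners, ld_of=ld_of,
    )
    return chrom, pos, placement


def _draw_genotypes(cfg, rng, chrom, pos, placement, n_children):
    maf = rng.uniform(0.05, 0.5, size=cfg.n_snps)
    dosage = rng.binomial(2, maf[None, :], size=(n_children, cfg.n_snps)).astype(np.int8)
    # LD partners copy their tagged in-probe SNP with a 5% per-allele flip
    for k, part in enumerate(placement["ld_partners"]):
        src = placement["inprobe_adms"][placement["ld_of"][k]]
        g = dosage[:, src].copy()
        flip = rng.random(n_children) < 0.10
        g[flip] = rng.binomial(2, maf[part], size=int(flip.sum())).astype(np.int8)
        dosage[:, part] = g
    # recompute empirical-ish maf for partners to stay consistent
    ref = rng.choice(list("ACGT"), size=cfg.n_snps)
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    snps = pd.DataFrame(
        {
            "snp_id": [f"rs{i:07d}" for i in range(cfg.n_snps)],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "maf": np.clip(maf, 0.05, 0.5),
        }
    )
    return dosage, snps


def _plant_causal_effects(cfg, rng, manifest, placement, snps):
    """Cross-sectional per-allele effects at ages 0/4/8 for causal pairs.

    Stable pairs keep the same effect at every age (no effect on change);
    age-varying pairs gain a linear-in-age component, so the change-score
    effect is the same in both 4-year comparison windows.
    """
    probe_ids = manifest["probe_id"].to_numpy()
    rows = []
    columns = ["snp_id", "probe_id", "b_age0", "b_age4", "b_age8",
               "d_effect_young", "d_effect_old", "age_varying", "artifact"]
    if cfg.n_causal_meqtl == 0:
        # fully null genotype-methylation coupling; probe-body SNP
        # geometry remains available for filter tests
        return pd.DataFrame(columns=columns)

    def _draw(snp_idx, probe_idx, artifact):
        base = rng.uniform(0.03, 0.08) * rng.choice([-1.0, 1.0])
        varying = rng.random() < cfg.frac_age_varying_meqtl or artifact != "clean"
        if varying:
            lo, hi = cfg.meqtl_beta_range
            delta = rng.uniform(lo, hi)
            delta *= np.sign(base) if rng.random() < 0.8 else -np.sign(base)
        else:
            delta = 0.0
        b4 = base
        b0, b8 = b4 - delta, b4 + delta
        rows.append(
            dict(snp_id=snps.loc[snp_idx, "snp_id"], probe_id=probe_ids[probe_idx],
                 b_age0=b0, b_age4=b4, b_age8=b8,
                 d_effect_young=b4 - b0, d_effect_old=b8 - b4,
                 age_varying=bool(varying), artifact=artifact)
        )

    for k, snp_idx in enumerate(placement["clean_causal"]):
        _draw(int(snp_idx), int(placement["causal_probe_idx"][k]), "clean")
    for k, snp_idx in enumerate(placement["inprobe_adms"]):
        _draw(int(snp_idx), int(placement["adms_hosts"][k]), "in_probe")
    for k, snp_idx in enumerate(placement["ld_partners"]):
        host = int(placement["adms_hosts"][placement["ld_of"][k]])
        _draw(int(snp_idx), host, "ld_partner")
    return pd.DataFrame(rows)


def _make_chromatin(cfg, rng, manifest, da_idx, ia_idx):
    """Per-state membership for 27 blood cell types.

    A latent per-probe state membership (mildly tilted at planted
    probes) is subsampled per cell type, so the 27-type union recovers
    roughly the latent track.
    """
    P = cfg.n_probes
    tilts_da = {"H3K27ac": 1.8, "Enh": 1.5, "H3K9me3": 0.5, "TssBiv": 0.8}
    tilts_ia = {"TssBiv": 2.5, "EnhBiv": 2.5, "H3K9me3": 1.5, "Enh": 1.5}
    chromatin = {}
    for state in CHROMATIN_STATES:
        rate = np.full(P, _STATE_BASE_RATE[state])
        rate[da_idx] *= tilts_da.get(state, 1.0)
        rate[ia_idx] *= tilts_ia.get(state, 1.0)
        latent = rng.random(P) < np.clip(rate, 0, 0.95)
        tracks = latent[:, None] & (rng.random((P, N_BLOOD_CELLTYPES)) < 0.35)
        chromatin[state] = pd.DataFrame(
            tracks, index=manifest["probe_id"],
            columns=[f"blood_ct{k:02d}" for k in range(1, N_BLOOD_CELLTYPES + 1)],
        )
    return chromatin


def _make_genes(cfg, rng, manifest, adms_idx):
    n_genes = max(200, cfg.n_probes // 8)
    probe_chrom = manifest["chrom"].to_numpy()
    probe_pos = manifest["pos"].to_numpy()
    auto = np.where(probe_chrom != "chrX")[0]
    anchors = rng.choice(auto, size=n_genes, replace=True)
    tss = probe_pos[anchors] + rng.integers(-80_000, 80_000, size=n_genes)
    genes = pd.DataFrame(
        {
            "gene_id": [f"GENE{i:05d}" for i in range(n_genes)],
            "chrom": probe_chrom[anchors],
            "tss": np.maximum(1, tss),
        }
    )
    # disease flags: baseline 14%, upweighted for genes nearest planted probes
    from .enrichment import annotate_nearest_gene

    nearest = annotate_nearest_gene(
        manifest.iloc[adms_idx][["probe_id", "chrom", "pos"]], genes
    )
    adms_genes = set(nearest.dropna())
    p = np.where(genes["gene_id"].isin(adms_genes), 0.20, 0.14)
    genes["disease"] = rng.random(n_genes) < p
    return genes


def generate_study(config: SimConfig) -> SimStudy:
    """Generate the full synthetic study; identical seeds give identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    manifest = _make_manifest(cfg, rng)
    base = np.empty(cfg.n_probes)
    kind = rng.random(cfg.n_probes)
    low, high = kind < 0.35, kind >= 0.70
    mid = ~(low | high)
    base[low] = rng.beta(2, 10, size=int(low.sum()))
    base[high] = rng.beta(10, 2, size=int(high.sum()))
    base[mid] = rng.uniform(0.2, 0.8, size=int(mid.sum()))
    base = np.clip(base, 0.02, 0.98)

    profiles, informative = _make_cell_profiles(cfg, rng, base, manifest)
    age_effect, da_idx, ia_idx = _plant_age_effects(cfg, rng, manifest, base)
    adms_idx = np.concatenate([da_idx, ia_idx])
    ref_probes = _pick_reference_probes(rng, manifest, informative, adms_idx)

    design, samples = _make_children(cfg, rng)
    children = design.index.to_numpy()

    chrom, pos, placement = _place_snps(cfg, rng, manifest, adms_idx)
    dosage, snps = _draw_genotypes(cfg, rng, chrom, pos, placement, len(children))
    causal = _plant_causal_effects(cfg, rng, manifest, placement, snps)
    genotypes = GenotypeData(dosage=dosage, sample_ids=list(children), snps=snps)

    # exposure / disease probes sit inside the planted a-DMS universe
    smoking_idx = rng.choice(da_idx, size=min(cfg.n_smoking_cpgs, da_idx.size),
                             replace=False) if da_idx.size else np.array([], int)
    asthma_idx = rng.choice(adms_idx, size=min(cfg.n_asthma_cpgs, adms_idx.size),
                            replace=False) if adms_idx.size else np.array([], int)
    probe_ids = manifest["probe_id"].to_numpy()
    smoking_probes = pd.Series(cfg.smoking_effect, index=probe_ids[smoking_idx])
    asthma_probes = pd.Series(cfg.asthma_effect, index=probe_ids[asthma_idx])

    # chip technical factor, mirrored in control probes
    chips = samples["chip"].unique()
    chip_gamma = pd.Series(rng.standard_normal(len(chips)), index=chips)
    load_target = rng.standard_normal(cfg.n_probes)
    load_control = rng.standard_normal(cfg.n_control_probes)

    # SNP-panel probe genotypes per child (identity fingerprints)
    panel_rows = np.where(manifest["snp_panel"])[0]
    panel_maf = rng.uniform(0.2, 0.5, size=panel_rows.size)
    panel_geno = rng.binomial(2, panel_maf[None, :], size=(len(children), panel_rows.size))
    panel_geno = pd.DataFrame(panel_geno, index=children)

    causal_snp_col = snps.set_index("snp_id").index
    betas, mixtures_all = {}, []
    for cset in ("young", "old"):
        smask = (samples["comparison_set"] == cset).to_numpy()
        sub = samples[smask]
        S = len(sub)
        mix = rng.dirichlet(_CELL_BASE * _DIRICHLET_CONC, size=S)
        mixtures_all.append(pd.DataFrame(mix, index=sub.index, columns=list(CELL_TYPES)))
        M = profiles.to_numpy().T @ mix.T  # probes x samples

        is_t2 = (sub["timepoint"] == "t2").to_numpy()
        ages = sub["age"].to_numpy()
        child_of = sub["child_id"].to_numpy()
        child_pos = design.index.get_indexer(child_of)

        M[:, is_t2] += age_effect[cset].to_numpy()[:, None]

        # cross-sectional genotype effects at the sample's age
        b_by_age = {0: "b_age0", 4: "b_age4", 8: "b_age8"}
        probe_pos_of = {p: i for i, p in enumerate(probe_ids)}
        snp_pos_of = {s: i for i, s in enumerate(causal_snp_col)}
        for row in causal.itertuples(index=False):
            pi = probe_pos_of[row.probe_id]
            g = dosage[child_pos, snp_pos_of[row.snp_id]].astype(float)
            for age in np.unique(ages):
                b = getattr(row, b_by_age[int(age)])
                M[pi, ages == age] += b * g[ages == age]

        if cset == "young" and smoking_idx.size:
            smoke = design["maternal_smoking"].to_numpy()[child_pos].astype(float)
            M[np.ix_(smoking_idx, np.where(is_t2)[0])] += (
                cfg.smoking_effect * smoke[is_t2][None, :]
            )
        if asthma_idx.size:
            has = design["asthma"].to_numpy()[child_pos].astype(float)
            M[asthma_idx, :] += cfg.asthma_effect * has[None, :]

        # SNP-panel fingerprints: genotype-determined, equal at both timepoints
        M[panel_rows, :] = 0.06 + 0.44 * panel_geno.to_numpy()[child_pos, :].T

        M = np.clip(M, 0.02, 0.98)
        L = logit(M)
        gamma = chip_gamma[sub["chip"]].to_numpy()
        L += cfg.tech_factor_sd * load_target[:, None] * gamma[None, :]
        sigma_l = cfg.noise_sd / (M * (1.0 - M))
        L += rng.standard_normal(M.shape) * sigma_l
        betas[cset] = pd.DataFrame(
            expit(L), index=pd.Index(probe_ids, name="probe_id"),
            columns=sub.index.to_numpy(),
        )
        del M, L, sigma_l

    sample_order = samples.index
    control_base = rng.normal(300.0, 30.0, size=cfg.n_control_probes)
    gamma_all = chip_gamma[samples["chip"]].to_numpy()
    control_vals = (
        control_base[:, None]
        + 40.0 * load_control[:, None] * gamma_all[None, :]
        + rng.normal(0.0, 20.0, size=(cfg.n_control_probes, len(sample_order)))
    )
    control = pd.DataFrame(
        np.maximum(control_vals, 1.0),
        index=pd.Index([f"neg_ctrl_{i:04d}" for i in range(cfg.n_control_probes)],
                       name="control_id"),
        columns=sample_order.to_numpy(),
    )

    det = rng.uniform(0.0, 0.008, size=(cfg.n_probes, len(sample_order))).astype(np.float32)
    fail = rng.random(det.shape) < 0.002
    det[fail] = rng.uniform(0.011, 1.0, size=int(fail.sum())).astype(np.float32)
    detection_p = pd.DataFrame(
        det, index=pd.Index(probe_ids, name="probe_id"),
        columns=sample_order.to_numpy(),
    )

    chromatin = _make_chromatin(cfg, rng, manifest, da_idx, ia_idx)
    gene_models = _make_genes(cfg, rng, manifest, adms_idx)

    truth = SimTruth(
        age_effect=age_effect,
        causal_pairs=causal,
        smoking_probes=smoking_probes,
        asthma_probes=asthma_probes,
        cell_profiles=profiles,
        sample_mixtures=pd.concat(mixtures_all),
        tech_loadings=dict(
            target=pd.Series(load_target, index=probe_ids),
            control=pd.Series(load_control, index=control.index),
            chip_factor=chip_gamma,
        ),
    )
    return SimStudy(
        config=cfg,
        betas=betas,
        design=design,
        samples=samples,
        control=control,
        detection_p=detection_p,
        genotypes=genotypes,
        manifest=manifest,
        cell_reference=profiles[ref_probes],
        gene_models=gene_models,
        chromatin=chromatin,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_outputs(study: SimStudy, directory: str) -> list[str]:
    """Write the study as TSV/VCF; returns the file list."""
    d = ensure_dir(directory)
    written = []

    def _w(fn, df, matrix=False):
        path = f"{d}/{fn}"
        (write_matrix_tsv if matrix else write_table_tsv)(df, path)
        written.append(path)

    for cset, df in study.betas.items():
        _w(f"betas_{cset}.tsv", df, matrix=True)
    _w("control_probes.tsv", study.control, matrix=True)
    _w("detection_p.tsv", study.detection_p, matrix=True)
    _w("design.tsv", study.design.reset_index(drop=True))
    _w("samples.tsv", study.samples.reset_index(drop=True))
    _w("manifest.tsv", study.manifest.reset_index(drop=True))
    _w("cell_reference.tsv", study.cell_reference, matrix=True)
    _w("gene_models.tsv", study.gene_models)
    for state, df in study.chromatin.items():
        _w(f"chromatin_{state}.tsv", df, matrix=True)
    write_vcf(study.genotypes, f"{d}/genotypes.vcf")
    written.append(f"{d}/genotypes.vcf")
    if study.truth is not None:
        t = study.truth
        _w("truth_age_effect.tsv", t.age_effect, matrix=True)
        _w("truth_causal_pairs.tsv", t.causal_pairs)
        _w("truth_smoking.tsv", t.smoking_probes.rename("effect").rename_axis("probe_id").reset_index())
        _w("truth_asthma.tsv", t.asthma_probes.rename("effect").rename_axis("probe_id").reset_index())
        _w("truth_mixtures.tsv", t.sample_mixtures, matrix=True)
    return written


def load_study(directory: str) -> SimStudy:
    """Reload a written study (truth included when present)."""
    import os

    d = directory
    betas = {}
    for cset in ("young", "old"):
        path = f"{d}/betas_{cset}.tsv"
        if os.path.exists(path):
            betas[cset] = read_matrix_tsv(path)
    samples = read_table_tsv(f"{d}/samples.tsv").set_index("sample_id", drop=False)
    design = read_table_tsv(f"{d}/design.tsv").set_index("child_id", drop=False)
    manifest = read_table_tsv(f"{d}/manifest.tsv").set_index("probe_id", drop=False)
    chromatin = {}
    for state in CHROMATIN_STATES:
        path = f"{d}/chromatin_{state}.tsv"
        if os.path.exists(path):
            chromatin[state] = read_matrix_tsv(path).astype(bool)
    truth = None
    if os.path.exists(f"{d}/truth_age_effect.tsv"):
        smoking = read_table_tsv(f"{d}/truth_smoking.tsv")
        asthma = read_table_tsv(f"{d}/truth_asthma.tsv")
        truth = SimTruth(
            age_effect=read_matrix_tsv(f"{d}/truth_age_effect.tsv"),
            causal_pairs=read_table_tsv(f"{d}/truth_causal_pairs.tsv"),
            smoking_probes=smoking.set_index("probe_id")["effect"] if len(smoking)
            else pd.Series(dtype=float),
            asthma_probes=asthma.set_index("probe_id")["effect"] if len(asthma)
            else pd.Series(dtype=float),
            cell_profiles=pd.DataFrame(),
            sample_mixtures=read_matrix_tsv(f"{d}/truth_mixtures.tsv"),
            tech_loadings={},
        )
    return SimStudy(
        config=None,
        betas=betas,
        design=design,
        samples=samples,
        control=read_matrix_tsv(f"{d}/control_probes.tsv"),
        detection_p=read_matrix_tsv(f"{d}/detection_p.tsv"),
        genotypes=read_vcf(f"{d}/genotypes.vcf"),
        manifest=manifest,
        cell_reference=read_matrix_tsv(f"{d}/cell_reference.tsv"),
        gene_models=read_table_tsv(f"{d}/gene_models.tsv"),
        chromatin=chromatin,
        truth=truth,
    )
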