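"""cis-dMeQTL mapping of methylation change, with discovery-replication.

The phenotype is the within-child methylation change; extreme values
are trimmed at quartile +/- 3*IQR; SNPs pair with probes within an
inclusive +/-250 kb window; each pair is tested with an additive linear
model; discovery cohorts are pooled by inverse-variance fixed-effect
meta-analysis and thresholded at FDR < 0.05, with replication requiring
the same effect direction and nominal p < 0.05; pairs whose SNP sits in
the probe body (or tags one through LD r^2 > 0.2) are removed as probe
artifacts; cross-sectional MeQTL effect sizes at the two ages are
compared by magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeData  # re-exported: genotype container lives with its VCF io
from .stats import bh_fdr, ivw_meta_arrays, prop_test_one_sample

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeData", "TrimBounds", "delta_phenotype", "iqr_trim",
    "iqr_trim_matrix", "cis_pairs", "scan_additive", "discover_and_replicate",
    "probe_snp_filter", "compare_effect_sizes", "EFFECT_CLASSES",
]

CIS_WINDOW_DEFAULT = 250_000
EFFECT_CLASSES = ("weaker_at_young", "stronger_at_young", "different_direction", "tie")


@dataclass
class TrimBounds:
    """Outlier bounds q25 - 3*IQR and q75 + 3*IQR."""

    lower: float
    upper: float
    convention: str = "linear interpolation at position 1 + q(n-1)"

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def delta_phenotype(
    beta_t1: pd.DataFrame, beta_t2: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Probe x child change scores (older - younger) for a comparison set."""
    for row in design.itertuples():
        if row.sample_t1 not in beta_t1.columns:
            raise ValueError(f"child '{row.child_id}' missing timepoint-1 sample")
        if row.sample_t2 not in beta_t2.columns:
            raise ValueError(f"child '{row.child_id}' missing timepoint-2 sample")
    if not beta_t1.index.equals(beta_t2.index):
        raise ValueError("timepoint matrices must share the probe universe")
    d = (
        beta_t2[design["sample_t2"]].to_numpy()
        - beta_t1[design["sample_t1"]].to_numpy()
    )
    return pd.DataFrame(d, index=beta_t1.index, columns=design["child_id"])


def iqr_trim(values) -> tuple[np.ndarray, TrimBounds]:
    """Mask of entries inside quartile +/- 3*IQR bounds (True = keep)."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 non-missing values to trim")
    q25, q75 = np.percentile(v[finite], [25, 75])
    iqr = q75 - q25
    bounds = TrimBounds(lower=q25 - 3 * iqr, upper=q75 + 3 * iqr)
    mask = finite & (v >= bounds.lower) & (v <= bounds.upper)
    return mask, bounds


def iqr_trim_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise IQR trimming of a probe x sample matrix; returns keep-mask."""
    v = values.to_numpy(dtype=float)
    if v.shape[1] < 4:
        raise ValueError("need at least 4 samples to trim")
    q25 = np.nanpercentile(v, 25, axis=1, keepdims=True)
    q75 = np.nanpercentile(v, 75, axis=1, keepdims=True)
    iqr = q75 - q25
    keep = np.isfinite(v) & (v >= q25 - 3 * iqr) & (v <= q75 + 3 * iqr)
    return pd.DataFrame(keep, index=values.index, columns=values.columns)


def cis_pairs(
    snp_positions: pd.DataFrame,
    probe_positions: pd.DataFrame,
    window: int = CIS_WINDOW_DEFAULT,
) -> pd.DataFrame:
    """Candidate SNP-probe pairs within ``window`` bp (inclusive), same chrom.

    ``snp_positions`` needs snp_id/chrom/pos, ``probe_positions`` needs
    probe_id/chrom/pos; distance is signed snp_pos - probe_pos on 1-based
    coordinates.
    """
    out = []
    for chrom, probes_c in probe_positions.groupby("chrom", sort=False):
        snps_c = snp_positions[snp_positions["chrom"] == chrom]
        if snps_c.empty:
            continue
        ppos = probes_c["pos"].to_numpy()
        order = np.argsort(ppos, kind="stable")
        ppos_sorted = ppos[order]
        pid_sorted = probes_c["probe_id"].to_numpy()[order]
        for snp_id, spos in zip(snps_c["snp_id"], snps_c["pos"]):
            lo = np.searchsorted(ppos_sorted, spos - window, side="left")
            hi = np.searchsorted(ppos_sorted, spos + window, side="right")
            for k in range(lo, hi):
                out.append((snp_id, pid_sorted[k], int(spos - ppos_sorted[k])))
    return pd.DataFrame(out, columns=["snp_id", "probe_id", "distance"])


def scan_additive(
    pheno: pd.DataFrame,
    geno: GenotypeData,
    pairs: pd.DataFrame,
    keep_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive-model OLS of phenotype on dosage for each candidate pair.

    Trimmed (masked) samples are dropped pairwise. Pairs whose dosage is
    constant after masking are flagged untestable (NaN statistics).
    """
    dose = geno.dosage_frame().reindex(columns=geno.snp_ids)
    common = [c for c in pheno.columns if c in dose.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between phenotype and genotypes")
    Y = pheno[common].to_numpy(dtype=float)
    G = dose.loc[common].to_numpy(dtype=float).T  # snps x samples
    if keep_mask is not None:
        M = keep_mask[common].to_numpy()
    else:
        M = np.isfinite(Y)

    probe_pos = pd.Index(pheno.index).get_indexer(pairs["probe_id"])
    snp_pos = pd.Index(geno.snp_ids).get_indexer(pairs["snp_id"])
    if (probe_pos < 0).any() or (snp_pos < 0).any():
        raise KeyError("pair references a probe or SNP absent from the inputs")

    y = Y[probe_pos]                     # pairs x samples
    g = G[snp_pos]
    m = M[probe_pos] & np.isfinite(y)
    n = m.sum(axis=1).astype(float)

    yw = np.where(m, y, 0.0)
    gw = np.where(m, g, 0.0)
    sy, sg = yw.sum(axis=1), gw.sum(axis=1)
    syy = (yw * yw).sum(axis=1)
    sgg = (gw * gw).sum(axis=1)
    sgy = (gw * yw).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sxx = sgg - sg * sg / n
        sxy = sgy - sg * sy / n
        syy_c = syy - sy * sy / n
        beta = sxy / sxx
        rss = np.maximum(syy_c - beta * sxy, 0.0)
        dof = n - 2
        se = np.sqrt(rss / np.maximum(dof, 1) / sxx)
        t = beta / se
    untestable = (sxx <= 1e-12) | (dof < 1)
    p = np.full(len(beta), np.nan)
    ok = ~untestable & np.isfinite(t)
    p[ok] = 2 * sps.t.sf(np.abs(t[ok]), df=dof[ok])
    res = pairs.copy()
    res["beta"] = np.where(untestable, np.nan, beta)
    res["se"] = np.where(untestable, np.nan, se)
    res["t"] = np.where(untestable, np.nan, t)
    res["p"] = p
    res["n"] = n.astype(int)
    res["untestable"] = untestable
    return res


def discover_and_replicate(
    discovery_results: list[pd.DataFrame],
    replication_results: pd.DataFrame,
    fdr_level: float = 0.05,
    p_rep: float = 0.05,
) -> pd.DataFrame:
    """IVW meta over discovery cohorts, BH-FDR, then replication flags.

    All inputs must share an identical pair universe (same order of
    snp_id/probe_id rows). Replication requires the same effect sign as
    the pooled discovery estimate and nominal p < ``p_rep``.
    """
    if not discovery_results:
        raise ValueError("need at least one discovery cohort")
    key0 = discovery_results[0][["snp_id", "probe_id"]]
    for other in discovery_results[1:] + [replication_results]:
        if not key0.equals(other[["snp_id", "probe_id"]].set_axis(key0.index)):
            raise ValueError("pair universes differ between inputs")

    betas = np.column_stack([d["beta"].to_numpy() for d in discovery_results])
    ses = np.column_stack([d["se"].to_numpy() for d in discovery_results])
    testable = np.isfinite(betas).all(axis=1) & np.isfinite(ses).all(axis=1)

    out = key0.copy()
    if "distance" in discovery_results[0]:
        out["distance"] = discovery_results[0]["distance"].to_numpy()
    for col in ("beta", "se", "z", "p"):
        out[col] = np.nan
    if testable.any():
        b, s, z, p = ivw_meta_arrays(betas[testable], ses[testable])
        out.loc[testable, ["beta", "se", "z", "p"]] = np.column_stack([b, s, z, p])
    out["q"] = np.nan
    out.loc[testable, "q"] = bh_fdr(out.loc[testable, "p"].to_numpy())
    out["significant"] = (out["q"] < fdr_level).fillna(False)

    out["beta_rep"] = replication_results["beta"].to_numpy()
    out["p_rep"] = replication_results["p"].to_numpy()
    same_sign = np.sign(out["beta_rep"]) == np.sign(out["beta"])
    out["replicated"] = (
        out["significant"] & same_sign & (out["p_rep"] < p_rep)
    ).fillna(False)
    out["n_discovery_cohorts"] = len(discovery_results)
    return out


def _in_probe_snps(manifest: pd.DataFrame, geno: GenotypeData) -> dict:
    """probe_id -> positional indices of SNPs inside that probe's body."""
    need = {"interval_start", "interval_end"}
    if not need.issubset(manifest.columns):
        raise KeyError("manifest lacks probe interval coordinates")
    snps = geno.snps
    result: dict[str, list[int]] = {}
    for chrom, sub in snps.groupby("chrom", sort=False):
        probes_c = manifest[manifest["chrom"] == chrom]
        spos = sub["pos"].to_numpy()
        order = np.argsort(spos, kind="stable")
        spos_sorted = spos[order]
        idx_sorted = sub.index.to_numpy()[order]
        for pid, lo_b, hi_b in zip(
            probes_c["probe_id"], probes_c["interval_start"], probes_c["interval_end"]
        ):
            lo = np.searchsorted(spos_sorted, lo_b, side="left")
            hi = np.searchsorted(spos_sorted, hi_b, side="right")
            if hi > lo:
                result[pid] = [int(i) for i in idx_sorted[lo:hi]]
    return result


def probe_snp_filter(
    pairs: pd.DataFrame,
    manifest: pd.DataFrame,
    geno: GenotypeData,
    r2_max: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop pairs whose SNP is inside the probe body or tags one via LD.

    LD r^2 is the squared Pearson correlation of dosages computed from
    the sample genotype matrix. Returns (kept, removed-with-reason).
    """
    in_probe = _in_probe_snps(manifest, geno)
    snp_idx = {s: i for i, s in enumerate(geno.snp_ids)}
    dose = np.asarray(geno.dosage, dtype=float)
    reasons = []
    for row in pairs.itertuples():
        inside = in_probe.get(row.probe_id, [])
        j = snp_idx[row.snp_id]
        if j in inside:
            reasons.append("in_probe")
            continue
        reason = ""
        gj = dose[:, j]
        for k in inside:
            gk = dose[:, k]
            if gj.std() == 0 or gk.std() == 0:
                continue
            r2 = np.corrcoef(gj, gk)[0, 1] ** 2
            if r2 > r2_max:
                reason = "ld_with_probe"
                break
        reasons.append(reason)
    reasons = np.array(reasons, dtype=object)
    kept = pairs[reasons == ""].copy()
    removed = pairs[reasons != ""].copy()
    removed["reason"] = reasons[reasons != ""]
    logger.info(
        "probe-SNP filter removed %d of %d pairs", len(removed), len(pairs)
    )
    return kept, removed


def compare_effect_sizes(
    cross_age_young: pd.DataFrame, cross_age_old: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Classify per-pair cross-sectional effect magnitudes across ages.

    Same-sign pairs are split by |beta_young| vs |beta_old| (exact
    equality is a tie, reported separately); opposite signs are their
    own class. The weaker/stronger split is tested against 0.5 with a
    one-sample proportion test (successes = weaker at the younger age).
    """
    key = ["snp_id", "probe_id"]
    if not cross_age_young[key].equals(cross_age_old[key].set_axis(cross_age_young.index)):
        raise ValueError("effect-size comparison needs identical pairs at both ages")
    by = cross_age_young["beta"].to_numpy()
    bo = cross_age_old["beta"].to_numpy()
    cls = np.full(len(by), "tie", dtype=object)
    opp = np.sign(by) * np.sign(bo) < 0
    cls[opp] = "different_direction"
    same = ~opp
    cls[same & (np.abs(by) < np.abs(bo))] = "weaker_at_young"
    cls[same & (np.abs(by) > np.abs(bo))] = "stronger_at_young"
    out = cross_age_young[key].copy()
    out["beta_young"] = by
    out["beta_old"] = bo
    out["effect_class"] = cls
    counts = {c: int((cls == c).sum()) for c in EFFECT_CLASSES}
    n_split = counts["weaker_at_young"] + counts["stronger_at_young"]
    if n_split:
        z, p = prop_test_one_sample(counts["weaker_at_young"], n_split, 0.5)
    else:
        z, p = 0.0, 1.0
    summary = dict(counts=counts, n_same_direction=n_split, prop_z=z, prop_p=p)
    return out, summary
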