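"""Sample/probe QC, control-probe correction, deconvolution, residualization.

Turns raw beta matrices into the adjusted matrix every downstream scan
consumes: samples failing the detection-P gate or the paired-sample
concordance check are dropped, probes are filtered on annotation rules,
blood cell-type proportions are estimated by constrained projection onto
reference profiles, and each probe is residualized on the selected
control-probe principal components plus study covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .stats import PCSelection, pca_permutation_select, pearson_r

logger = logging.getLogger(__name__)

SAMPLE_REASONS = ("detection_fail", "pair_mixup")
PROBE_REASONS = ("sex_chrom", "multi_map", "snp_probe_panel", "snp_at_target_maf", "cph")


@dataclass
class QCReport:
    """Removed samples/probes with reason codes; reasons partition removals."""

    samples_removed: list = field(default_factory=list)  # (sample_id, reason)
    probes_removed: list = field(default_factory=list)   # (probe_id, reason)

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for _, reason in self.samples_removed + self.probes_removed:
            out[reason] = out.get(reason, 0) + 1
        return out

    def merged(self, other: "QCReport") -> "QCReport":
        return QCReport(
            samples_removed=self.samples_removed + other.samples_removed,
            probes_removed=self.probes_removed + other.probes_removed,
        )


@dataclass
class AdjustedMatrix:
    """Residual methylation after removing control PCs and covariates."""

    values: pd.DataFrame          # probes x samples
    regressors: list              # names of removed covariate columns
    n_control_pcs: int

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def sample_qc(
    detection_p: pd.DataFrame,
    p_threshold: float = 0.01,
    max_fail_fraction: float = 0.10,
) -> tuple[list, list, QCReport]:
    """Drop samples lacking signal in more than ``max_fail_fraction`` of probes.

    A probe fails in a sample when its detection p exceeds ``p_threshold``;
    the sample is removed only when its failing fraction strictly exceeds
    ``max_fail_fraction`` (a sample at exactly the boundary is kept).
    """
    if detection_p.size == 0:
        raise ValueError("empty detection-p matrix")
    vals = detection_p.to_numpy()
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("detection p-values must lie in [0, 1]")
    fail_frac = (vals > p_threshold).mean(axis=0)
    remove_mask = fail_frac > max_fail_fraction
    keep = [s for s, r in zip(detection_p.columns, remove_mask) if not r]
    remove = [s for s, r in zip(detection_p.columns, remove_mask) if r]
    report = QCReport(samples_removed=[(s, "detection_fail") for s in remove])
    return keep, remove, report


def pair_concordance_check(
    beta_snp_probes_t1: pd.DataFrame,
    beta_snp_probes_t2: pd.DataFrame,
    r_min: float = 0.9,
) -> pd.DataFrame:
    """Flag putative sample mix-ups from SNP-fingerprint probe betas.

    Both inputs are probes x pairs over the genotype-fingerprint probes;
    a pair whose Pearson r falls strictly below ``r_min`` is flagged.
    """
    if not beta_snp_probes_t1.index.equals(beta_snp_probes_t2.index):
        raise ValueError("timepoints must cover the same probe set")
    if len(beta_snp_probes_t1.index) < 10:
        raise ValueError("need at least 10 fingerprint probes")
    if not beta_snp_probes_t1.columns.equals(beta_snp_probes_t2.columns):
        raise ValueError("timepoints must cover the same pairs")
    rows = []
    for col in beta_snp_probes_t1.columns:
        r = pearson_r(beta_snp_probes_t1[col], beta_snp_probes_t2[col])
        rows.append((col, r, r < r_min))
    return pd.DataFrame(rows, columns=["pair", "r", "mixup"]).set_index("pair")


def probe_filter(
    manifest: pd.DataFrame,
    maf: pd.Series | None = None,
    maf_max: float = 0.10,
) -> tuple[list, QCReport]:
    """Annotation-based probe exclusion.

    Removes sex-chromosome probes, multi-mapping probes, the SNP-assay
    fingerprint panel, and probes with a SNP at the target site whose
    allele frequency strictly exceeds ``maf_max``. CpH probes are kept
    here (they are excluded later from enrichment backgrounds only).
    """
    if maf is None:
        maf = manifest["target_maf"]
    missing = maf.index.difference(manifest.index)
    if len(missing):
        raise KeyError(f"probes in MAF table missing from manifest: {list(missing)[:5]}")
    maf = maf.reindex(manifest.index).fillna(0.0)

    removed: list[tuple[str, str]] = []
    gone = pd.Series(False, index=manifest.index)
    for mask, reason in (
        (manifest["chrom"].isin(["chrX", "chrY"]), "sex_chrom"),
        (manifest["multi_map"].astype(bool), "multi_map"),
        (manifest["snp_panel"].astype(bool), "snp_probe_panel"),
        (maf > maf_max, "snp_at_target_maf"),
    ):
        newly = mask & ~gone
        removed.extend((p, reason) for p in manifest.index[newly])
        gone |= mask
    keep = list(manifest.index[~gone])
    return keep, QCReport(probes_removed=removed)


def deconvolve_celltypes(beta_sample, ref: pd.DataFrame) -> pd.Series:
    """Estimate cell-type proportions by constrained projection.

    Least squares of the sample's reference-probe betas on the cell-type
    profiles subject to non-negativity and sum <= 1, solved as NNLS on an
    augmented system with a slack cell absorbing 1 - sum(proportions).
    """
    y = np.asarray(beta_sample, dtype=float)
    A = ref.to_numpy(dtype=float).T  # probes x types
    n_probes, n_types = A.shape
    if n_probes < n_types:
        raise ValueError("need at least as many reference probes as cell types")
    if y.shape != (n_probes,):
        raise ValueError("sample vector must align to reference probes")
    lam = 1000.0
    A_aug = np.vstack(
        [np.hstack([A, np.zeros((n_probes, 1))]), lam * np.ones((1, n_types + 1))]
    )
    b_aug = np.concatenate([y, [lam]])
    sol, _ = nnls(A_aug, b_aug)
    return pd.Series(sol[:n_types], index=ref.index, name="proportion")


def deconvolve_matrix(beta: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame:
    """Per-sample deconvolution of a probes x samples matrix (aligned rows).

    Same constrained projection as :func:`deconvolve_celltypes`, but the
    augmented design is QR-reduced once, so each sample solves a tiny
    (k+1)-dimensional NNLS with an identical minimizer.
    """
    sub = beta.loc[ref.columns]
    A = ref.to_numpy(dtype=float).T
    n_probes, k = A.shape
    if n_probes < k:
        raise ValueError("need at least as many reference probes as cell types")
    lam = 1000.0
    A_aug = np.vstack([np.hstack([A, np.zeros((n_probes, 1))]),
                       lam * np.ones((1, k + 1))])
    Q, R = np.linalg.qr(A_aug)
    B = np.vstack([sub.to_numpy(dtype=float), lam * np.ones((1, sub.shape[1]))])
    rhs = Q.T @ B
    out = {
        s: pd.Series(nnls(R, rhs[:, j])[0][:k], index=ref.index)
        for j, s in enumerate(sub.columns)
    }
    return pd.DataFrame(out).T


def _design_from_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Numeric design columns; categoricals dummy-coded against a reference."""
    parts = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype.kind in "biufc":
            parts.append(s.astype(float).to_frame(col))
        else:
            dummies = pd.get_dummies(s.astype("category"), prefix=col, drop_first=True)
            parts.append(dummies.astype(float))
    return pd.concat(parts, axis=1)


def _check_collinear(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    with_icpt = np.column_stack([np.ones(len(arr)), arr])
    if np.linalg.matrix_rank(with_icpt) == with_icpt.shape[1]:
        return
    # name an offending pair for the error message
    Z = arr - arr.mean(axis=0)
    sd = Z.std(axis=0)
    const = np.where(sd == 0)[0]
    if len(const):
        raise ValueError(f"covariate '{X.columns[const[0]]}' is constant")
    C = np.corrcoef(Z.T)
    np.fill_diagonal(C, 0.0)
    i, j = np.unravel_index(np.nanargmax(np.abs(C)), C.shape)
    raise ValueError(
        f"collinear covariates: '{X.columns[i]}' and '{X.columns[j]}' "
        f"(|r| = {abs(C[i, j]):.6f})"
    )


def build_adjusted_matrix(
    beta: pd.DataFrame,
    control: pd.DataFrame | None,
    covariates: pd.DataFrame | None,
    n_perm: int = 10000,
    alpha: float = 1e-4,
    max_components: int = 10,
    random_state: int = 0,
    precomputed_pcs: pd.DataFrame | None = None,
) -> AdjustedMatrix:
    """Residualize each probe on selected control PCs plus covariates.

    ``control`` is control probes x samples (column-aligned with ``beta``);
    PC selection follows the permutation rule. ``covariates`` is a
    samples x covariates table (categoricals allowed); either input may
    be None to correct on the other alone. ``precomputed_pcs`` (samples x
    scores) bypasses re-running the permutation selection when the same
    control matrix feeds several adjustments.
    """
    samples = beta.columns
    blocks = []
    n_pcs = 0
    if precomputed_pcs is not None:
        n_pcs = precomputed_pcs.shape[1]
        if n_pcs:
            blocks.append(precomputed_pcs.reindex(samples))
    elif control is not None:
        if not control.columns.equals(samples):
            raise ValueError("control matrix samples must align with beta matrix")
        sel: PCSelection = pca_permutation_select(
            control.to_numpy().T, n_perm=n_perm, alpha=alpha,
            max_components=max_components, random_state=random_state,
        )
        n_pcs = sel.n_selected
        if n_pcs:
            blocks.append(
                pd.DataFrame(
                    sel.scores, index=samples,
                    columns=[f"control_pc{k + 1}" for k in range(n_pcs)],
                )
            )
    if covariates is not None:
        cov = covariates.reindex(samples)
        if cov.isna().any().any():
            raise ValueError("covariates incomplete for some samples")
        blocks.append(_design_from_covariates(cov))

    if blocks:
        X_df = pd.concat(blocks, axis=1)
        _check_collinear(X_df)
        X = np.column_stack([np.ones(len(samples)), X_df.to_numpy()])
        regressors = list(X_df.columns)
    else:
        X = np.ones((len(samples), 1))
        regressors = []

    Y = beta.to_numpy(dtype=float).T  # samples x probes
    coef = np.linalg.lstsq(X, Y, rcond=None)[0]
    resid = (Y - X @ coef).T
    values = pd.DataFrame(resid, index=beta.index, columns=samples)
    logger.info(
        "adjusted %d probes on %d regressors (%d control PCs)",
        len(beta.index), len(regressors), n_pcs,
    )
    return AdjustedMatrix(values=values, regressors=regressors, n_control_pcs=n_pcs)
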