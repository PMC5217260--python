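"""Exposure and disease association on the a-DMS universe.

Maternal smoking (binary, last-trimester definition) is tested against
the within-child methylation change; asthma status is tested against
cross-sectional methylation levels. Both use Huber robust regression
with the family's covariates, and BH FDR is computed within each
analysis family over the a-DMS set only.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .formatting import format_percent
from .preprocess import _design_from_covariates
from .stats import bh_fdr, huber_regress_many

logger = logging.getLogger(__name__)


def _scan_term(
    Y: pd.DataFrame, design_cols: pd.DataFrame, term: str
) -> pd.DataFrame:
    """Huber regression of every row of Y on the design; report one term."""
    X_df = _design_from_covariates(design_cols)
    X = np.column_stack([np.ones(len(X_df)), X_df.to_numpy()])
    fit = huber_regress_many(X, Y.to_numpy(dtype=float))
    j = 1 + list(X_df.columns).index(term)
    out = pd.DataFrame(
        {
            "probe_id": Y.index,
            "beta": fit.coefficients[:, j],
            "se": fit.standard_errors[:, j],
            "t": fit.t_statistics[:, j],
            "p": fit.two_sided_p[:, j],
            "n": fit.n_obs,
            "converged": fit.converged,
        }
    ).set_index("probe_id", drop=False)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def test_exposure_on_delta(
    delta: pd.DataFrame,
    exposure_design: pd.DataFrame,
    target_probes: list | None = None,
) -> pd.DataFrame:
    """Robust regression of methylation change on maternal smoking.

    ``delta`` is probes x children; ``exposure_design`` is children x
    covariates and must contain ``maternal_smoking`` plus maternal age,
    parity and maternal education. FDR is computed over the tested
    (a-DMS) probes only.
    """
    if target_probes is not None:
        delta = delta.loc[delta.index.intersection(pd.Index(target_probes))]
    design = exposure_design.reindex(delta.columns)
    if design.isna().any().any():
        bad = design.index[design.isna().any(axis=1)].tolist()
        raise ValueError(f"children with incomplete exposure covariates: {bad[:5]}")
    expo = design["maternal_smoking"].astype(int)
    if expo.nunique() < 2:
        raise ValueError("exposure has a single class; association is undefined")
    cols = design[["maternal_smoking", "maternal_age", "parity", "maternal_education"]]
    return _scan_term(delta, cols, "maternal_smoking")


def direction_tally(
    results: pd.DataFrame, p_threshold: float = 0.05
) -> tuple[int, int, int]:
    """Sign tally of nominally significant effects.

    Returns (n_negative, n_positive, n_total_nominal); exact zero
    estimates count as positive and are logged. The negative fraction in
    percent is ``format_percent(n_negative, n_total)``.
    """
    nominal = results[results["p"] < p_threshold]
    n_zero = int((nominal["beta"] == 0).sum())
    if n_zero:
        logger.warning("%d exact-zero effects tallied as positive", n_zero)
    n_neg = int((nominal["beta"] < 0).sum())
    n_pos = len(nominal) - n_neg
    return n_neg, n_pos, len(nominal)


def negative_fraction_percent(n_negative: int, n_total: int) -> float:
    return format_percent(n_negative, n_total) if n_total else 0.0


def test_disease_assoc(
    adjusted_levels: pd.DataFrame,
    disease_design: pd.DataFrame,
    target_probes: list | None = None,
) -> pd.DataFrame:
    """Robust regression of methylation level on disease status.

    ``adjusted_levels`` is probes x samples at one age (levels corrected
    for control-probe PCs); ``disease_design`` is samples x covariates
    and must contain ``asthma`` plus the study covariates and cell-type
    proportions. FDR is per analysis family (one age).
    """
    if target_probes is not None:
        adjusted_levels = adjusted_levels.loc[
            adjusted_levels.index.intersection(pd.Index(target_probes))
        ]
    design = disease_design.reindex(adjusted_levels.columns)
    if design.isna().any().any():
        bad = design.index[design.isna().any(axis=1)].tolist()
        raise ValueError(f"samples with incomplete disease covariates: {bad[:5]}")
    status = design["asthma"].astype(int)
    if status.nunique() < 2:
        raise ValueError("disease status has a single class; association is undefined")
    return _scan_term(adjusted_levels, design, "asthma")
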