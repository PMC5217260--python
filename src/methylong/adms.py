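"""Age-differential methylation site (a-DMS) detection and classification.

The paired design is handled by differencing: per child, the adjusted
methylation change (older minus younger) is tested per probe with a
Huber intercept-only robust location model. Probes genome-wide
significant in BOTH comparison sets are classified by sign agreement:
consistent decrease (da), consistent increase (ia), or inconsistent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formatting import format_percent
from .stats import bonferroni_threshold, huber_regress_many

DMS_CLASSES = ("da", "ia", "inconsistent", "not_significant")


@dataclass
class DMSSummary:
    """Counts and one-decimal percentages of the consistency classes."""

    n_significant: int
    n_da: int
    n_ia: int
    n_inconsistent: int
    pct_da: float
    pct_ia: float
    pct_inconsistent: float
    n_consistent: int
    threshold: float


def paired_differences(adjusted: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Probe x child matrix of within-child change (older - younger)."""
    cols = set(adjusted.columns)
    for row in design.itertuples():
        if row.sample_t1 not in cols or row.sample_t2 not in cols:
            raise ValueError(f"child '{row.child_id}' is missing a timepoint sample")
    d = (
        adjusted[design["sample_t2"]].to_numpy()
        - adjusted[design["sample_t1"]].to_numpy()
    )
    return pd.DataFrame(d, index=adjusted.index, columns=design["child_id"])


def test_age_dms(adjusted: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe robust location test of the within-child change.

    ``adjusted`` is the residualized probes x samples matrix covering one
    comparison set; ``design`` maps each child to its two samples. The
    effect is the robust mean change; p is two-sided on the intercept.
    """
    diffs = paired_differences(adjusted, design)
    n = diffs.shape[1]
    fit = huber_regress_many(np.ones((n, 1)), diffs.to_numpy())
    return pd.DataFrame(
        {
            "probe_id": diffs.index,
            "delta": fit.coefficients[:, 0],
            "se": fit.standard_errors[:, 0],
            "t": fit.t_statistics[:, 0],
            "p": fit.two_sided_p[:, 0],
            "n_pairs": n,
            "converged": fit.converged,
        }
    ).set_index("probe_id", drop=False)


def classify_consistency(
    results_young: pd.DataFrame,
    results_old: pd.DataFrame,
    n_tests: int,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, DMSSummary]:
    """Partition both-significant probes by direction agreement.

    ``n_tests`` is the size of the shared probe universe, which sets the
    Bonferroni threshold alpha / n_tests applied in each set.
    """
    if not results_young.index.equals(results_old.index):
        raise ValueError("comparison sets must share one probe universe")
    threshold = bonferroni_threshold(alpha, n_tests)
    dy = results_young["delta"].to_numpy()
    do = results_old["delta"].to_numpy()
    py = results_young["p"].to_numpy()
    po = results_old["p"].to_numpy()
    sig = (py < threshold) & (po < threshold)
    cls = np.full(len(dy), "not_significant", dtype=object)
    cls[sig & (dy < 0) & (do < 0)] = "da"
    cls[sig & (dy > 0) & (do > 0)] = "ia"
    cls[sig & (dy * do < 0)] = "inconsistent"
    records = pd.DataFrame(
        {
            "probe_id": results_young.index,
            "delta_young": dy,
            "p_young": py,
            "delta_old": do,
            "p_old": po,
            "class": cls,
        }
    ).set_index("probe_id", drop=False)
    summary = summarize_classes(
        int((cls == "da").sum()), int((cls == "ia").sum()),
        int((cls == "inconsistent").sum()), threshold,
    )
    return records, summary


def summarize_classes(n_da: int, n_ia: int, n_inconsistent: int,
                      threshold: float) -> DMSSummary:
    """Headline arithmetic: percentages are of the both-significant total."""
    n_sig = n_da + n_ia + n_inconsistent
    if n_sig:
        pcts = [format_percent(k, n_sig) for k in (n_da, n_ia, n_inconsistent)]
    else:
        pcts = [0.0, 0.0, 0.0]
    return DMSSummary(
        n_significant=n_sig,
        n_da=n_da,
        n_ia=n_ia,
        n_inconsistent=n_inconsistent,
        pct_da=pcts[0],
        pct_ia=pcts[1],
        pct_inconsistent=pcts[2],
        n_consistent=n_da + n_ia,
        threshold=threshold,
    )
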