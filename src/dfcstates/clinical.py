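"""Cohort description and clinical-correlation statistics.

Continuous demographics are compared with the pooled-variance two-sample t;
categorical ones with the Pearson chi-squared test (no Yates continuity
correction — expected counts are large in cohorts of this size; a flag
restores it).  Correlations between dynamic-network metrics and clinical
severity scores (e.g. JOA, NDI) use Pearson's r with a Student-t reference,
with Spearman available by flag.  No multiple-testing correction is applied
across clinical correlations; the number of tests is reported so users can
correct post hoc.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ClinicalCorrelation",
    "pooled_two_sample_t",
    "pooled_t_from_moments",
    "describe_cohort",
    "correlate_clinical",
]

CONTINUOUS_DEFAULT = ("age", "education_years")
PATIENT_ONLY = ("duration_months", "joa", "ndi")


@dataclasses.dataclass(frozen=True)
class ClinicalCorrelation:
    metric: str
    score: str
    r: float
    p: float
    n: int
    method: str


def pooled_two_sample_t(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pooled-variance two-sample t and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def pooled_t_from_moments(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple:
    """Pooled two-sample t from summary statistics (mean, SD, n per group)."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = (mean1 - mean2) / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def describe_cohort(
    meta: pd.DataFrame,
    continuous: Sequence[str] = CONTINUOUS_DEFAULT,
    yates: bool = False,
) -> pd.DataFrame:
    """Demographics table: per-variable group summaries, test statistic, p.

    Patient-only clinical scales (symptom duration, JOA, NDI) are summarised
    for the patient group without a test.  A warning flag marks chi-squared
    tests with a zero expected cell count as unreliable.
    """
    pat = meta[meta["group"] == "patient"]
    ctl = meta[meta["group"] == "control"]
    if len(pat) < 2 or len(ctl) < 2:
        raise ValueError("need at least 2 subjects per group")
    rows = []
    for var in continuous:
        t, p = pooled_two_sample_t(pat[var].dropna(), ctl[var].dropna())
        rows.append(
            {
                "variable": var,
                "patient": f"{pat[var].mean():.2f} ± {pat[var].std(ddof=1):.2f}",
                "control": f"{ctl[var].mean():.2f} ± {ctl[var].std(ddof=1):.2f}",
                "test": "two-sample t",
                "statistic": t,
                "p": p,
                "unreliable": False,
            }
        )
    # sex: chi-squared on the 2 x 2 contingency table
    tab = pd.crosstab(meta["group"], meta["sex"])
    expected = stats.contingency.expected_freq(tab.to_numpy())
    unreliable = bool((expected == 0).any())
    if unreliable:
        logger.warning("zero expected cell count; chi-squared unreliable")
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=yates)
    rows.append(
        {
            "variable": "sex",
            "patient": f"M {int(tab.loc['patient'].get('M', 0))} / F {int(tab.loc['patient'].get('F', 0))}",
            "control": f"M {int(tab.loc['control'].get('M', 0))} / F {int(tab.loc['control'].get('F', 0))}",
            "test": "chi-squared",
            "statistic": float(chi2),
            "p": float(p),
            "unreliable": unreliable,
        }
    )
    for var in PATIENT_ONLY:
        if var in meta.columns and pat[var].notna().any():
            rows.append(
                {
                    "variable": var,
                    "patient": f"{pat[var].mean():.2f} ± {pat[var].std(ddof=1):.2f}",
                    "control": "NA",
                    "test": "",
                    "statistic": np.nan,
                    "p": np.nan,
                    "unreliable": False,
                }
            )
    return pd.DataFrame(rows)


def correlate_clinical(
    metric: Sequence[float],
    scores: Sequence[float],
    metric_name: str = "metric",
    score_name: str = "score",
    method: str = "pearson",
) -> ClinicalCorrelation:
    """Correlation between a dynamic-network metric and a clinical score.

    Missing values are dropped pairwise; at least 3 complete pairs are
    required; zero variance in either vector is an error (the correlation
    is undefined).
    """
    x = np.asarray(metric, float)
    y = np.asarray(scores, float)
    if x.shape != y.shape:
        raise ValueError("metric and scores must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return ClinicalCorrelation(
        metric=metric_name, score=score_name, r=float(r), p=float(p),
        n=int(x.size), method=method,
    )
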