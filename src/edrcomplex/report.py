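"""Cohort-level report generation.

Builds the three report blocks of the analysis as JSON-serialisable dicts:

* descriptive — per-class descriptor counts/percentages with chi-square
  p-values (Pearson and likelihood-ratio side by side), homogeneous-subset
  letters, and the ApEn median [IQR] per class with Kruskal-Wallis and
  Dunn-Bonferroni results;
* factorial — the two-factor fixed-effects model of ApEn on consciousness
  and etiology (F and p per term);
* models — the ordinal model battery (coefficients, -2LL, Nagelkerke R²,
  likelihood-ratio tests).

Each report carries a ``schema_version`` and is checked against a minimal
key schema before being returned.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .groupstats import (
    ContingencyTable,
    chi_square_independence,
    dunn_posthoc,
    kruskal_wallis,
    pairwise_proportion_ztests,
    twoway_factorial,
)
from .ordinal import compare_models

__all__ = [
    "percentage",
    "descriptive_report",
    "factorial_report",
    "models_report",
    "validate_report",
    "REPORT_SCHEMAS",
]

SCHEMA_VERSION = 1

REPORT_SCHEMAS = {
    "descriptive": {"schema_version", "n_total", "groups", "descriptors", "apen"},
    "factorial": {"schema_version", "terms", "anova_type", "post_hoc"},
    "models": {"schema_version", "models", "null_minus2ll", "lrt"},
}


def percentage(count: float, total: float, decimals: int = 1) -> float:
    """Percentage rounded to the printed precision (e.g. 25 of 202 -> 12.4)."""
    if total <= 0:
        raise SchemaError("total must be positive")
    return round(100.0 * count / total, decimals)


def validate_report(report: dict, kind: str) -> dict:
    missing = REPORT_SCHEMAS[kind] - set(report)
    if missing:
        raise SchemaError(f"{kind} report is missing keys {sorted(missing)}")
    return report


def _median_iqr(x: np.ndarray) -> tuple[float, float]:
    q1, q2, q3 = np.percentile(x, [25, 50, 75])
    return float(q2), float(q3 - q1)


def descriptive_report(
    cohort: pd.DataFrame,
    descriptor_cols: Sequence[str] = ("frequency_theta", "apg", "reactivity"),
) -> dict:
    """Descriptive cohort table: descriptor prevalences and ApEn by class."""
    groups = [str(g) for g in cohort["group"].cat.categories]
    sizes = {g: int((cohort["group"] == g).sum()) for g in groups}
    n_total = int(len(cohort))

    descriptors = {}
    for col in descriptor_cols:
        present = [int(cohort.loc[cohort["group"] == g, col].sum()) for g in groups]
        totals = [sizes[g] for g in groups]
        table = ContingencyTable.from_presence(
            present, totals, col_labels=groups, descriptor=col
        )
        chi = chi_square_independence(table)
        pairwise = pairwise_proportion_ztests(table)
        descriptors[col] = {
            "present": dict(zip(groups, present)),
            "percent": {g: percentage(p, sizes[g]) for g, p in zip(groups, present)},
            "chi_square": chi.extra["variants"],
            "p_value": chi.p_value,
            "subset_letters": pairwise.attrs["subset_letters"],
            "pairwise": pairwise.drop(columns=["same_subset"]).to_dict("records"),
        }

    apen_block = {}
    for g in groups:
        med, iqr = _median_iqr(cohort.loc[cohort["group"] == g, "apen"].to_numpy())
        apen_block[g] = {"median": round(med, 3), "iqr": round(iqr, 3), "n": sizes[g]}
    kw = kruskal_wallis(cohort["apen"], cohort["group"].astype(str))
    dunn = dunn_posthoc(cohort["apen"], cohort["group"].astype(str))
    med_all, iqr_all = _median_iqr(cohort["apen"].to_numpy())

    report = {
        "schema_version": SCHEMA_VERSION,
        "n_total": n_total,
        "groups": sizes,
        "descriptors": descriptors,
        "apen": {
            "overall": {"median": round(med_all, 3), "iqr": round(iqr_all, 3)},
            "by_group": apen_block,
            "kruskal_wallis": {
                "H": kw.statistic,
                "df": kw.df,
                "p": kw.p_value,
                "mean_ranks": kw.extra["mean_ranks"],
            },
            "dunn_bonferroni": dunn.to_dict("records"),
        },
    }
    return validate_report(report, "descriptive")


def factorial_report(cohort: pd.DataFrame) -> dict:
    """Two-factor fixed-effects model of ApEn: consciousness x etiology."""
    res = twoway_factorial(
        cohort["apen"], cohort["group"].astype(str), cohort["etiology"].astype(str)
    )
    report = {
        "schema_version": SCHEMA_VERSION,
        "terms": res.extra["terms"],
        "anova_type": res.extra["anova_type"],
        "post_hoc": res.post_hoc.to_dict("records"),
    }
    return validate_report(report, "factorial")


def models_report(cohort: pd.DataFrame) -> dict:
    """Ordinal model battery: coefficients, -2LL, Nagelkerke R², LRTs."""
    comp = compare_models(cohort)
    models = {}
    for name, fit in comp.fits.items():
        models[name] = {
            "predictors": list(fit.predictors),
            "coefficients": fit.coefficients.round(6).to_dict("index"),
            "thresholds": [float(t) for t in fit.thresholds],
            "minus2ll": fit.minus2ll,
            "nagelkerke_r2": comp.r2[name],
            "n": fit.n,
            "converged": fit.converged,
            "warnings": fit.warnings_,
        }
    report = {
        "schema_version": SCHEMA_VERSION,
        "models": models,
        "null_minus2ll": comp.null_m2ll,
        "lrt": comp.lrt.to_dict("records"),
    }
    return validate_report(report, "models")
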