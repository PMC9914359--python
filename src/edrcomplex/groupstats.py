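"""Group-comparison battery for the cohort table.

Covers the non-parametric comparison of approximate entropy across ordered
consciousness classes (Kruskal-Wallis with Dunn-Bonferroni post hocs), the
association of binary EEG descriptors with class (chi-square, both Pearson
and likelihood-ratio variants, with Bonferroni-corrected pairwise
two-proportion z-tests and homogeneous-subset letters), and a two-factor
fixed-effects model of ApEn on consciousness and etiology with interaction
(Type-III tests).

Dunn's post hoc and the column-proportion z-tests are implemented here
directly (tie-corrected formulas); the omnibus tests delegate to scipy, the
factorial model to statsmodels OLS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as st

from .errors import InvalidArgumentError

__all__ = [
    "TestResult",
    "ContingencyTable",
    "kruskal_wallis",
    "dunn_posthoc",
    "chi_square_independence",
    "pairwise_proportion_ztests",
    "twoway_factorial",
]


@dataclass
class TestResult:
    """A test statistic with df, p-value and optional post-hoc table."""

    statistic: float
    df: float | tuple[float, ...]
    p_value: float
    method: str
    extra: dict = field(default_factory=dict)
    post_hoc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise InvalidArgumentError(f"p-value outside [0,1]: {self.p_value}")


@dataclass
class ContingencyTable:
    """Descriptor-by-class counts (rows: levels; cols: ordered classes)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InvalidArgumentError("counts must be a 2-D table")
        if np.any(self.counts < 0) or not np.allclose(
            self.counts, np.round(self.counts)
        ):
            raise InvalidArgumentError("counts must be non-negative integers")
        if np.any(self.counts.sum(axis=0) == 0) or np.any(self.counts.sum(axis=1) == 0):
            raise InvalidArgumentError("all row and column margins must be positive")

    @classmethod
    def from_presence(
        cls,
        present: Sequence[float],
        totals: Sequence[float],
        col_labels: Sequence[str] = ("UWS", "MCS", "EMCS"),
        descriptor: str = "descriptor",
    ) -> "ContingencyTable":
        present = np.asarray(present, dtype=float)
        totals = np.asarray(totals, dtype=float)
        return cls(
            counts=np.vstack([present, totals - present]),
            row_labels=(f"{descriptor}_present", f"{descriptor}_absent"),
            col_labels=tuple(col_labels),
        )


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks and the tie-correction sum T = sum(t^3 - t)."""
    ranks = st.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def kruskal_wallis(
    values: Sequence[float], groups: Sequence[str]
) -> TestResult:
    """Kruskal-Wallis H test of ApEn across consciousness classes.

    Delegates the tie-corrected H and its chi-square p-value to scipy and
    additionally reports per-group mean ranks (needed by Dunn's post hoc and
    for descriptive tables).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise InvalidArgumentError("every group must be non-empty")
    if np.ptp(values) == 0:  # all values identical: no between-group rank variance
        h, p = 0.0, 1.0
    else:
        h, p = st.kruskal(*samples)
    ranks, _ = _rank_with_ties(values)
    mean_ranks = {str(g): float(np.mean(ranks[groups == g])) for g in labels}
    return TestResult(
        statistic=float(h),
        df=len(labels) - 1,
        p_value=float(p),
        method="kruskal-wallis",
        extra={"mean_ranks": mean_ranks, "n": {str(g): int((groups == g).sum()) for g in labels}},
    )


def dunn_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise rank tests after Kruskal-Wallis, Bonferroni-corrected.

    z_ij = (Rbar_i - Rbar_j) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j) )
    with T = sum(t^3 - t) the tie correction.  Corrected p-values are raw p
    times the number of pairs, capped at 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = list(pd.unique(groups))
    n_total = len(values)
    ranks, tie_sum = _rank_with_ties(values)
    variance_base = n_total * (n_total + 1) / 12.0 - tie_sum / (12.0 * (n_total - 1))
    pairs = list(combinations(labels, 2))
    n_pairs = len(pairs)
    rows = []
    for a, b in pairs:
        na, nb = int((groups == a).sum()), int((groups == b).sum())
        if na == 0 or nb == 0:
            import warnings

            warnings.warn(f"pair ({a}, {b}) has an empty group; skipped")
            continue
        ra = float(np.mean(ranks[groups == a]))
        rb = float(np.mean(ranks[groups == b]))
        se = np.sqrt(variance_base * (1.0 / na + 1.0 / nb))
        z = 0.0 if se == 0 else (ra - rb) / se
        p_raw = 2 * st.norm.sf(abs(z))
        p_corr = min(1.0, p_raw * n_pairs) if correction == "bonferroni" else p_raw
        rows.append(
            {
                "pair": f"{a} vs {b}",
                "mean_rank_1": ra,
                "mean_rank_2": rb,
                "z": float(z),
                "p_raw": float(p_raw),
                "p_corrected": float(p_corr),
            }
        )
    return pd.DataFrame(rows)


def chi_square_independence(
    table: ContingencyTable, method: str = "likelihood_ratio"
) -> TestResult:
    """Chi-square test of descriptor-by-class independence.

    Both the Pearson X^2 and the likelihood-ratio G statistic are computed
    (no continuity correction); `method` selects which one populates the
    headline statistic/p, and the other is carried in ``extra`` so reports
    can show them side by side.
    """
    if method not in ("pearson", "likelihood_ratio"):
        raise InvalidArgumentError(f"unknown chi-square method {method!r}")
    obs = table.counts
    pearson = st.chi2_contingency(obs, correction=False)
    lrt = st.chi2_contingency(obs, correction=False, lambda_="log-likelihood")
    both = {
        "pearson": {"statistic": float(pearson.statistic), "p": float(pearson.pvalue)},
        "likelihood_ratio": {"statistic": float(lrt.statistic), "p": float(lrt.pvalue)},
    }
    pick = both[method]
    return TestResult(
        statistic=pick["statistic"],
        df=int(pearson.dof),
        p_value=pick["p"],
        method=f"chi-square ({method})",
        extra={"variants": both, "expected": np.asarray(pearson.expected_freq)},
    )


def _two_proportion_z(x1: float, n1: float, x2: float, n2: float) -> tuple[float, float]:
    """Pooled two-proportion z-test, no continuity correction."""
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * st.norm.sf(abs(z)))


def _compact_letters(labels: Sequence[str], same: np.ndarray) -> dict[str, str]:
    """Homogeneous-subset letters: one letter per maximal clique of the
    'not significantly different' graph; each column gets the letters of the
    cliques it belongs to."""
    k = len(labels)
    cliques: list[set[int]] = []
    # enumerate maximal cliques by brute force (k is tiny: the classes)
    from itertools import combinations as _comb

    for size in range(k, 0, -1):
        for cand in _comb(range(k), size):
            if all(same[i, j] for i, j in _comb(cand, 2)):
                cand_set = set(cand)
                if not any(cand_set <= c for c in cliques):
                    cliques.append(cand_set)
    letters = {lab: "" for lab in labels}
    for idx, clique in enumerate(sorted(cliques, key=lambda c: min(c))):
        letter = chr(ord("a") + idx)
        for i in clique:
            letters[labels[i]] += letter
    return letters


def pairwise_proportion_ztests(
    table: ContingencyTable, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Column-wise two-proportion z-tests with homogeneous-subset letters.

    For each pair of classes the presence rates are compared with a pooled
    z-test (no continuity correction); p-values are Bonferroni-corrected
    over the pairs.  Columns sharing a subset letter are not significantly
    different at the 5% level — the convention used in descriptive cohort
    tables.
    """
    if table.counts.shape[0] != 2:
        raise InvalidArgumentError("pairwise proportion tests need a 2xk table")
    present = table.counts[0]
    totals = table.counts.sum(axis=0)
    labels = list(table.col_labels)
    k = len(labels)
    pairs = list(combinations(range(k), 2))
    n_pairs = len(pairs)
    rows = []
    same = np.eye(k, dtype=bool)
    for i, j in pairs:
        z, p_raw = _two_proportion_z(present[i], totals[i], present[j], totals[j])
        p_corr = min(1.0, p_raw * n_pairs) if correction == "bonferroni" else p_raw
        not_different = p_corr >= 0.05
        same[i, j] = same[j, i] = not_different
        rows.append(
            {
                "pair": f"{labels[i]} vs {labels[j]}",
                "prop_1": present[i] / totals[i],
                "prop_2": present[j] / totals[j],
                "z": z,
                "p_raw": p_raw,
                "p_corrected": p_corr,
                "same_subset": bool(not_different),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["subset_letters"] = _compact_letters(labels, same)
    return out


def twoway_factorial(
    apen: Sequence[float],
    consciousness: Sequence[str],
    etiology: Sequence[str],
    posthoc_correction: str = "bonferroni",
) -> TestResult:
    """Two-factor fixed-effects model of ApEn with interaction (Type III).

    Fits ``apen ~ C(consciousness) * C(etiology)`` by OLS with sum-to-zero
    contrasts and reports Type-III F tests per term.  If some factor-level
    cell is empty the interaction is not estimable under sum coding, so the
    model falls back to Type-II tests with a logged warning.  Pairwise
    post-hoc contrasts within each factor (on marginal means, pooled
    residual variance) are Bonferroni-adjusted.
    """
    import warnings

    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {
            "apen": np.asarray(apen, dtype=float),
            "consciousness": np.asarray(consciousness, dtype=object),
            "etiology": np.asarray(etiology, dtype=object),
        }
    )
    if df.isna().any().any():
        raise InvalidArgumentError("every observation needs both factor labels")
    cells = df.groupby(["consciousness", "etiology"], sort=False).size()
    n_levels = df["consciousness"].nunique() * df["etiology"].nunique()
    anova_type = 3
    if len(cells) < n_levels:
        warnings.warn("empty factor cells: falling back to Type-II tests")
        anova_type = 2
    formula_typ3 = (
        "apen ~ C(consciousness, Sum) * C(etiology, Sum)"
        if anova_type == 3
        else "apen ~ C(consciousness) * C(etiology)"
    )
    fit = smf.ols(formula_typ3, data=df).fit()
    table = anova_lm(fit, typ=anova_type)

    def _term_row(name_contains: str) -> pd.Series:
        match = [i for i in table.index if name_contains in i]
        return table.loc[match[0]]

    inter = _term_row(":")
    terms = {}
    for label, key in [
        ("consciousness", "C(consciousness"),
        ("etiology", "C(etiology"),
    ]:
        row = table.loc[[i for i in table.index if i.startswith(key) and ":" not in i][0]]
        terms[label] = {"F": float(row["F"]), "p": float(row["PR(>F)"]), "df": float(row["df"])}
    terms["interaction"] = {
        "F": float(inter["F"]),
        "p": float(inter["PR(>F)"]),
        "df": float(inter["df"]),
    }

    # pairwise post hocs on marginal means with pooled residual variance
    resid_df = fit.df_resid
    s2 = float(fit.mse_resid)
    posthoc_rows = []
    for factor in ("consciousness", "etiology"):
        levels = list(pd.unique(df[factor]))
        n_pairs = len(levels) * (len(levels) - 1) // 2
        for a, b in combinations(levels, 2):
            xa = df.loc[df[factor] == a, "apen"]
            xb = df.loc[df[factor] == b, "apen"]
            se = np.sqrt(s2 * (1 / len(xa) + 1 / len(xb)))
            tstat = (xa.mean() - xb.mean()) / se
            p_raw = 2 * st.t.sf(abs(tstat), resid_df)
            p_corr = min(1.0, p_raw * n_pairs) if posthoc_correction == "bonferroni" else p_raw
            posthoc_rows.append(
                {
                    "factor": factor,
                    "pair": f"{a} vs {b}",
                    "diff": float(xa.mean() - xb.mean()),
                    "t": float(tstat),
                    "p_raw": float(p_raw),
                    "p_corrected": float(p_corr),
                }
            )

    return TestResult(
        statistic=terms["consciousness"]["F"],
        df=(terms["consciousness"]["df"], float(resid_df)),
        p_value=terms["consciousness"]["p"],
        method=f"two-way factorial (type {anova_type})",
        extra={"terms": terms, "anova_type": anova_type},
        post_hoc=pd.DataFrame(posthoc_rows),
    )
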