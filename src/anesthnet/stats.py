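"""Repeated-measures comparison of scalar indices across the five conditions.

The testing ladder mirrors common practice for small within-subject designs:
Shapiro-Wilk normality per condition; if every condition looks normal, a
one-way repeated-measures ANOVA with Mauchly's sphericity test and
Greenhouse-Geisser degree-of-freedom correction when sphericity is rejected;
otherwise the Friedman rank test. A significant omnibus is followed by all
pairwise contrasts (paired t-tests on the parametric branch, Wilcoxon
signed-rank on the rank branch), Bonferroni-corrected over the condition
pairs.

The RM-ANOVA, Mauchly and Greenhouse-Geisser computations are closed-form
matrix formulas on the subject x condition table, which keeps large
simulation studies (thousands of tables) cheap.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

log = logging.getLogger(__name__)


@dataclass
class TestReport:
    index_name: str
    normality_p: dict
    chosen_test: str  # "rm_anova" | "friedman"
    omnibus_stat: float
    omnibus_p: float
    sphericity_p: float = float("nan")
    gg_epsilon: float = float("nan")
    gg_applied: bool = False
    posthoc: dict = field(default_factory=dict)  # (a, b) -> (stat, p, p_bonf)
    stratum: dict = field(default_factory=dict)


def _rm_anova(values: np.ndarray) -> tuple[float, float, int, int]:
    """One-way repeated-measures ANOVA F, p and degrees of freedom."""
    n, k = values.shape
    grand = values.mean()
    cond_means = values.mean(axis=0)
    subj_means = values.mean(axis=1)
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_tot = ((values - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        raise ValueError("zero error variance in RM-ANOVA")
    f = ms_cond / ms_err
    return f, float(sst.f.sf(f, df1, df2)), df1, df2


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centered covariance."""
    k = values.shape[1]
    s = np.cov(values, rowvar=False)
    row = s.mean(axis=0, keepdims=True)
    centered = s - row - row.T + s.mean()
    num = np.trace(centered) ** 2
    den = (k - 1) * (centered**2).sum()
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def _mauchly(values: np.ndarray) -> float:
    """Mauchly's sphericity test p-value (chi-square approximation)."""
    n, k = values.shape
    if n <= k - 1:
        # covariance of contrasts singular; sphericity untestable
        return float("nan")
    # orthonormal contrast basis (Helmert)
    m = np.zeros((k - 1, k))
    for i in range(k - 1):
        m[i, : i + 1] = 1.0
        m[i, i + 1] = -(i + 1)
        m[i] /= np.linalg.norm(m[i])
    s = np.cov(values, rowvar=False)
    sd = m @ s @ m.T
    eig = np.linalg.eigvalsh(sd)
    eig = np.maximum(eig, 1e-300)
    p = k - 1
    w = float(np.prod(eig) / (eig.mean() ** p))
    df = p * (p + 1) // 2 - 1
    nd = n - 1
    d = 1.0 - (2 * p**2 + p + 2) / (6.0 * p * nd)
    chi2 = -nd * d * np.log(max(w, 1e-300))
    # Box's second-order chi-square series correction
    w2 = (
        (p + 2)
        * (p - 1)
        * (p - 2)
        * (2 * p**3 + 6 * p**2 + 3 * p + 2)
        / (288.0 * (nd * p * d) ** 2)
    )
    pval = sst.chi2.sf(chi2, df) + w2 * (
        sst.chi2.sf(chi2, df + 4) - sst.chi2.sf(chi2, df)
    )
    return float(min(max(pval, 0.0), 1.0))


def compare_conditions(
    values: np.ndarray | pd.DataFrame,
    condition_labels: tuple | None = None,
    alpha: float = 0.05,
    index_name: str = "",
    parametric_posthoc: bool | None = None,
) -> TestReport:
    """Run the full testing ladder on a subject x condition table.

    ``values`` is complete-case (no missing entries), one row per subject.
    Post-hoc contrasts are computed only when the omnibus test rejects at
    ``alpha``; the Bonferroni family is the set of condition pairs within
    this table.
    """
    if isinstance(values, pd.DataFrame):
        condition_labels = tuple(values.columns)
        values = values.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if condition_labels is None:
        condition_labels = tuple(f"C{i + 1}" for i in range(k))
    if n < 3:
        raise ValueError("at least 3 subjects are required")
    if np.isnan(values).any():
        raise ValueError("missing values are not allowed (complete-case)")
    for j, label in enumerate(condition_labels):
        if np.ptp(values[:, j]) == 0:
            raise ValueError(
                f"condition {label!r} has zero variance; test degenerate"
            )
    normality_p = {
        label: float(sst.shapiro(values[:, j]).pvalue)
        for j, label in enumerate(condition_labels)
    }
    any_non_normal = any(p < alpha for p in normality_p.values())
    report = TestReport(
        index_name=index_name,
        normality_p=normality_p,
        chosen_test="friedman" if any_non_normal else "rm_anova",
        omnibus_stat=float("nan"),
        omnibus_p=float("nan"),
    )
    if any_non_normal:
        stat, p = sst.friedmanchisquare(*(values[:, j] for j in range(k)))
        report.omnibus_stat, report.omnibus_p = float(stat), float(p)
    else:
        f, p, df1, df2 = _rm_anova(values)
        report.sphericity_p = _mauchly(values)
        report.gg_epsilon = _gg_epsilon(values)
        if np.isfinite(report.sphericity_p) and report.sphericity_p < alpha:
            report.gg_applied = True
            eps = report.gg_epsilon
            p = float(sst.f.sf(f, df1 * eps, df2 * eps))
        report.omnibus_stat, report.omnibus_p = float(f), float(p)
    if report.omnibus_p < alpha:
        pairs = list(itertools.combinations(range(k), 2))
        n_comp = len(pairs)
        use_t = (
            parametric_posthoc
            if parametric_posthoc is not None
            else not any_non_normal
        )
        for a, b in pairs:
            xa, xb = values[:, a], values[:, b]
            if use_t:
                stat, raw = sst.ttest_rel(xa, xb)
            else:
                try:
                    stat, raw = sst.wilcoxon(xa, xb)
                except ValueError:  # all-zero differences
                    stat, raw = 0.0, 1.0
            key = (condition_labels[a], condition_labels[b])
            report.posthoc[key] = (
                float(stat),
                float(raw),
                float(min(1.0, raw * n_comp)),
            )
    return report


def batch_compare(
    tidy: pd.DataFrame,
    value_col: str = "value",
    subject_col: str = "subject",
    condition_col: str = "condition",
    stratum_cols: tuple = ("index", "band", "roi"),
    alpha: float = 0.05,
    condition_order: tuple | None = None,
) -> list[TestReport]:
    """One ladder run per stratum of a long-format results table.

    Strata are the distinct combinations of ``stratum_cols`` present in the
    input (missing columns are ignored), enumerated in sorted order. Strata
    whose subject x condition table is incomplete or degenerate are skipped
    with a logged warning rather than failing the batch.
    """
    cols = [c for c in stratum_cols if c in tidy.columns]
    reports = []
    groups = tidy.groupby(cols, sort=True) if cols else [((), tidy)]
    for key, grp in groups:
        if not isinstance(key, tuple):
            key = (key,)
        table = grp.pivot_table(
            index=subject_col,
            columns=condition_col,
            values=value_col,
            aggfunc="mean",
        )
        if condition_order is not None:
            table = table.reindex(
                columns=[c for c in condition_order if c in table.columns]
            )
        if table.isna().any().any() or table.shape[0] < 3 or table.shape[1] < 2:
            log.warning("skipping incomplete stratum %s", dict(zip(cols, key)))
            continue
        try:
            report = compare_conditions(
                table, alpha=alpha, index_name="/".join(map(str, key))
            )
        except ValueError as exc:
            log.warning("skipping stratum %s: %s", dict(zip(cols, key)), exc)
            continue
        report.stratum = dict(zip(cols, key))
        reports.append(report)
    return reports


def reports_to_frame(reports: list[TestReport]) -> pd.DataFrame:
    """Long-format summary of a batch of test reports."""
    rows = []
    for r in reports:
        base = {
            "index": r.index_name,
            "test": r.chosen_test,
            "omnibus_stat": r.omnibus_stat,
            "omnibus_p": r.omnibus_p,
            "sphericity_p": r.sphericity_p,
            "gg_epsilon": r.gg_epsilon,
            "gg_applied": r.gg_applied,
        }
        base.update({f"stratum_{k}": v for k, v in r.stratum.items()})
        if r.posthoc:
            for (a, b), (stat, raw, bonf) in r.posthoc.items():
                rows.append(
                    {
                        **base,
                        "pair": f"{a}-{b}",
                        "pair_stat": stat,
                        "pair_p_raw": raw,
                        "pair_p_bonferroni": bonf,
                    }
                )
        else:
            rows.append({**base, "pair": ""})
    return pd.DataFrame(rows)
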