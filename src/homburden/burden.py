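"""Burden testing over homozygosity profiles, plus the cohort summary.

Two complementary approaches are used on each context x stratum cell:

* an *overall* burden test comparing per-sample rates between two
  phenotype groups — Student's t when both groups look normal by the
  D'Agostino-Pearson omnibus test (and are large enough for it),
  otherwise Mann-Whitney — with Benjamini-Hochberg adjustment across the
  panel of contexts tested together;
* a *relative* burden test that pools both groups, binarizes each sample
  at pooled mean + 1 SD ("above-1SD"), and sends the resulting 2x2 table
  to the exact association engine (two-sided Fisher p, conditional-MLE
  OR, exact 90% CI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import exact_assoc
from .io_model import (
    BENIGN_LB,
    CANCER,
    FEMALE,
    MALE,
    NDD,
    OTHER_GROUP,
    PATHOGENIC_LP,
    VUS,
    SampleRecord,
)

T_TEST = "t_test"
MANN_WHITNEY = "mann_whitney"

NORMALITY_ALPHA = 0.05
NORMALITY_MIN_N = 8  # validity floor of the omnibus normality test
EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class BurdenTestResult:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    test_used: str
    statistic: float
    p_raw: float
    direction: int  # sign of mean_a - mean_b
    context: str | None = None
    stratum: str | None = None
    p_adjusted: float | None = None


@dataclass(frozen=True)
class RelativeBurdenResult:
    group_a: str
    group_b: str
    threshold: float
    table: exact_assoc.Table2x2
    assoc: exact_assoc.AssociationResult
    context: str | None = None
    stratum: str | None = None
    degenerate: bool = False


def _clean(rates) -> np.ndarray:
    arr = np.asarray(rates, dtype=float)
    return arr[~np.isnan(arr)]


def _route_test(a: np.ndarray, b: np.ndarray) -> str:
    """T-test only when both groups are big enough for the omnibus
    normality test and both pass it; otherwise Mann-Whitney."""
    if len(a) < NORMALITY_MIN_N or len(b) < NORMALITY_MIN_N:
        return MANN_WHITNEY
    for grp in (a, b):
        if np.ptp(grp) == 0:  # constant group: trivially non-normal
            return MANN_WHITNEY
        if stats.normaltest(grp).pvalue <= NORMALITY_ALPHA:
            return MANN_WHITNEY
    return T_TEST


def overall_burden_test(
    rates_a,
    rates_b,
    group_a: str = "a",
    group_b: str = "b",
    context: str | None = None,
    stratum: str | None = None,
    force_test: str | None = None,
) -> BurdenTestResult:
    """Two-sided two-group comparison of per-sample homozygosity rates.

    NA rates are dropped per group. ``force_test`` overrides the
    normality routing (used for reproducing a known routing).
    """
    a, b = _clean(rates_a), _clean(rates_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 non-NA rates")
    direction = int(np.sign(np.mean(a) - np.mean(b)))

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return BurdenTestResult(group_a, group_b, len(a), len(b),
                                force_test or MANN_WHITNEY, float("nan"), 1.0,
                                0, context, stratum)

    test = force_test or _route_test(a, b)
    if test == T_TEST:
        res = stats.ttest_ind(a, b, equal_var=True)
    elif test == MANN_WHITNEY:
        method = (
            "exact"
            if max(len(a), len(b)) <= EXACT_MW_MAX_N and len(np.unique(pooled)) == len(pooled)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=True)
    else:
        raise ValueError(f"unknown test {test!r}")
    return BurdenTestResult(group_a, group_b, len(a), len(b), test,
                            float(res.statistic), float(res.pvalue),
                            direction, context, stratum)


def anova_screen(*groups) -> float:
    """Unadjusted one-way fixed-effects ANOVA p across >= 2 groups."""
    cleaned = [_clean(g) for g in groups]
    return float(stats.f_oneway(*cleaned).pvalue)


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (monotonicity enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def relative_burden_test(
    rates_a,
    rates_b,
    group_a: str = "a",
    group_b: str = "b",
    context: str | None = None,
    stratum: str | None = None,
    confidence: float = exact_assoc.DEFAULT_CONFIDENCE,
) -> RelativeBurdenResult:
    """Above-1SD relative burden: binarize at pooled mean + 1 sample SD
    (strictly above) and test the 2x2 with the exact engine."""
    a, b = _clean(rates_a), _clean(rates_b)
    if len(a) + len(b) < 3:
        raise ValueError("pooled n must be >= 3")
    pooled = np.concatenate([a, b])
    sd = float(np.std(pooled, ddof=1))
    mean = float(np.mean(pooled))
    if sd == 0:
        table = exact_assoc.Table2x2(0, len(a), 0, len(b))
        assoc = exact_assoc.AssociationResult(
            table, 1.0, 1.0, 0.0, float("inf"), confidence, True
        )
        return RelativeBurdenResult(group_a, group_b, mean, table, assoc,
                                    context, stratum, True)
    threshold = mean + sd
    hi_a, hi_b = int((a > threshold).sum()), int((b > threshold).sum())
    table = exact_assoc.Table2x2(hi_a, len(a) - hi_a, hi_b, len(b) - hi_b)
    assoc = exact_assoc.associate(table, confidence)
    return RelativeBurdenResult(group_a, group_b, threshold, table, assoc,
                                context, stratum, assoc.degenerate)


# ---------------------------------------------------------------------------
# group selection and panel runner
# ---------------------------------------------------------------------------

NON_NDD = "non_NDD"
NDD_ONLY = "NDD_only"
ASD_ONLY = "ASD_only"


def select_group(records: list[SampleRecord], label: str) -> list[str]:
    """Sample ids belonging to a named contrast group.

    ``non_NDD`` pools cancer and other; ``NDD_only``/``ASD_only`` drop
    cancer-comorbid cases, for contrasts against the cancer group.
    """
    preds = {
        NDD: lambda r: r.is_ndd,
        "ASD": lambda r: r.is_asd,
        CANCER: lambda r: r.has_cancer and not r.is_ndd,
        OTHER_GROUP: lambda r: r.groups == frozenset({OTHER_GROUP}),
        NON_NDD: lambda r: not r.is_ndd,
        NDD_ONLY: lambda r: r.is_ndd and not r.has_cancer,
        ASD_ONLY: lambda r: r.is_asd and not r.has_cancer,
    }
    if label not in preds:
        raise ValueError(f"unknown group label {label!r}")
    return [r.id for r in records if preds[label](r)]


def _rates_for(profiles: pd.DataFrame, ids, context: str, stratum: str) -> np.ndarray:
    sub = profiles[
        (profiles["context"] == context)
        & (profiles["stratum"] == stratum)
        & (profiles["sample_id"].isin(set(ids)))
    ]
    return sub["rate"].to_numpy()


def run_burden_panel(
    profiles: pd.DataFrame,
    records: list[SampleRecord],
    group_a: str,
    group_b: str,
    contexts: list[str],
    stratum: str,
) -> pd.DataFrame:
    """Overall + relative burden tests for one contrast over a context
    panel; BH adjustment spans the panel (the comparison family)."""
    ids_a = select_group(records, group_a)
    ids_b = select_group(records, group_b)
    rows = []
    for context in contexts:
        ra = _rates_for(profiles, ids_a, context, stratum)
        rb = _rates_for(profiles, ids_b, context, stratum)
        overall = overall_burden_test(ra, rb, group_a, group_b, context, stratum)
        rel = relative_burden_test(ra, rb, group_a, group_b, context, stratum)
        rows.append(
            {
                "context": context,
                "stratum": stratum,
                "group_a": group_a,
                "group_b": group_b,
                "n_a": overall.n_a,
                "n_b": overall.n_b,
                "test_used": overall.test_used,
                "statistic": overall.statistic,
                "p_raw": overall.p_raw,
                "direction": overall.direction,
                "rel_threshold": rel.threshold,
                "rel_table": f"{rel.table.a},{rel.table.b}|{rel.table.c},{rel.table.d}",
                "rel_or": rel.assoc.or_cmle,
                "rel_ci_low": rel.assoc.ci_low,
                "rel_ci_high": rel.assoc.ci_high,
                "rel_p": rel.assoc.p_two_sided,
                "rel_degenerate": rel.degenerate,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(out.columns.get_loc("p_raw") + 1, "p_adjusted", adjust_bh(out["p_raw"]))
    return out


# ---------------------------------------------------------------------------
# cohort summary (demographics table)
# ---------------------------------------------------------------------------

SUMMARY_GROUPS = (NDD, "ASD", CANCER, OTHER_GROUP)


def cohort_summary(records: list[SampleRecord]) -> pd.DataFrame:
    """Per-group demographics: n, sex counts/percentages, variant-class
    counts/percentages (integer percent, denominator = group n).

    ASD is reported as a subset of NDD, so group columns do not sum to
    the cohort total; the cohort total is NDD + CANCER + OTHER.
    """

    def pct(k: int, n: int) -> float:
        return float(round(100 * k / n)) if n else float("nan")

    rows = {}
    for label in SUMMARY_GROUPS:
        members = [r for r in records if r.id in set(select_group(records, label))]
        n = len(members)
        male = sum(r.sex == MALE for r in members)
        female = sum(r.sex == FEMALE for r in members)
        classes = {c: sum(r.variant_class == c for r in members)
                   for c in (PATHOGENIC_LP, BENIGN_LB, VUS)}
        rows[label] = {
            "n": n,
            "male_n": male,
            "male_pct": pct(male, n),
            "female_n": female,
            "female_pct": pct(female, n),
            "pathogenic_lp_n": classes[PATHOGENIC_LP],
            "pathogenic_lp_pct": pct(classes[PATHOGENIC_LP], n),
            "benign_lb_n": classes[BENIGN_LB],
            "benign_lb_pct": pct(classes[BENIGN_LB], n),
            "vus_n": classes[VUS],
            "vus_pct": pct(classes[VUS], n),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
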