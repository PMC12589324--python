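"""Cohort statistics: normality-gated comparisons and irAE associations.

The battery mirrors common practice in exploratory clinical PET studies:

* paired pre/post comparisons use a paired t-test when a Shapiro–Wilk test
  on the paired differences does not reject normality (α = 0.05), and a
  two-sided Wilcoxon signed-rank test otherwise;
* independent two-group comparisons use Student's equal-variance t-test when
  Shapiro–Wilk rejects in neither group, and a two-sided Mann–Whitney U test
  otherwise;
* 2×2 categorical associations use Fisher's exact test when any expected
  cell count is below 5 and the chi-square test otherwise, reporting the
  sample odds ratio (a·d)/(b·c) with the Haldane–Anscombe 0.5 correction
  applied only when a zero in b or c would make the ratio undefined;
* the continuous↔categorical bridge dichotomizes per-patient Δ-uptake at the
  cohort median (strictly greater = "increased"; ties counted and logged)
  and feeds the resulting 2×2 table to the categorical machinery.

Every result records which test the gate selected — the gate decision is an
analysis output, not a hidden detail.  P-values are reported raw; an
optional Benjamini–Hochberg column can be added to report tables but is off
by default, matching the exploratory framing of this kind of study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats.contingency import odds_ratio as _conditional_odds_ratio

__all__ = [
    "PatientRecord",
    "TestResult",
    "AssociationResult",
    "ReportConfig",
    "AE_LABELS",
    "THYROID_SUBTYPES",
    "paired_compare",
    "group_compare",
    "categorical_assoc",
    "median_split_association",
    "lab_compare",
    "contingency_compare",
    "build_cohort_report",
]

#: Adverse-event labels tracked per patient (0/1 columns in the clinical CSV).
AE_LABELS = (
    "thyroid_related",
    "hypothyroidism",
    "hyperthyroidism",
    "thyroiditis",
    "hepatitis",
    "colitis",
)

#: Labels implying the thyroid_related composite.
THYROID_SUBTYPES = ("hypothyroidism", "hyperthyroidism", "thyroiditis")


@dataclass(frozen=True)
class PatientRecord:
    """Clinical covariates and adverse-event labels for one patient."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    cancer_type: str  # "lung" | "melanoma" | "lymphoma"
    ici_drug: str
    ici_class: str  # "PD-1" | "PD-L1" | "CTLA-4" | "combination"
    adverse_events: frozenset = frozenset()
    scan_interval_months: float = float("nan")
    ft3_pre: float | None = None
    ft3_post: float | None = None
    ft4_pre: float | None = None
    ft4_post: float | None = None

    def __post_init__(self) -> None:
        ae = set(self.adverse_events)
        unknown = ae - set(AE_LABELS) - {"none"}
        if unknown:
            raise ValueError(f"unknown adverse-event labels: {sorted(unknown)}")
        if "none" in ae and len(ae) > 1:
            raise ValueError("'none' is mutually exclusive with other labels")
        if any(s in ae for s in THYROID_SUBTYPES) and "thyroid_related" not in ae:
            raise ValueError("thyroid subtypes imply the thyroid_related composite")
        object.__setattr__(self, "adverse_events", frozenset(ae))


@dataclass
class TestResult:
    """Outcome of one hypothesis test, including the gate decision."""

    test_name: str  # paired_t | wilcoxon_signed_rank | student_t | mann_whitney_u | chi_square_rxc | none
    statistic: float
    p_value: float
    n: int
    n2: int | None = None
    normality_gate: bool | None = None
    shapiro_p: float | None = None
    shapiro_p2: float | None = None
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if not self.degenerate and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


@dataclass
class AssociationResult:
    """A 2×2 association: table, odds ratio, p-value and test identity."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    test_used: str  # "fisher_exact" | "chi_square"
    split_rule: str = ""
    tie_count: int = 0
    haldane_corrected: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2) or (self.table < 0).any():
            raise ValueError("table must be 2×2 with nonnegative counts")
        if self.odds_ratio < 0:
            raise ValueError("odds ratio must be nonnegative")


def _shapiro_p(x: np.ndarray) -> float:
    """Shapiro–Wilk p-value; constant input counts as a normality rejection
    (SW is undefined there and a constant sample carries no distributional
    evidence for the parametric branch)."""
    if np.ptp(x) == 0:
        return 0.0
    return float(sps.shapiro(x).pvalue)


def paired_compare(
    pre: Sequence[float], post: Sequence[float], alpha_shapiro: float = 0.05
) -> TestResult:
    """Paired pre/post comparison with a Shapiro–Wilk gate on the differences.

    Gate not rejected → paired t-test; rejected → two-sided Wilcoxon
    signed-rank.  Zero-variance differences (including the all-zero case) are
    flagged degenerate: no p-value is meaningful there.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    n = pre.size
    if n < 3:
        raise ValueError("paired comparison needs at least 3 complete pairs")
    d = post - pre
    if np.ptp(d) == 0:
        return TestResult(
            test_name="none",
            statistic=float("nan"),
            p_value=float("nan"),
            n=n,
            degenerate=True,
            note="zero-variance differences"
            + ("" if d[0] else " (pre == post)"),
        )
    sw = _shapiro_p(d)
    gate = sw > alpha_shapiro
    if gate:
        res = sps.ttest_rel(post, pre)
        name = "paired_t"
    else:
        res = sps.wilcoxon(post, pre)
        name = "wilcoxon_signed_rank"
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=n,
        normality_gate=gate,
        shapiro_p=sw,
    )


def group_compare(
    a: Sequence[float], b: Sequence[float], alpha_shapiro: float = 0.05
) -> TestResult:
    """Independent two-group comparison with per-group Shapiro–Wilk gates.

    Neither group rejected → Student's equal-variance t-test; otherwise a
    two-sided Mann–Whitney U test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if np.ptp(np.concatenate([a, b])) == 0:
        return TestResult(
            test_name="none",
            statistic=float("nan"),
            p_value=float("nan"),
            n=a.size,
            n2=b.size,
            degenerate=True,
            note="all observations identical",
        )
    sw_a, sw_b = _shapiro_p(a), _shapiro_p(b)
    gate = (sw_a > alpha_shapiro) and (sw_b > alpha_shapiro)
    if gate:
        res = sps.ttest_ind(a, b, equal_var=True)
        name = "student_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    return TestResult(
        test_name=name,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=a.size,
        n2=b.size,
        normality_gate=gate,
        shapiro_p=sw_a,
        shapiro_p2=sw_b,
    )


def _sample_odds_ratio(table: np.ndarray) -> tuple[float, bool]:
    a, b, c, d = (float(v) for v in table.ravel())
    if b == 0 or c == 0:
        # Haldane–Anscombe: +0.5 to every cell, only when the plain ratio
        # would divide by zero.
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)), True
    return (a * d) / (b * c), False


def categorical_assoc(
    table,
    or_estimator: str = "sample",
    split_rule: str = "",
    tie_count: int = 0,
    test: str = "auto",
) -> AssociationResult:
    """Test a 2×2 contingency table and report an odds ratio.

    With ``test="auto"``: Fisher's exact test (two-sided) when any expected
    cell count is < 5, otherwise the chi-square test (with continuity
    correction, the scipy default for 2×2); ``"fisher"``/``"chi_square"``
    force a branch.  ``or_estimator``: ``"sample"`` for (a·d)/(b·c), or
    ``"conditional_mle"`` for the conditional maximum-likelihood estimate
    underlying Fisher's exact framework.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2×2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("counts must be integers")
    t = t.astype(np.int64)
    total = int(t.sum())
    if total == 0 or (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        orx, hal = _sample_odds_ratio(t)
        return AssociationResult(
            table=t,
            odds_ratio=orx,
            p_value=1.0,
            test_used="fisher_exact",
            split_rule=split_rule,
            tie_count=tie_count,
            haldane_corrected=hal,
            degenerate=True,
        )
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if test == "auto":
        test = "fisher" if (expected < 5).any() else "chi_square"
    if test == "fisher":
        _, p = sps.fisher_exact(t, alternative="two-sided")
        test_used = "fisher_exact"
    elif test == "chi_square":
        _, p, _, _ = sps.chi2_contingency(t)
        test_used = "chi_square"
    else:
        raise ValueError(f"unknown test {test!r}")
    if or_estimator == "sample":
        orx, hal = _sample_odds_ratio(t)
    elif or_estimator == "conditional_mle":
        orx, hal = float(_conditional_odds_ratio(t).statistic), False
    else:
        raise ValueError(f"unknown or_estimator {or_estimator!r}")
    return AssociationResult(
        table=t,
        odds_ratio=orx,
        p_value=float(p),
        test_used=test_used,
        split_rule=split_rule,
        tie_count=tie_count,
        haldane_corrected=hal,
    )


def median_split_association(
    deltas: Sequence[float],
    labels: Sequence[int],
    or_estimator: str = "sample",
    split: str = "median",
) -> AssociationResult:
    """Associate dichotomized Δ-uptake with a binary adverse-event label.

    ``split="median"`` labels a patient "increased" when their Δ is strictly
    above the cohort median (ties fall in the non-increased half and are
    counted); ``split="zero"`` uses Δ > 0 instead.  The resulting table

        rows    = increased / not increased
        columns = AE / no AE

    is passed to :func:`categorical_assoc`.
    """
    deltas = np.asarray(deltas, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if deltas.shape != labels.shape:
        raise ValueError("deltas and labels must align")
    if deltas.size < 4:
        raise ValueError("median-split association needs at least 4 patients")
    if labels.all() or not labels.any():
        raise ValueError("need at least one patient in each label class")
    if split == "median":
        threshold = float(np.median(deltas))
        rule = f"delta > cohort median ({threshold:.6g})"
    elif split == "zero":
        threshold = 0.0
        rule = "delta > 0"
    else:
        raise ValueError(f"unknown split {split!r}")
    if np.ptp(deltas) == 0:
        return AssociationResult(
            table=np.zeros((2, 2), dtype=np.int64),
            odds_ratio=1.0,
            p_value=1.0,
            test_used="fisher_exact",
            split_rule=rule + " [degenerate: all deltas identical]",
            tie_count=int(deltas.size),
            degenerate=True,
        )
    increased = deltas > threshold
    ties = int(np.sum(deltas == threshold))
    table = np.array(
        [
            [np.sum(increased & labels), np.sum(increased & ~labels)],
            [np.sum(~increased & labels), np.sum(~increased & ~labels)],
        ],
        dtype=np.int64,
    )
    return categorical_assoc(
        table, or_estimator=or_estimator, split_rule=rule, tie_count=ties
    )


def lab_compare(
    pre_labs: Sequence[float], post_labs: Sequence[float], alpha_shapiro: float = 0.05
) -> TestResult:
    """Paired comparison of laboratory values on complete cases only.

    Pairs with a missing value on either side are dropped; the reported ``n``
    is the number of complete pairs actually tested.  Fewer than 3 complete
    pairs yields an insufficient-data flag instead of a test.
    """
    pre = np.asarray(pre_labs, dtype=float)
    post = np.asarray(post_labs, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post labs must align")
    complete = ~(np.isnan(pre) | np.isnan(post))
    n = int(complete.sum())
    if n < 3:
        return TestResult(
            test_name="none",
            statistic=float("nan"),
            p_value=float("nan"),
            n=n,
            degenerate=True,
            note="insufficient complete lab pairs",
        )
    res = paired_compare(pre[complete], post[complete], alpha_shapiro=alpha_shapiro)
    res.note = (res.note + " complete-case analysis").strip()
    return res


def contingency_compare(groups: Sequence, values: Sequence) -> TestResult | AssociationResult:
    """Group×category association for the clinical-characteristics table.

    A 2×2 cross-tabulation goes through :func:`categorical_assoc`; larger
    r×c tables use the chi-square test of independence.
    """
    ct = pd.crosstab(pd.Series(groups), pd.Series(values))
    if ct.shape == (2, 2):
        return categorical_assoc(ct.to_numpy())
    if min(ct.shape) < 2:
        return TestResult(
            test_name="none",
            statistic=float("nan"),
            p_value=float("nan"),
            n=int(ct.to_numpy().sum()),
            degenerate=True,
            note="variable constant within the cohort",
        )
    chi2, p, _, _ = sps.chi2_contingency(ct.to_numpy())
    return TestResult(
        test_name="chi_square_rxc",
        statistic=float(chi2),
        p_value=float(p),
        n=int(ct.to_numpy().sum()),
    )


# ---------------------------------------------------------------------------
# cohort report


@dataclass
class ReportConfig:
    """Tunable analysis parameters, all surfaced in the report header."""

    alpha_shapiro: float = 0.05
    split_statistic: str = "delta_suv_max"  # or "delta_suv_mean"
    split: str = "median"  # or "zero"
    or_estimator: str = "sample"  # or "conditional_mle"
    fdr_adjust: bool = False
    group_variable: str = "hypothyroidism"


def _maybe_fdr(df: pd.DataFrame, enabled: bool) -> pd.DataFrame:
    if not enabled or df.empty:
        return df
    mask = df["p_value"].notna()
    adj = np.full(len(df), np.nan)
    if mask.any():
        adj[mask.to_numpy()] = sps.false_discovery_control(
            df.loc[mask, "p_value"].to_numpy(), method="bh"
        )
    df = df.copy()
    df["p_adjusted_bh"] = adj
    return df


def _paired_vectors(measurements: pd.DataFrame, organ: str, column: str):
    sub = measurements[
        (measurements["organ"] == organ) & (~measurements["empty_flag"].astype(bool))
    ]
    wide = sub.pivot_table(
        index="patient_id", columns="timepoint", values=column, aggfunc="first"
    )
    if "pre" not in wide.columns or "post" not in wide.columns:
        return None
    wide = wide.dropna(subset=["pre", "post"])
    return wide["pre"].to_numpy(), wide["post"].to_numpy()


def _result_row(res: TestResult) -> dict:
    return {
        "test_name": res.test_name,
        "test_statistic": res.statistic,
        "p_value": res.p_value,
        "normality_gate": res.normality_gate,
        "shapiro_p": res.shapiro_p,
        "degenerate": res.degenerate,
        "note": res.note,
    }


def build_cohort_report(
    records: pd.DataFrame,
    measurements: pd.DataFrame,
    deltas: pd.DataFrame,
    config: ReportConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the full cohort analysis as a dictionary of tidy tables.

    Sections
    --------
    ``organ_paired``
        Per organ × statistic (SUVmax, SUVmean, plus the spleen-to-liver
        SUVmean ratio): pre/post means, mean Δ, fraction of patients with
        Δ > 0, gated paired test.
    ``ae_group``
        Per adverse-event label × organ × Δ-statistic: gated two-group
        comparison of Δ between labelled and unlabelled patients.
    ``median_split``
        Per adverse-event label × organ: dichotomized-Δ association with the
        label (split statistic and rule from the config).
    ``clinical``
        Characteristics table split by ``config.group_variable``: continuous
        variables gated t / Mann–Whitney, categorical variables Fisher /
        chi-square.

    Inconsistent patient keys are reported in a ``warnings`` table, never
    fatal; tests on subsets that are too small are emitted as flagged rows.
    """
    config = config or ReportConfig()
    organs = sorted(measurements["organ"].unique()) if len(measurements) else []
    warnings: list[dict] = []

    rec_ids = set(records["patient_id"]) if len(records) else set()
    meas_ids = set(measurements["patient_id"]) if len(measurements) else set()
    for pid in sorted(meas_ids - rec_ids):
        warnings.append({"context": "keys", "message": f"measurements for unknown patient {pid}"})
    for pid in sorted(rec_ids - meas_ids):
        warnings.append({"context": "keys", "message": f"patient {pid} has no measurements"})

    # -- (i) per-organ paired pre-vs-post ----------------------------------
    paired_rows = []
    targets = [(organ, stat) for organ in organs for stat in ("suv_max", "suv_mean")]
    for organ, stat in targets:
        vecs = _paired_vectors(measurements, organ, stat)
        if vecs is None or len(vecs[0]) < 3:
            paired_rows.append(
                {
                    "organ": organ,
                    "statistic": stat,
                    "n": 0 if vecs is None else len(vecs[0]),
                    "degenerate": True,
                    "note": "insufficient paired data",
                }
            )
            continue
        pre, post = vecs
        res = paired_compare(pre, post, alpha_shapiro=config.alpha_shapiro)
        paired_rows.append(
            {
                "organ": organ,
                "statistic": stat,
                "n": len(pre),
                "mean_pre": float(pre.mean()),
                "mean_post": float(post.mean()),
                "mean_delta": float((post - pre).mean()),
                "sd_delta": float((post - pre).std(ddof=1)),
                "pct_increased": float(100.0 * np.mean((post - pre) > 0)),
                **_result_row(res),
            }
        )
    # spleen-to-liver SUVmean ratio as an extra paired marker
    ratio = _spleen_liver_paired(measurements)
    if ratio is not None:
        pre, post = ratio
        if len(pre) >= 3:
            res = paired_compare(pre, post, alpha_shapiro=config.alpha_shapiro)
            paired_rows.append(
                {
                    "organ": "spleen_liver_ratio",
                    "statistic": "suv_mean_ratio",
                    "n": len(pre),
                    "mean_pre": float(pre.mean()),
                    "mean_post": float(post.mean()),
                    "mean_delta": float((post - pre).mean()),
                    "sd_delta": float((post - pre).std(ddof=1)),
                    "pct_increased": float(100.0 * np.mean((post - pre) > 0)),
                    **_result_row(res),
                }
            )
    organ_paired = _maybe_fdr(
        pd.DataFrame(paired_rows), config.fdr_adjust
    )

    # -- (ii) Δ-uptake group comparisons per AE label ----------------------
    group_rows = []
    merged = deltas.merge(records, on="patient_id", how="inner") if len(deltas) else pd.DataFrame()
    for label in AE_LABELS:
        if label not in getattr(merged, "columns", []):
            continue
        for organ in organs:
            sub = merged[merged["organ"] == organ]
            for stat in ("delta_suv_max", "delta_suv_mean"):
                pos = sub.loc[sub[label] == 1, stat].to_numpy()
                neg = sub.loc[sub[label] == 0, stat].to_numpy()
                base = {
                    "ae_label": label,
                    "organ": organ,
                    "statistic": stat,
                    "n_pos": len(pos),
                    "n_neg": len(neg),
                }
                if len(pos) < 3 or len(neg) < 3:
                    group_rows.append({**base, "degenerate": True, "note": "group too small"})
                    continue
                res = group_compare(pos, neg, alpha_shapiro=config.alpha_shapiro)
                group_rows.append(
                    {
                        **base,
                        "mean_pos": float(pos.mean()),
                        "mean_neg": float(neg.mean()),
                        **_result_row(res),
                    }
                )
    ae_group = _maybe_fdr(pd.DataFrame(group_rows), config.fdr_adjust)

    # -- (iii) median-split associations -----------------------------------
    split_rows = []
    for label in AE_LABELS:
        if label not in getattr(merged, "columns", []):
            continue
        for organ in organs:
            sub = merged[merged["organ"] == organ]
            d = sub[config.split_statistic].to_numpy()
            y = sub[label].to_numpy().astype(bool)
            base = {"ae_label": label, "organ": organ, "split_statistic": config.split_statistic}
            if len(d) < 4 or y.all() or not y.any():
                split_rows.append({**base, "degenerate": True, "note": "label class empty or cohort too small"})
                continue
            res = median_split_association(
                d, y, or_estimator=config.or_estimator, split=config.split
            )
            a, b, c, dd = res.table.ravel()
            split_rows.append(
                {
                    **base,
                    "n": len(d),
                    "table_a": int(a),
                    "table_b": int(b),
                    "table_c": int(c),
                    "table_d": int(dd),
                    "odds_ratio": res.odds_ratio,
                    "p_value": res.p_value,
                    "test_used": res.test_used,
                    "split_rule": res.split_rule,
                    "tie_count": res.tie_count,
                    "haldane_corrected": res.haldane_corrected,
                    "degenerate": res.degenerate,
                }
            )
    median_split = pd.DataFrame(split_rows)

    # -- (iv) clinical characteristics -------------------------------------
    clinical_rows = []
    gv = config.group_variable
    if len(records) and gv in records.columns and records[gv].nunique() == 2:
        grp = records[gv].to_numpy()
        for var in ("age", "scan_interval_months"):
            if var not in records.columns:
                continue
            a = records.loc[records[gv] == 1, var].dropna().to_numpy()
            b = records.loc[records[gv] == 0, var].dropna().to_numpy()
            base = {"variable": var, "kind": "continuous"}
            if len(a) < 3 or len(b) < 3:
                clinical_rows.append({**base, "degenerate": True, "note": "group too small"})
                continue
            res = group_compare(a, b, alpha_shapiro=config.alpha_shapiro)
            clinical_rows.append(
                {**base, "n_pos": len(a), "n_neg": len(b),
                 "mean_pos": float(np.mean(a)), "mean_neg": float(np.mean(b)),
                 **_result_row(res)}
            )
        cat_vars = ["sex", "cancer_type", "ici_class"] + [
            l for l in AE_LABELS if l != gv and l in records.columns
        ]
        for var in cat_vars:
            if var not in records.columns:
                continue
            res = contingency_compare(grp, records[var].to_numpy())
            if isinstance(res, AssociationResult):
                clinical_rows.append(
                    {
                        "variable": var,
                        "kind": "categorical",
                        "test_name": res.test_used,
                        "p_value": res.p_value,
                        "odds_ratio": res.odds_ratio,
                        "degenerate": res.degenerate,
                    }
                )
            else:
                clinical_rows.append(
                    {"variable": var, "kind": "categorical", **_result_row(res)}
                )
    elif len(records):
        warnings.append(
            {"context": "clinical", "message": f"group variable {gv!r} absent or not binary"}
        )
    clinical = pd.DataFrame(clinical_rows)

    return {
        "organ_paired": organ_paired,
        "ae_group": ae_group,
        "median_split": median_split,
        "clinical": clinical,
        "warnings": pd.DataFrame(warnings, columns=["context", "message"]),
    }


def _spleen_liver_paired(measurements: pd.DataFrame):
    """Per-patient pre/post spleen-to-liver SUVmean ratio vectors."""
    need = {"spleen", "liver"}
    if not len(measurements) or not need <= set(measurements["organ"].unique()):
        return None
    usable = measurements[~measurements["empty_flag"].astype(bool)]
    wide = usable.pivot_table(
        index="patient_id",
        columns=["organ", "timepoint"],
        values="suv_mean",
        aggfunc="first",
    )
    cols = [("spleen", "pre"), ("liver", "pre"), ("spleen", "post"), ("liver", "post")]
    if not all(c in wide.columns for c in cols):
        return None
    wide = wide.dropna(subset=cols)
    wide = wide[(wide[("liver", "pre")] > 0) & (wide[("liver", "post")] > 0)]
    pre = (wide[("spleen", "pre")] / wide[("liver", "pre")]).to_numpy()
    post = (wide[("spleen", "post")] / wide[("liver", "post")]).to_numpy()
    return pre, post
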