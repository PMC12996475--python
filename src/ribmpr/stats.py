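"""Stratified diagnostic-accuracy statistics for per-rib fracture labels.

The unit of analysis is one rib: each patient contributes 24 records
(side x rib index 1-12) carrying a reference-standard label and one or
more predicted labels.  Labels are ``"negative"`` or a fracture type
(``displaced``, ``non-displaced``, ``buckle``, ``old``); any fracture type
counts as positive at the binary level.

Provided strata: overall, anatomical side, rib index, fracture type
(one-vs-rest), patient sex, age group (<30, 30-50, 50-70, >70 years), and
per patient (a patient is positive when any rib is positive).  Sensitivity
and specificity come with Wilson score confidence intervals; group
comparisons use exact McNemar (paired), Fisher's exact test (sex), the
Cochran-Armitage trend test (ordered age groups), and the Pearson
chi-square homogeneity test (rib levels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "NEGATIVE_LABEL",
    "AGE_BINS",
    "ConfusionCounts",
    "DiagnosticResult",
    "confusion_counts",
    "pool_counts",
    "sens_spec",
    "wilson_interval",
    "mcnemar_exact",
    "fisher_exact_2x2",
    "cochran_armitage",
    "chi_square_homogeneity",
    "per_patient_error_table",
]

NEGATIVE_LABEL = "negative"
FRACTURE_TYPES = ("displaced", "non-displaced", "buckle", "old")

#: Age bins: [0, 30), [30, 50), [50, 70), [70, inf)
AGE_BINS = (30, 50, 70)
AGE_GROUP_LABELS = ("<30", "30-50", "50-70", ">70")

REQUIRED_COLUMNS = ("patient", "side", "rib_index", "ref")


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN for one stratum."""

    stratum: str
    key: object
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticResult:
    """Sensitivity/specificity with Wilson CIs for one stratum."""

    stratum: str
    key: object
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    n_positive: int
    specificity: float
    specificity_ci: tuple[float, float]
    n_negative: int


def _is_positive(labels: pd.Series) -> pd.Series:
    return labels.astype(str) != NEGATIVE_LABEL


def _age_group(ages: pd.Series) -> pd.Series:
    bins = [-np.inf, *AGE_BINS, np.inf]
    return pd.cut(ages, bins=bins, labels=AGE_GROUP_LABELS, right=False)


def _validate(records: pd.DataFrame, pred_col: str) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, pred_col) if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    dup = records.duplicated(subset=["patient", "side", "rib_index"])
    if dup.any():
        keys = records.loc[dup, ["patient", "side", "rib_index"]].iloc[0].tolist()
        raise ValueError(f"duplicate (patient, side, rib_index) key: {keys}")


def _counts(ref_pos: pd.Series, pred_pos: pd.Series, stratum: str, key) -> ConfusionCounts:
    return ConfusionCounts(
        stratum=stratum, key=key,
        tp=int((ref_pos & pred_pos).sum()),
        fp=int((~ref_pos & pred_pos).sum()),
        tn=int((~ref_pos & ~pred_pos).sum()),
        fn=int((ref_pos & ~pred_pos).sum()),
    )


def confusion_counts(records: pd.DataFrame, stratifier: str = "overall",
                     pred_col: str = "pred") -> list[ConfusionCounts]:
    """Confusion counts for one stratification of the rib-level records.

    ``stratifier`` is one of ``overall``, ``side``, ``rib_index``,
    ``fracture_type``, ``sex``, ``age_group``, ``patient``.

    At the fracture-type level the comparison is one-vs-rest on the typed
    labels: for type t, TP are ribs with reference and prediction both t,
    FN reference t predicted otherwise, FP reference not-t predicted t.
    At the patient level a patient counts positive when any rib is
    positive.
    """
    _validate(records, pred_col)
    ref_pos = _is_positive(records["ref"])
    pred_pos = _is_positive(records[pred_col])

    if stratifier == "overall":
        return [_counts(ref_pos, pred_pos, "overall", "overall")]
    if stratifier == "side":
        return [_counts(ref_pos[records["side"] == k],
                        pred_pos[records["side"] == k], "side", k)
                for k in sorted(records["side"].unique())]
    if stratifier == "rib_index":
        return [_counts(ref_pos[records["rib_index"] == k],
                        pred_pos[records["rib_index"] == k], "rib_index", int(k))
                for k in sorted(records["rib_index"].unique())]
    if stratifier == "fracture_type":
        out = []
        ref = records["ref"].astype(str)
        pred = records[pred_col].astype(str)
        for t in FRACTURE_TYPES:
            out.append(_counts(ref == t, pred == t, "fracture_type", t))
        return out
    if stratifier == "sex":
        if "sex" not in records.columns:
            raise ValueError("records have no 'sex' column")
        return [_counts(ref_pos[records["sex"] == k],
                        pred_pos[records["sex"] == k], "sex", k)
                for k in sorted(records["sex"].unique())]
    if stratifier == "age_group":
        if "age" not in records.columns:
            raise ValueError("records have no 'age' column")
        groups = _age_group(records["age"])
        return [_counts(ref_pos[groups == g], pred_pos[groups == g], "age_group", g)
                for g in AGE_GROUP_LABELS]
    if stratifier == "patient":
        per = records.assign(_ref=ref_pos, _pred=pred_pos).groupby("patient")
        agg = per.agg(ref_any=("_ref", "any"), pred_any=("_pred", "any"))
        return [_counts(agg["ref_any"], agg["pred_any"], "patient", "patient")]
    raise ValueError(f"unknown stratifier {stratifier!r}")


def pool_counts(counts: list[ConfusionCounts], key="pooled") -> ConfusionCounts:
    """Sum confusion counts across strata (conservation: stratified counts
    sum to the overall counts for any partition)."""
    return ConfusionCounts(
        stratum="pooled", key=key,
        tp=sum(c.tp for c in counts), fp=sum(c.fp for c in counts),
        tn=sum(c.tn for c in counts), fn=sum(c.fn for c in counts),
    )


def wilson_interval(successes: int, trials: int, conf: float = 0.95
                    ) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("Wilson interval needs trials > 0")
    if not 0 <= successes <= trials:
        raise ValueError("need 0 <= successes <= trials")
    lo, hi = proportion_confint(successes, trials, alpha=1 - conf, method="wilson")
    p = successes / trials
    # guard against floating-point bounds excluding the point estimate
    return float(min(lo, p)), float(max(hi, p))


def sens_spec(counts: ConfusionCounts, conf: float = 0.95) -> DiagnosticResult:
    """Sensitivity and specificity with Wilson CIs.

    A zero denominator leaves the corresponding metric NaN ("undefined")
    rather than raising.
    """
    if counts.positives > 0:
        sens = counts.tp / counts.positives
        sens_ci = wilson_interval(counts.tp, counts.positives, conf)
    else:
        sens, sens_ci = float("nan"), (float("nan"), float("nan"))
    if counts.negatives > 0:
        spec = counts.tn / counts.negatives
        spec_ci = wilson_interval(counts.tn, counts.negatives, conf)
    else:
        spec, spec_ci = float("nan"), (float("nan"), float("nan"))
    return DiagnosticResult(
        stratum=counts.stratum, key=counts.key,
        sensitivity=sens, sensitivity_ci=sens_ci, n_positive=counts.positives,
        specificity=spec, specificity_ci=spec_ci, n_negative=counts.negatives,
    )


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p from the discordant-pair counts.

    ``p = min(1, 2 P(X <= min(b, c)))`` with ``X ~ Binomial(b + c, 1/2)``;
    no discordance gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    p = 2.0 * sps.binom.cdf(min(b, c), n, 0.5)
    return float(min(1.0, p))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def cochran_armitage(successes, totals, scores=None) -> tuple[float, float]:
    """Cochran-Armitage trend test across ordered groups.

    Returns ``(Z, p)`` with a two-sided normal p-value.  Default scores are
    1..k.  Reversing the group order flips the sign of Z.
    """
    x = np.asarray(successes, dtype=np.float64)
    n = np.asarray(totals, dtype=np.float64)
    if x.shape != n.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need >= 2 ordered groups of matching shape")
    if n.sum() <= 0:
        raise ValueError("all-zero group totals")
    s = np.arange(1, len(x) + 1, dtype=np.float64) if scores is None \
        else np.asarray(scores, dtype=np.float64)
    N = n.sum()
    pbar = x.sum() / N
    num = float(np.sum(s * (x - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(n * s ** 2) - np.sum(n * s) ** 2 / N)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


def chi_square_homogeneity(successes, totals) -> tuple[float, int, float]:
    """Pearson chi-square on the k x 2 (success, failure) table.

    Returns ``(chi2, df, p)`` with ``df = k - 1``.  A zero expected count
    raises rather than silently returning an undefined statistic.
    """
    x = np.asarray(successes, dtype=np.float64)
    n = np.asarray(totals, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("need >= 2 groups")
    table = np.column_stack([x, n - x])
    if (table < 0).any():
        raise ValueError("successes must not exceed totals")
    expected = sps.contingency.expected_freq(table)
    if (expected == 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def per_patient_error_table(records: pd.DataFrame, pred_col: str = "pred"
                            ) -> pd.DataFrame:
    """Distribution of per-patient diagnostic errors.

    For each patient, count missed fractures (reference positive, predicted
    negative) and false-positive ribs.  Patients are then classified on
    total error count, *not* on net fracture count: ``exact_match`` means
    zero missed and zero false positive; ``one_missed`` / ``one_fp`` are
    the single-error categories; ``two_missed`` / ``two_fp`` the pure
    two-error categories; everything else (including one missed plus one
    false positive) lands in ``other``.

    Returns a DataFrame indexed by category with ``count`` and ``pct`` of
    patients.
    """
    _validate(records, pred_col)
    ref_pos = _is_positive(records["ref"])
    pred_pos = _is_positive(records[pred_col])
    per = records.assign(_miss=(ref_pos & ~pred_pos), _fp=(~ref_pos & pred_pos))
    agg = per.groupby("patient").agg(missed=("_miss", "sum"), fp=("_fp", "sum"))

    def classify(row) -> str:
        m, f = int(row["missed"]), int(row["fp"])
        if m == 0 and f == 0:
            return "exact_match"
        if (m, f) == (1, 0):
            return "one_missed"
        if (m, f) == (0, 1):
            return "one_fp"
        if (m, f) == (2, 0):
            return "two_missed"
        if (m, f) == (0, 2):
            return "two_fp"
        return "other"

    cats = agg.apply(classify, axis=1)
    order = ["exact_match", "one_missed", "one_fp", "two_missed", "two_fp", "other"]
    counts = cats.value_counts().reindex(order, fill_value=0)
    out = pd.DataFrame({"count": counts})
    out["pct"] = 100.0 * out["count"] / len(agg)
    out.attrs["n_patients"] = len(agg)
    return out
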