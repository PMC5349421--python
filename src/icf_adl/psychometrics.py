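"""Validation statistics for the ADL disability indices.

Implements the clinimetric machinery used to validate the instrument:

* ROC/AUC with the Mann-Whitney (midrank) estimator and the DeLong
  structural-component variance for SEs and confidence intervals;
* the DeLong test for comparing two correlated ROC curves measured on the
  same subjects;
* Youden-optimal operating cutoffs with sensitivity and specificity;
* two-way mixed-model intraclass correlation (single measures, absolute
  agreement ICC(A,1) or consistency ICC(C,1)) with F-based CIs;
* Pearson correlation with Fisher-z confidence intervals and the Evans
  strength labels;
* covariate-adjusted group comparison (ANCOVA) with Bonferroni-corrected
  pairwise contrasts;
* a discriminative-validity report combining all of the above per group
  pair and marker, with each index compared against its conventional-scale
  reference (Katz total for b-ADL, Lawton total for i-ADL).

The ROC orientation convention throughout: the more-impaired group is the
positive class and higher marker values predict membership in it.  The
disability indices already run in that direction; the Lawton total runs the
opposite way (higher = more autonomy) and is negated before ROC analysis.
"""

from __future__ import annotations

import itertools
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05  # two-sided significance level used throughout


class DegenerateComparisonError(ValueError):
    """The variance of an AUC difference is zero but the difference is not."""


class OneClassError(ValueError):
    """ROC requested with an empty positive or negative class."""


@dataclass(frozen=True)
class Participant:
    """Cohort row: group membership, covariates, optional comparator scores."""

    participant_id: str
    group: str  # HC, MCI or AD
    age: float
    education: float
    gender: str
    n_medications: int
    n_comorbidities: int
    mmse: Optional[float] = None
    katz_total: Optional[float] = None
    lawton_total: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


GROUPS = ("HC", "MCI", "AD")
#: Impairment ordering used to pick the positive class in a group pair.
GROUP_SEVERITY = {g: i for i, g in enumerate(GROUPS)}


@dataclass(frozen=True)
class RocResult:
    marker_name: str
    auc: float
    se: float
    ci_low: float
    ci_high: float
    n_positive: int
    n_negative: int
    cutoff: Optional[float] = None
    sensitivity: Optional[float] = None  # percent
    specificity: Optional[float] = None  # percent


@dataclass(frozen=True)
class RocComparison:
    marker_a: RocResult
    marker_b: RocResult
    auc_difference: float
    z: float
    p: float


@dataclass(frozen=True)
class IccResult:
    icc: float
    model: str
    ci_low: float
    ci_high: float
    n_subjects: int
    n_raters: int
    p: float


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    strength: str


@dataclass
class GroupComparison:
    adjusted_means: dict[str, float]
    f_statistic: float
    df_num: int
    df_den: int
    p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, mean diff, Bonferroni p)
    covariates: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong
# ---------------------------------------------------------------------------

def _split_classes(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels.astype(bool)]
    neg = scores[~labels.astype(bool)]
    if len(pos) == 0 or len(neg) == 0:
        raise OneClassError("both classes must be non-empty for ROC analysis")
    return pos, neg


def _delong_placements(pos: np.ndarray, neg: np.ndarray):
    """AUC and per-subject structural components (midrank placements).

    ``v10[i]`` is the fraction of negatives a positive subject outranks
    (ties counted 1/2); ``v01[j]`` the mirrored quantity for negatives.
    ``v10.mean() == v01.mean() == AUC`` exactly.
    """
    m, n = len(pos), len(neg)
    ranks_all = stats.rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - stats.rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(neg)) / m
    return v10.mean(), v10, v01


def auc(scores: Sequence[float], labels: Sequence[int],
        marker_name: str = "marker") -> RocResult:
    """Mann-Whitney AUC with DeLong SE and normal-approximation 95% CI.

    ``labels`` is binary with 1 = positive (more-impaired) class; higher
    scores are taken to predict the positive class.  Constant scores give
    AUC 0.5 with a warning.  The CI is computed untruncated and clipped to
    [0, 1].
    """
    pos, neg = _split_classes(scores, labels)
    if np.ptp(np.concatenate([pos, neg])) == 0:
        _warnings.warn("constant scores: AUC is 0.5 by convention", stacklevel=2)
    a, v10, v01 = _delong_placements(pos, neg)
    var = (np.var(v10, ddof=1) / len(pos) if len(pos) > 1 else 0.0) \
        + (np.var(v01, ddof=1) / len(neg) if len(neg) > 1 else 0.0)
    se = float(np.sqrt(max(var, 0.0)))
    zc = stats.norm.ppf(1 - ALPHA / 2)
    return RocResult(
        marker_name=marker_name,
        auc=float(a),
        se=se,
        ci_low=float(np.clip(a - zc * se, 0.0, 1.0)),
        ci_high=float(np.clip(a + zc * se, 0.0, 1.0)),
        n_positive=len(pos),
        n_negative=len(neg),
    )


def delong_compare(scores_a: Sequence[float], scores_b: Sequence[float],
                   labels: Sequence[int],
                   name_a: str = "marker_a", name_b: str = "marker_b",
                   ) -> RocComparison:
    """DeLong test for two correlated AUCs measured on the same subjects.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab), two-sided p from
    the standard normal.  Identical markers give difference 0 and p = 1;
    zero variance of a non-zero difference raises
    :class:`DegenerateComparisonError`.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired markers must be observed on the same subjects")
    roc_a = auc(scores_a, labels, name_a)
    roc_b = auc(scores_b, labels, name_b)

    pos_a, neg_a = _split_classes(scores_a, labels)
    pos_b, neg_b = _split_classes(scores_b, labels)
    _, v10_a, v01_a = _delong_placements(pos_a, neg_a)
    _, v10_b, v01_b = _delong_placements(pos_b, neg_b)
    m, n = len(pos_a), len(neg_a)

    def _cov(x, y, size):
        return float(np.cov(x, y, ddof=1)[0, 1]) / size if size > 1 else 0.0

    var_a = roc_a.se ** 2
    var_b = roc_b.se ** 2
    cov_ab = _cov(v10_a, v10_b, m) + _cov(v01_a, v01_b, n)
    var_diff = var_a + var_b - 2.0 * cov_ab
    diff = roc_a.auc - roc_b.auc

    if var_diff <= 1e-15:
        if abs(diff) <= 1e-12:
            return RocComparison(roc_a, roc_b, 0.0, 0.0, 1.0)
        raise DegenerateComparisonError(
            "AUC difference has zero variance but is non-zero")
    z = diff / float(np.sqrt(var_diff))
    p = float(2 * stats.norm.sf(abs(z)))
    return RocComparison(roc_a, roc_b, float(diff), float(z), p)


def youden_cutoff(scores: Sequence[float], labels: Sequence[int]
                  ) -> tuple[float, float, float]:
    """Optimal operating point maximising Youden's J = sens + spec - 1.

    Candidate cutoffs are midpoints between adjacent distinct observed
    values; the classification rule is score >= cutoff -> positive.  Ties in
    J are broken toward higher specificity (then the higher cutoff).
    Returns ``(cutoff, sensitivity_percent, specificity_percent)``.
    """
    pos, neg = _split_classes(scores, labels)
    distinct = np.unique(np.concatenate([pos, neg]))
    if len(distinct) == 1:
        _warnings.warn("constant scores: no informative cutoff", stacklevel=2)
        return float(distinct[0]), 100.0, 0.0
    candidates = (distinct[:-1] + distinct[1:]) / 2.0

    best = None
    for c in candidates:
        sens = float(np.mean(pos >= c))
        spec = float(np.mean(neg < c))
        key = (sens + spec - 1.0, spec, c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, c, sens, spec = best
    return float(c), 100.0 * sens, 100.0 * spec


def roc_with_cutoff(scores, labels, marker_name: str = "marker") -> RocResult:
    """AUC plus the Youden-optimal cutoff, sensitivity and specificity."""
    base = auc(scores, labels, marker_name)
    cut, sens, spec = youden_cutoff(scores, labels)
    return RocResult(marker_name, base.auc, base.se, base.ci_low, base.ci_high,
                     base.n_positive, base.n_negative, cut, sens, spec)


# ---------------------------------------------------------------------------
# Interrater reliability (two-way mixed ICC)
# ---------------------------------------------------------------------------

def icc_two_way(ratings, definition: str = "agreement") -> IccResult:
    """Single-measure ICC from a two-way mixed model.

    ``ratings`` is an (n_subjects x k_raters) table with no missing cells.
    ``definition='agreement'`` gives McGraw-Wong ICC(A,1) (absolute
    agreement; rater mean differences penalised); ``'consistency'`` gives
    ICC(C,1).  Confidence intervals use the exact F-based formulas, with a
    Satterthwaite df approximation for ICC(A,1).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    if np.isnan(x).any():
        raise ValueError("missing cells are not supported (no imputation)")
    n, k = x.shape
    if n < 5:
        raise ValueError("at least 5 subjects are required")
    if definition not in ("agreement", "consistency"):
        raise ValueError(f"unknown ICC definition {definition!r}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    df1, df2 = n - 1, (n - 1) * (k - 1)
    if mse == 0.0:
        # Perfect reproduction of every rating.
        icc_val = 1.0 if msr > 0 else 0.0
        p = 0.0 if msr > 0 else 1.0
        return IccResult(icc_val, _icc_tag(definition), icc_val, icc_val, n, k, p)

    f_obs = msr / mse
    p = float(stats.f.sf(f_obs, df1, df2))
    q = stats.f.ppf(1 - ALPHA / 2, df1, df2)

    if definition == "consistency":
        icc_val = (msr - mse) / (msr + (k - 1) * mse)
        fl = f_obs / q
        fu = f_obs * stats.f.ppf(1 - ALPHA / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    else:
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        icc_val = (msr - mse) / denom
        r = icc_val
        if r >= 1.0:
            lo = hi = 1.0
        else:
            a_ = (k * r) / (n * (1 - r))
            b_ = 1 + (k * r * (n - 1)) / (n * (1 - r))
            nu = (a_ * msc + b_ * mse) ** 2 / (
                (a_ * msc) ** 2 / (k - 1) + (b_ * mse) ** 2 / ((n - 1) * (k - 1)))
            f_l = stats.f.ppf(1 - ALPHA / 2, n - 1, nu)
            f_u = stats.f.ppf(1 - ALPHA / 2, nu, n - 1)
            lo = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
            hi = (n * (f_u * msr - mse)
                  / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    lo, hi = float(min(lo, icc_val)), float(min(max(hi, icc_val), 1.0))
    return IccResult(float(icc_val), _icc_tag(definition), lo, hi, n, k, p)


def _icc_tag(definition: str) -> str:
    kind = "absolute agreement ICC(A,1)" if definition == "agreement" \
        else "consistency ICC(C,1)"
    return f"two-way mixed, single measures, {kind}"


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

#: Evans (1996) interpretation bands for |r|.
EVANS_BANDS = [(0.20, "very weak"), (0.40, "weak"), (0.60, "moderate"),
               (0.80, "strong"), (1.01, "excellent")]


def evans_strength(r: float) -> str:
    for bound, label in EVANS_BANDS:
        if abs(r) < bound:
            return label
    return "excellent"


def pearson_ci(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Pearson r with Fisher-z 95% CI, two-sided p and Evans strength label."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need >= 4 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: an input has zero variance")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - ALPHA)
    r = float(res.statistic)
    return PearsonResult(r, float(ci.low), float(ci.high), float(res.pvalue),
                         len(x), evans_strength(r))


# ---------------------------------------------------------------------------
# Covariate-adjusted group comparison (ANCOVA)
# ---------------------------------------------------------------------------

def group_compare(data: pd.DataFrame, outcome: str, group: str = "group",
                  covariates: Sequence[str] = (),
                  ) -> GroupComparison:
    """ANCOVA: outcome ~ group + covariates, Bonferroni pairwise contrasts.

    Categorical covariates (object/category dtype, e.g. gender) enter as
    factors.  Adjusted group means are model predictions at the covariate
    means (factor covariates at their sample distribution).  With no
    covariates this reduces exactly to the classical one-way ANOVA F.
    Perfectly collinear covariates are rejected naming the offender.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = data[[outcome, group, *covariates]].copy()
    if df[group].nunique() < 2:
        raise ValueError("need at least two groups")
    counts = df[group].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 subjects: {small}")

    cat = [c for c in covariates
           if df[c].dtype == object or str(df[c].dtype) == "category"]
    _check_collinearity(df, group, covariates, cat)

    terms = [f"C({group})"] + [f"C({c})" if c in cat else c for c in covariates]
    model = smf.ols(f"{outcome} ~ " + " + ".join(terms), data=df).fit()
    atable = anova_lm(model, typ=2)
    grow = atable.loc[f"C({group})"]
    f_stat = float(grow["F"])
    df_num = int(grow["df"])
    df_den = int(atable.loc["Residual", "df"])
    p_overall = float(grow["PR(>F)"])

    levels = sorted(df[group].unique(), key=lambda g: GROUP_SEVERITY.get(g, 99))
    # Adjusted means: predict per group with covariates frozen at sample means
    # (numeric) or averaged over the observed distribution (factors).
    adjusted = {}
    for g in levels:
        ref = df.copy()
        ref[group] = g
        adjusted[g] = float(model.predict(ref).mean())

    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    pairwise = []
    for a_, b_ in pairs:
        name_a, name_b = f"C({group})[T.{a_}]", f"C({group})[T.{b_}]"
        vec = pd.Series(0.0, index=model.params.index)
        if name_a in vec.index:
            vec[name_a] = 1.0
        if name_b in vec.index:
            vec[name_b] = -1.0
        tt = model.t_test(vec.to_numpy())
        p_adj = min(1.0, float(tt.pvalue) * k)
        pairwise.append((a_, b_, adjusted[a_] - adjusted[b_], p_adj))

    return GroupComparison(adjusted, f_stat, df_num, df_den, p_overall,
                           pairwise, list(covariates))


def _check_collinearity(df, group, covariates, cat):
    """Reject a design whose covariate block is rank-deficient, naming it."""
    numeric = [c for c in covariates if c not in cat]
    if not numeric:
        return
    mat = np.column_stack([np.ones(len(df))] +
                          [df[c].to_numpy(dtype=float) for c in numeric])
    for j, c in enumerate(numeric, start=1):
        if np.linalg.matrix_rank(mat[:, :j + 1]) <= np.linalg.matrix_rank(mat[:, :j]):
            raise ValueError(f"collinear covariate: {c!r}")


# ---------------------------------------------------------------------------
# Discriminative-validity report
# ---------------------------------------------------------------------------

#: Default reference marker per index family; Lawton runs higher = more
#: autonomy, so it is negated before ROC (orientation -1).
DEFAULT_REFERENCES = {"b_adl": "katz_total", "i_adl": "lawton_total"}
DEFAULT_ORIENTATION = {"lawton_total": -1}

VALIDITY_COLUMNS = ["comparison", "marker", "n_negative", "n_positive",
                    "auc", "se", "ci_low", "ci_high",
                    "cutoff", "sensitivity", "specificity",
                    "reference", "delong_z", "delong_p"]


def validity_report(data: pd.DataFrame,
                    comparisons: Sequence[tuple[str, str]] = (
                        ("HC", "MCI"), ("MCI", "AD"), ("HC", "AD")),
                    markers: Sequence[str] = (),
                    references: Optional[Mapping[str, str]] = None,
                    orientation: Optional[Mapping[str, int]] = None,
                    group_col: str = "group",
                    ) -> pd.DataFrame:
    """Discriminative-validity table: AUC/CI/cutoff per group pair and marker.

    ``data`` holds one row per participant with ``group_col``, the marker
    columns and (when present) the reference columns.  For each pair the
    more impaired group is the positive class.  Each index marker is also
    compared against its reference marker with the DeLong test; a missing
    reference column drops that comparison with a warning.  Cutoffs are
    reported in the marker's native units (the reference's orientation sign
    is undone for reporting).
    """
    references = dict(DEFAULT_REFERENCES if references is None else references)
    orientation = dict(DEFAULT_ORIENTATION if orientation is None else orientation)
    if not markers:
        markers = [c for c in data.columns
                   if c.startswith(("b_adl_", "i_adl_"))]

    rows = []
    for g_neg, g_pos in comparisons:
        if GROUP_SEVERITY.get(g_neg, 0) > GROUP_SEVERITY.get(g_pos, 0):
            g_neg, g_pos = g_pos, g_neg
        sub = data[data[group_col].isin([g_neg, g_pos])]
        labels = (sub[group_col] == g_pos).to_numpy(dtype=int)
        comparison = f"{g_neg} vs {g_pos}"

        # reference markers first, each reported once per comparison
        ref_scores: dict[str, np.ndarray] = {}
        for ref in dict.fromkeys(references.values()):
            if ref not in sub.columns or sub[ref].isna().any():
                _warnings.warn(
                    f"reference marker {ref!r} unavailable for {comparison}; "
                    "DeLong comparisons against it are omitted", stacklevel=2)
                continue
            sign = orientation.get(ref, 1)
            sc = sign * sub[ref].to_numpy(dtype=float)
            ref_scores[ref] = sc
            rr = roc_with_cutoff(sc, labels, ref)
            rows.append(_validity_row(comparison, rr, sign, None, None, None))

        for marker in markers:
            sign = orientation.get(marker, 1)
            sc = sign * sub[marker].to_numpy(dtype=float)
            rr = roc_with_cutoff(sc, labels, marker)
            family = marker[:5]
            ref = references.get(family)
            z = p = None
            if ref in ref_scores:
                cmp_res = delong_compare(sc, ref_scores[ref], labels, marker, ref)
                z, p = cmp_res.z, cmp_res.p
            else:
                ref = None
            rows.append(_validity_row(comparison, rr, sign, ref, z, p))
    return pd.DataFrame(rows, columns=VALIDITY_COLUMNS)


def _validity_row(comparison, rr: RocResult, sign, ref, z, p):
    return {
        "comparison": comparison, "marker": rr.marker_name,
        "n_negative": rr.n_negative, "n_positive": rr.n_positive,
        "auc": rr.auc, "se": rr.se, "ci_low": rr.ci_low, "ci_high": rr.ci_high,
        "cutoff": sign * rr.cutoff if rr.cutoff is not None else None,
        "sensitivity": rr.sensitivity, "specificity": rr.specificity,
        "reference": ref, "delong_z": z, "delong_p": p,
    }
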