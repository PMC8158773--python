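"""Agreement and clinical-accuracy statistics for cuffless-vs-cuff BP.

All differences are oriented **predicted minus reference** (cuffless
minus cuff); the cuff mean is the reference method throughout.

The zonal error grid partitions each (reference, predicted) pair into
clinical-risk zones by the relative deviation d = |pred - ref| / ref:

=====  =============================  =====================================
zone   deviation (exact fraction)     clinical meaning
=====  =============================  =====================================
A      d <= 1/12  (~8.3%)             clinically accurate
B      d <= 2/12  (~16.7%)            no significant clinical importance
C      d <= 4/12  (~33.3%)            may influence a decision, not dangerous
D      d <= 5/12  (~41.7%)            potentially dangerous error
E      d >  5/12                      extreme error
=====  =============================  =====================================

The fractions are stored as exact rationals (k/12, upper edges
inclusive), not as the rounded percentages: for a 140 mmHg reference the
zone-A band is 140 * 11/12 = 128.33... -> printed 128.3, which a 0.917
decimal approximation would miss.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "AgreementReport",
    "ErrorGridResult",
    "ClassificationReport",
    "EvaluationReport",
    "DEFAULT_ZONE_FRACTIONS",
    "CONDITION_THRESHOLDS",
    "bland_altman",
    "spearman_corr",
    "zone_of",
    "zone_boundaries",
    "error_grid",
    "subgroup_errors",
    "classify_hypertension",
    "delong_auc_ci",
    "evaluate_pairs",
]

ZONES = ("A", "B", "C", "D", "E")
DEFAULT_ZONE_FRACTIONS: tuple[Fraction, ...] = (
    Fraction(1, 12), Fraction(2, 12), Fraction(4, 12), Fraction(5, 12)
)
# condition -> (systolic threshold, diastolic threshold), strict 'greater than'
CONDITION_THRESHOLDS = {
    "hypertension": (140.0, 90.0),
    "prehypertension": (130.0, 85.0),
}


@dataclass
class PairedMeasurements:
    """Per-subject reference (cuff mean) and predicted SBP/DBP, mmHg."""

    ref_sbp: np.ndarray
    ref_dbp: np.ndarray
    pred_sbp: np.ndarray
    pred_dbp: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        arrays = [np.asarray(getattr(self, k), dtype=float)
                  for k in ("ref_sbp", "ref_dbp", "pred_sbp", "pred_dbp")]
        n = arrays[0].size
        if any(a.size != n for a in arrays) or n < 1:
            raise ValueError("paired arrays must be nonempty and equal-length")
        if any(np.isnan(a).any() for a in arrays):
            raise ValueError("missing pairs are not allowed")
        self.ref_sbp, self.ref_dbp, self.pred_sbp, self.pred_dbp = arrays

    @property
    def n(self) -> int:
        return self.ref_sbp.size

    def ref(self, target: str) -> np.ndarray:
        return self.ref_sbp if target == "sbp" else self.ref_dbp

    def pred(self, target: str) -> np.ndarray:
        return self.pred_sbp if target == "sbp" else self.pred_dbp


# ---------------------------------------------------------------------------
# Bland-Altman and correlation
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    target: str
    n: int
    bias: float
    sd: float
    ci_low: float
    ci_high: float
    t_p: float
    loa_low: float
    loa_high: float
    spearman_r: float
    spearman_p: float
    means: list[float] = field(default_factory=list)
    diffs: list[float] = field(default_factory=list)


def bland_altman(pairs: PairedMeasurements, target: str = "sbp"
                 ) -> AgreementReport:
    """Mean difference (bias), its 95% CI and t-test, and limits of agreement.

    Differences are predicted - reference; the per-pair (mean, difference)
    coordinates for the classic plot are included in the report.
    """
    ref, pred = pairs.ref(target), pairs.pred(target)
    d = pred - ref
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    if n >= 3 and sd > 0:
        t = stats.ttest_1samp(d, 0.0)
        ci = t.confidence_interval(0.95)
        ci_low, ci_high, t_p = float(ci.low), float(ci.high), float(t.pvalue)
    else:
        # degenerate (zero-variance or tiny n): CI collapses to the bias
        ci_low = ci_high = bias
        t_p = math.nan
    r, p = spearman_corr(pairs, target)
    return AgreementReport(
        target=target,
        n=n,
        bias=bias,
        sd=sd,
        ci_low=ci_low,
        ci_high=ci_high,
        t_p=t_p,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        spearman_r=r,
        spearman_p=p,
        means=((ref + pred) / 2.0).tolist(),
        diffs=d.tolist(),
    )


def spearman_corr(pairs: PairedMeasurements, target: str = "sbp"
                  ) -> tuple[float, float]:
    """Spearman rank correlation (mid-rank ties) between the two methods."""
    ref, pred = pairs.ref(target), pairs.pred(target)
    if np.unique(ref).size < 2 or np.unique(pred).size < 2:
        return math.nan, math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r, p = stats.spearmanr(ref, pred)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# zonal error grid
# ---------------------------------------------------------------------------

def zone_of(
    reference: float,
    predicted: float,
    fractions: tuple[Fraction, ...] = DEFAULT_ZONE_FRACTIONS,
) -> str:
    """Zone label A-E from the exact relative deviation (upper edges inclusive)."""
    if reference <= 0:
        raise ValueError("reference pressure must be positive")
    dev = abs(Fraction(str(predicted)) - Fraction(str(reference))) \
        / Fraction(str(reference))
    for zone, frac in zip(ZONES, fractions):
        if dev <= frac:
            return zone
    return "E"


def _round_half_up_1dp(x: Fraction) -> float:
    """Half-up rounding to one decimal, exact in rational arithmetic."""
    scaled = x * 10 + Fraction(1, 2)
    return math.floor(scaled) / 10.0


def zone_boundaries(
    reference: float,
    fractions: tuple[Fraction, ...] = DEFAULT_ZONE_FRACTIONS,
) -> dict[str, tuple[float, float]]:
    """Zone band edges ``reference * (1 -+ f)``, half-up rounded to 1 decimal.

    Returns ``{"A": (lower, upper), ...}`` for the four bounded zones;
    predictions beyond the outermost pair fall in zone E.
    """
    if reference <= 0:
        raise ValueError("reference pressure must be positive")
    ref = Fraction(str(reference))
    out = {}
    for zone, frac in zip(ZONES, fractions):
        out[zone] = (
            _round_half_up_1dp(ref * (1 - frac)),
            _round_half_up_1dp(ref * (1 + frac)),
        )
    return out


@dataclass
class ErrorGridResult:
    target: str
    n: int
    labels: list[str]
    counts: dict[str, int]
    percentages: dict[str, float]
    fractions: list[float]
    reference: list[float] = field(default_factory=list)
    predicted: list[float] = field(default_factory=list)


def error_grid(
    pairs: PairedMeasurements,
    target: str = "sbp",
    fractions: tuple[Fraction, ...] = DEFAULT_ZONE_FRACTIONS,
) -> ErrorGridResult:
    """Zone label per pair plus zone counts and percentages (sum 100)."""
    ref, pred = pairs.ref(target), pairs.pred(target)
    labels = [zone_of(r, p, fractions) for r, p in zip(ref, pred)]
    counts = {z: labels.count(z) for z in ZONES}
    pct = {z: 100.0 * c / pairs.n for z, c in counts.items()}
    return ErrorGridResult(
        target=target,
        n=pairs.n,
        labels=labels,
        counts=counts,
        percentages=pct,
        fractions=[float(f) for f in fractions],
        reference=ref.tolist(),
        predicted=pred.tolist(),
    )


# ---------------------------------------------------------------------------
# subgroup error analysis
# ---------------------------------------------------------------------------

def _subgroup_label(sbp: float, dbp: float) -> str:
    if sbp < 110 and dbp < 70:
        return "<110/70"
    if sbp > 140 or dbp > 90:
        return ">140/90"
    return "110/70-140/90"


def subgroup_errors(pairs: PairedMeasurements) -> pd.DataFrame:
    """Error summaries per BP subgroup and target.

    Subgroups are assigned from the reference cuff values: low if
    SBP < 110 and DBP < 70, high if SBP > 140 or DBP > 90, else middle.
    For each subgroup x target the table reports mean +- sd, median with
    quartiles, and a one-sample Wilcoxon signed-rank p for zero median
    error.  Empty subgroups yield a row of nulls with a warning.
    """
    groups = ["all", "<110/70", "110/70-140/90", ">140/90"]
    assignment = np.array([
        _subgroup_label(s, d) for s, d in zip(pairs.ref_sbp, pairs.ref_dbp)
    ])
    rows = []
    for g in groups:
        sel = np.ones(pairs.n, bool) if g == "all" else assignment == g
        for target in ("sbp", "dbp"):
            d = (pairs.pred(target) - pairs.ref(target))[sel]
            row = {"group": g, "target": target, "n": int(sel.sum())}
            if d.size == 0:
                warnings.warn(f"empty subgroup {g!r}", stacklevel=2)
                row.update(mean=math.nan, sd=math.nan, median=math.nan,
                           q25=math.nan, q75=math.nan, wilcoxon_p=math.nan)
            else:
                row.update(
                    mean=float(np.mean(d)),
                    sd=float(np.std(d, ddof=1)) if d.size > 1 else math.nan,
                    median=float(np.median(d)),
                    q25=float(np.percentile(d, 25)),
                    q75=float(np.percentile(d, 75)),
                )
                if np.allclose(d, 0) or d.size < 3:
                    row["wilcoxon_p"] = math.nan
                else:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        row["wilcoxon_p"] = float(
                            stats.wilcoxon(d, zero_method="wilcox").pvalue
                        ) if np.any(d != 0) else math.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hypertension classification with DeLong
# ---------------------------------------------------------------------------

def delong_auc_ci(
    scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, tuple[float, float]]:
    """AUC of ``scores`` against binary ``labels`` with DeLong variance.

    Uses the placement-value (structural components) formulation: the
    variance of the empirical AUC is S10/m + S01/n with S10, S01 the
    sample variances of the positive- and negative-class placement
    values.  Returns (auc, se, (lo, hi)); the CI is truncated to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    x = scores[labels]     # positives
    y = scores[~labels]    # negatives
    m, n = x.size, y.size
    if m == 0 or n == 0:
        raise ValueError("AUC requires both classes present")
    gt = (x[:, None] > y[None, :]).astype(float)
    eq = (x[:, None] == y[None, :]).astype(float)
    mat = gt + 0.5 * eq
    v10 = mat.mean(axis=1)
    v01 = mat.mean(axis=0)
    auc = float(mat.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    se = math.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, se, (lo, hi)


@dataclass
class ClassificationReport:
    condition: str
    sbp_threshold: float
    dbp_threshold: float
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    auc: float
    auc_se: float
    auc_ci_low: float
    auc_ci_high: float


def _exceedance_score(sbp, dbp, thr_s, thr_d):
    """Continuous hypertension score: max scaled threshold exceedance."""
    return np.maximum((np.asarray(sbp, float) - thr_s) / thr_s,
                      (np.asarray(dbp, float) - thr_d) / thr_d)


def classify_hypertension(
    pairs: PairedMeasurements, condition: str = "hypertension"
) -> ClassificationReport:
    """Sensitivity/specificity of the cuffless method at a BP threshold.

    A subject is positive when SBP > s-threshold OR DBP > d-threshold,
    applied identically to reference and predicted values.  The AUC (with
    DeLong CI) uses the continuous exceedance score of the predicted
    values against the reference labels, since a fixed-threshold
    confusion table alone has no ROC.
    """
    try:
        thr_s, thr_d = CONDITION_THRESHOLDS[condition]
    except KeyError:
        raise ValueError(
            f"unknown condition {condition!r}; expected one of "
            f"{sorted(CONDITION_THRESHOLDS)}"
        ) from None
    ref_pos = (pairs.ref_sbp > thr_s) | (pairs.ref_dbp > thr_d)
    pred_pos = (pairs.pred_sbp > thr_s) | (pairs.pred_dbp > thr_d)
    tp = int(np.sum(ref_pos & pred_pos))
    fp = int(np.sum(~ref_pos & pred_pos))
    tn = int(np.sum(~ref_pos & ~pred_pos))
    fn = int(np.sum(ref_pos & ~pred_pos))
    sens = 100.0 * tp / (tp + fn) if (tp + fn) else math.nan
    spec = 100.0 * tn / (tn + fp) if (tn + fp) else math.nan
    if math.isnan(sens) or math.isnan(spec):
        warnings.warn(
            f"single-class reference for condition {condition!r}; "
            "sensitivity or specificity undefined", stacklevel=2,
        )
    acc = 100.0 * (tp + tn) / pairs.n
    if ref_pos.any() and (~ref_pos).any():
        score = _exceedance_score(pairs.pred_sbp, pairs.pred_dbp, thr_s, thr_d)
        auc, se, (lo, hi) = delong_auc_ci(score, ref_pos)
    else:
        auc = se = lo = hi = math.nan
    return ClassificationReport(
        condition=condition,
        sbp_threshold=thr_s,
        dbp_threshold=thr_d,
        n=pairs.n,
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity_pct=sens,
        specificity_pct=spec,
        accuracy_pct=acc,
        auc=auc,
        auc_se=se,
        auc_ci_low=lo,
        auc_ci_high=hi,
    )


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    n: int
    agreement: dict[str, AgreementReport]
    grid: dict[str, ErrorGridResult]
    subgroups: pd.DataFrame
    classification: dict[str, ClassificationReport]


def evaluate_pairs(pairs: PairedMeasurements) -> EvaluationReport:
    """Run the complete statistical battery on one set of paired readings."""
    return EvaluationReport(
        n=pairs.n,
        agreement={t: bland_altman(pairs, t) for t in ("sbp", "dbp")},
        grid={t: error_grid(pairs, t) for t in ("sbp", "dbp")},
        subgroups=subgroup_errors(pairs),
        classification={
            c: classify_hypertension(pairs, c) for c in CONDITION_THRESHOLDS
        },
    )
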