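"""Classifier evaluation for thiopurine-intolerance prediction.

Condition positivity is defined on the phenotype (DIP <= cutoff, the seven
standard cutoffs being 15/25/35/45/60/80/100%); test positivity on the
predictor (GVB score <= threshold for the quantitative burden models —
lower burden score = higher risk — or the PM+IM arm for the categorical
star-allele baseline).  The module provides confusion-matrix metrics,
ROC/AUC with stratified-bootstrap confidence intervals, Youden-index
threshold selection, the star-allele vs burden comparison report, and the
single-gene contribution analysis that re-scores each gene after excluding
subjects affected by the other two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve

DIP_CUTOFFS = (15.0, 25.0, 35.0, 45.0, 60.0, 80.0, 100.0)


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Decimal half-up rounding, as used for report display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts: condition positive = intolerant (DIP <= cutoff), test
    positive = predicted intolerant."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassifierMetrics:
    """Derived proportions; a zero denominator yields None (undefined)."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def rounded(self, ndigits: int = 3) -> "ClassifierMetrics":
        vals = {k: (None if v is None else round_half_up(v, ndigits))
                for k, v in self.__dict__.items()}
        return ClassifierMetrics(**vals)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(table: ConfusionTable) -> ClassifierMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy from a 2x2 table."""
    if table.total == 0:
        raise ValueError("empty confusion table")
    return ClassifierMetrics(
        sensitivity=_ratio(table.tp, table.tp + table.fn),
        specificity=_ratio(table.tn, table.tn + table.fp),
        ppv=_ratio(table.tp, table.tp + table.fp),
        npv=_ratio(table.tn, table.tn + table.fn),
        accuracy=(table.tp + table.tn) / table.total,
    )


@dataclass
class RocResult:
    """ROC curve, AUC, and a stratified-bootstrap 95% interval."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float | None
    ci_high: float | None
    dip_cutoff: float | None = None
    n_positive: int = 0
    n_negative: int = 0


def _risk_scores(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "lower":
        return -scores  # lower raw score = higher risk
    if direction == "higher":
        return scores
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


def roc_auc(scores: Sequence[float], labels: Sequence[bool],
            direction: str = "lower", n_bootstrap: int = 2000,
            seed: int = 0, dip_cutoff: float | None = None) -> RocResult:
    """ROC curve and AUC of a score against binary condition labels.

    AUC is the tie-corrected Mann-Whitney probability that a positive
    subject's risk-oriented score exceeds a negative's.  The 95% CI comes
    from a stratified bootstrap (positives and negatives resampled
    separately; ``n_bootstrap=0`` skips it).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes nonempty")
    risk = _risk_scores(s, direction)
    fpr, tpr, _ = roc_curve(y, risk)
    auc = float(roc_auc_score(y, risk))
    ci_low = ci_high = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        pos, neg = risk[y], risk[~y]
        aucs = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            bp = rng.choice(pos, size=n_pos, replace=True)
            bn = rng.choice(neg, size=n_neg, replace=True)
            yy = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
            aucs[b] = roc_auc_score(yy, np.concatenate([bp, bn]))
        ci_low, ci_high = (float(np.percentile(aucs, 2.5)),
                           float(np.percentile(aucs, 97.5)))
        ci_low, ci_high = min(ci_low, auc), max(ci_high, auc)
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, ci_low=ci_low,
                     ci_high=ci_high, dip_cutoff=dip_cutoff,
                     n_positive=n_pos, n_negative=n_neg)


@dataclass(frozen=True)
class YoudenCutoff:
    """Youden-optimal threshold on the raw score scale."""

    threshold: float
    j_statistic: float  # sensitivity + specificity - 1
    sensitivity: float
    specificity: float


def youden_cutoff(scores: Sequence[float], labels: Sequence[bool],
                  direction: str = "lower") -> YoudenCutoff:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Every observed score is a candidate threshold; a subject tests positive
    when its score is <= threshold (direction 'lower') or >= threshold
    ('higher').  Ties in J are broken toward the threshold classifying more
    subjects as positive (higher sensitivity), the conservative choice for a
    toxicity screen.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("Youden cutoff requires both classes nonempty")
    if direction not in ("lower", "higher"):
        raise ValueError("direction must be 'lower' or 'higher'")
    candidates = np.unique(s)  # ascending
    if direction == "higher":
        candidates = candidates[::-1]  # so that later = more positives
    best = None
    for t in candidates:
        pred = s <= t if direction == "lower" else s >= t
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1.0
        # candidates are ordered so later thresholds call more subjects
        # positive; replacing on ties keeps the most-sensitive maximizer
        if best is None or j > best[0] - 1e-12:
            best = (j, t, sens, spec)
    j, t, sens, spec = best
    return YoudenCutoff(threshold=float(t), j_statistic=float(j),
                        sensitivity=float(sens), specificity=float(spec))


def classify_by_gvb(scores: Sequence[float], threshold: float,
                    direction: str = "lower") -> np.ndarray:
    """Predicted-intolerant labels: score <= threshold (inclusive) for the
    burden direction ('lower'), >= for 'higher'."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return s <= threshold if direction == "lower" else s >= threshold


def confusion_from_predictions(condition: Sequence[bool],
                               predicted: Sequence[bool]) -> ConfusionTable:
    """Cross-tabulate condition vs predicted labels into a 2x2 table."""
    y = np.asarray(condition, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    return ConfusionTable(tp=int((p & y).sum()), fp=int((p & ~y).sum()),
                          fn=int((~p & y).sum()), tn=int((~p & ~y).sum()))


class YoudenThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style classifier thresholding a 1-D risk score.

    ``fit(X, y)`` learns the Youden-optimal threshold on the training scores
    (``X`` of shape (n,) or (n, 1)); ``predict`` applies score <= threshold_
    (direction 'lower') to call intolerance.  A fixed ``threshold`` bypasses
    fitting of the cutoff.
    """

    def __init__(self, direction: str = "lower",
                 threshold: float | None = None):
        self.direction = direction
        self.threshold = threshold

    @staticmethod
    def _scores(X) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        if a.ndim == 2:
            if a.shape[1] != 1:
                raise ValueError("expected a single score column")
            a = a[:, 0]
        return a

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y, dtype=bool)
        self.classes_ = np.array([False, True])
        if self.threshold is not None:
            self.threshold_ = float(self.threshold)
            pred = classify_by_gvb(s, self.threshold_, self.direction)
            sens = (pred & y).sum() / max(y.sum(), 1)
            spec = (~pred & ~y).sum() / max((~y).sum(), 1)
            self.j_statistic_ = float(sens + spec - 1.0)
        else:
            cut = youden_cutoff(s, y, self.direction)
            self.threshold_ = cut.threshold
            self.j_statistic_ = cut.j_statistic
        return self

    def predict(self, X):
        if not hasattr(self, "threshold_"):
            raise ValueError("classifier is not fitted")
        return classify_by_gvb(self._scores(X), self.threshold_, self.direction)

    def decision_function(self, X):
        s = self._scores(X)
        return -s if self.direction == "lower" else s


def compare_models(subjects: pd.DataFrame, profiles: pd.DataFrame,
                   calls: pd.DataFrame,
                   two_gene_label: str = "NUDT15,TPMT",
                   three_gene_label: str = "NUDT15,TPMT,CRIM1",
                   dip_cutoff: float = 25.0,
                   n_bootstrap: int = 0, seed: int = 0) -> pd.DataFrame:
    """Star-allele baseline vs two- and three-gene GVB models.

    For each cohort (discovery, replication, combined) and each predictor —
    the categorical PM+IM risk arm, and each GVB gene set thresholded at its
    own per-cohort Youden cutoff — emits the 2x2 counts, the derived
    metrics, and the AUC (undefined for the binary baseline beyond its
    single operating point; reported from the 0/1 indicator).
    """
    missing = set(subjects["subject_id"]) - set(profiles.index)
    missing |= set(subjects["subject_id"]) - set(calls.index)
    if missing:
        raise ValueError(f"predictors missing for subjects: "
                         f"{sorted(missing)[:5]}")
    rows = []
    cohorts = {"discovery": subjects[subjects["cohort"] == "discovery"],
               "replication": subjects[subjects["cohort"] == "replication"],
               "combined": subjects}
    for cohort_name, sub in cohorts.items():
        if sub.empty:
            continue
        ids = list(sub["subject_id"])
        condition = sub["dip"].to_numpy(dtype=float) <= dip_cutoff
        predictors: dict[str, tuple[np.ndarray, float | None]] = {}
        risk = (calls.loc[ids, "combined"] == "PM+IM").to_numpy()
        predictors["CPIC NUDT15 and TPMT metabolizer"] = (risk, None)
        for label in (two_gene_label, three_gene_label):
            scores = profiles.loc[ids, label].to_numpy(dtype=float)
            if condition.any() and not condition.all():
                thr = youden_cutoff(scores, condition).threshold
            else:
                thr = np.nan
            predictors[f"GVB {label}"] = (scores, thr)
        for name, (values, thr) in predictors.items():
            degenerate = not condition.any() or condition.all()
            if thr is None:
                pred = values.astype(bool)
                auc = (None if degenerate else
                       float(roc_auc_score(condition, values.astype(float))))
            else:
                pred = (np.zeros_like(values, dtype=bool) if np.isnan(thr)
                        else classify_by_gvb(values, thr))
                auc = (None if degenerate else
                       roc_auc(values, condition, direction="lower",
                               n_bootstrap=n_bootstrap, seed=seed).auc)
            table = confusion_from_predictions(condition, pred)
            m = confusion_metrics(table)
            rows.append({
                "cohort": cohort_name, "predictor": name,
                "dip_cutoff": dip_cutoff,
                "threshold": thr, "tp": table.tp, "fp": table.fp,
                "fn": table.fn, "tn": table.tn,
                "sensitivity": m.sensitivity, "specificity": m.specificity,
                "ppv": m.ppv, "npv": m.npv, "accuracy": m.accuracy,
                "auc": auc,
            })
    return pd.DataFrame(rows)


def single_gene_contribution(subjects: pd.DataFrame, profiles: pd.DataFrame,
                             calls: pd.DataFrame,
                             crim1_genotypes: Mapping[str, float] | pd.Series,
                             gene: str,
                             dip_cutoffs: Sequence[float] = DIP_CUTOFFS,
                             n_bootstrap: int = 0, seed: int = 0,
                             ) -> dict[float, RocResult | None]:
    """Single-gene ROC after controlling for the other two genes.

    Subset rules: CRIM1 is scored on subjects wild-type (NM) for both NUDT15
    and TPMT; NUDT15 on subjects wild-type for TPMT who are not homozygous
    for the masked CRIM1 variant; TPMT symmetrically with NUDT15.  Returns
    {dip_cutoff: RocResult or None when the subset is degenerate}.
    """
    if gene not in {"CRIM1", "NUDT15", "TPMT"}:
        raise ValueError(f"unknown gene {gene!r}")
    ids = subjects["subject_id"]
    crim1 = pd.Series(crim1_genotypes).reindex(ids)
    hom = crim1.to_numpy(dtype=float) == 2
    nm = {g: calls.loc[ids, g].to_numpy() == "NM" for g in ("NUDT15", "TPMT")}
    if gene == "CRIM1":
        keep = nm["NUDT15"] & nm["TPMT"]
    elif gene == "NUDT15":
        keep = nm["TPMT"] & ~hom
    else:
        keep = nm["NUDT15"] & ~hom
    sub = subjects[keep]
    out: dict[float, RocResult | None] = {}
    for cutoff in dip_cutoffs:
        if sub.empty:
            out[cutoff] = None
            continue
        condition = sub["dip"].to_numpy(dtype=float) <= cutoff
        if not condition.any() or condition.all():
            out[cutoff] = None
            continue
        scores = profiles.loc[sub["subject_id"], gene].to_numpy(dtype=float)
        if np.ptp(scores) == 0:
            out[cutoff] = None  # constant predictor: ROC undefined
            continue
        out[cutoff] = roc_auc(scores, condition, direction="lower",
                              n_bootstrap=n_bootstrap, seed=seed,
                              dip_cutoff=cutoff)
    return out
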