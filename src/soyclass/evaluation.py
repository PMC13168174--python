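"""Confusion-matrix evaluation suite, severity analysis, and decisions.

Per-class metrics are computed one-vs-rest: the focal class is positive,
the other two classes pool into the negative class, and from the collapsed
2x2 table

    sensitivity = TP/(TP+FN)        specificity = TN/(TN+FP)
    precision   = TP/(TP+FP)        NPV         = TN/(TN+FN)
    F1          = 2*prec*sens/(prec+sens)
    balanced accuracy = (sensitivity + specificity)/2
    prevalence = (TP+FN)/n,  detection rate = TP/n,
    detection prevalence = (TP+FP)/n

Overall: accuracy = trace/n with a Wald 95% CI (z = 1.96); Cohen's kappa
(P_o - P_e)/(1 - P_e) with P_e from row/column marginals; the no-information
rate is the largest class prevalence, tested against accuracy by a one-sided
exact binomial tail; McNemar's chi-square (b - c)^2/(b + c) is reported per
one-vs-rest collapse without continuity correction.  Macro metrics are
unweighted means over the three classes.  Zero-denominator cells surface as
NaN with an explicit flag, never as 0.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .markers import PCAResult
from .selection_index import CLASS_ORDER, CLASS_RANK

_CLASS_METRICS = ("sensitivity", "specificity", "precision", "npv", "f1",
                  "balanced_accuracy", "prevalence", "detection_rate",
                  "detection_prevalence")


@dataclasses.dataclass
class ConfusionMatrix3:
    """3x3 counts indexed (true class, predicted class) in low < moderate < high order."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(CLASS_ORDER), columns=list(CLASS_ORDER))

    def __add__(self, other: "ConfusionMatrix3") -> "ConfusionMatrix3":
        return ConfusionMatrix3(self.counts + other.counts)


def confusion_matrix(preds: pd.DataFrame) -> ConfusionMatrix3:
    """Count pooled (true, predicted) pairs over the fixed class order."""
    if len(preds) == 0:
        raise ValueError("no predictions to tabulate")
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(preds["true_class"], preds["predicted_class"]):
        if t not in CLASS_RANK or p not in CLASS_RANK:
            raise ValueError(f"unknown class label in ({t!r}, {p!r})")
        counts[CLASS_RANK[t], CLASS_RANK[p]] += 1
    return ConfusionMatrix3(counts)


def _safe_ratio(num: float, den: float, undefined: list, name: str) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def one_vs_rest_counts(cm: ConfusionMatrix3, focal: str) -> dict:
    k = CLASS_RANK[focal]
    c = cm.counts
    tp = int(c[k, k])
    fn = int(c[k].sum() - tp)
    fp = int(c[:, k].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)
    return {"tp": tp, "tn": tn, "fp": fp, "fn": fn}


def class_metrics(cm: ConfusionMatrix3, focal: str) -> dict:
    """One-vs-rest metrics for the focal class; NaN + flag on zero denominators."""
    if focal not in CLASS_RANK:
        raise ValueError(f"unknown class {focal!r}")
    t = one_vs_rest_counts(cm, focal)
    tp, tn, fp, fn = t["tp"], t["tn"], t["fp"], t["fn"]
    n = cm.total
    undefined: list[str] = []
    sens = _safe_ratio(tp, tp + fn, undefined, "sensitivity")
    spec = _safe_ratio(tn, tn + fp, undefined, "specificity")
    prec = _safe_ratio(tp, tp + fp, undefined, "precision")
    npv = _safe_ratio(tn, tn + fn, undefined, "npv")
    f1 = _safe_ratio(2 * prec * sens, prec + sens, undefined, "f1") \
        if np.isfinite(prec) and np.isfinite(sens) else float("nan")
    if not (np.isfinite(prec) and np.isfinite(sens)) and "f1" not in undefined:
        undefined.append("f1")
    bal = (sens + spec) / 2.0
    return {
        "class": focal, **t,
        "sensitivity": sens, "specificity": spec, "precision": prec, "npv": npv,
        "f1": f1, "balanced_accuracy": bal,
        "prevalence": _safe_ratio(tp + fn, n, undefined, "prevalence"),
        "detection_rate": _safe_ratio(tp, n, undefined, "detection_rate"),
        "detection_prevalence": _safe_ratio(tp + fp, n, undefined, "detection_prevalence"),
        "undefined": undefined,
    }


def class_metrics_table(cm: ConfusionMatrix3) -> pd.DataFrame:
    return pd.DataFrame([class_metrics(cm, c) for c in CLASS_ORDER]).set_index("class")


@dataclasses.dataclass
class OverallMetricReport:
    accuracy: float
    accuracy_ci95: tuple
    kappa: float
    p_o: float
    p_e: float
    nir: float
    p_acc_gt_nir: float
    mcnemar: pd.DataFrame           # per class: b, c, chi2, p
    macro: dict                     # macro-averaged class metrics
    n: int


def overall_metrics(cm: ConfusionMatrix3, per_class: pd.DataFrame | None = None,
                    exact_binomial: bool = True) -> OverallMetricReport:
    """Accuracy with Wald CI, kappa, NIR test, per-class McNemar, macro means."""
    if per_class is None:
        per_class = class_metrics_table(cm)
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    correct = int(np.trace(cm.counts))
    acc = correct / n
    half = 1.96 * np.sqrt(acc * (1 - acc) / n)
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    kappa = (acc - p_e) / (1 - p_e) if p_e < 1 else 1.0
    nir = float(row.max())
    if exact_binomial:
        p_acc = float(stats.binom.sf(correct - 1, n, nir))
    else:
        z = (correct - n * nir) / np.sqrt(n * nir * (1 - nir))
        p_acc = float(stats.norm.sf(z))

    rows = []
    for cls in CLASS_ORDER:
        t = one_vs_rest_counts(cm, cls)
        b, c = t["fp"], t["fn"]
        if b + c == 0:
            chi2, p = float("nan"), float("nan")
        else:
            chi2 = (b - c) ** 2 / (b + c)
            p = float(stats.chi2.sf(chi2, df=1))
        rows.append({"class": cls, "b": b, "c": c, "chi2": chi2, "p": p,
                     "undefined": b + c == 0})
    mcnemar = pd.DataFrame(rows).set_index("class")

    macro = {f"macro_{m}": float(per_class[m].mean()) for m in _CLASS_METRICS}
    return OverallMetricReport(
        accuracy=acc, accuracy_ci95=(acc - half, acc + half), kappa=float(kappa),
        p_o=acc, p_e=p_e, nir=nir, p_acc_gt_nir=p_acc, mcnemar=mcnemar,
        macro=macro, n=n)


@dataclasses.dataclass
class SeverityReport:
    """Proportions of correct / mild / extreme outcomes over pooled predictions."""

    proportions: dict
    counts: dict
    n_extreme_high_low: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError("severity proportions must sum to 1")


def severity_analysis(preds: pd.DataFrame) -> SeverityReport:
    """Classify each pooled prediction as correct, mild, or extreme.

    The ordinal distance |rank(true) - rank(pred)| in the low < moderate <
    high ordering is 0 (correct), 1 (mild, one class away) or 2 (extreme,
    confusion between the low and high ends).
    """
    if len(preds) == 0:
        raise ValueError("no predictions")
    dist = np.array([abs(CLASS_RANK[t] - CLASS_RANK[p])
                     for t, p in zip(preds["true_class"], preds["predicted_class"])])
    n = len(dist)
    counts = {"correct": int((dist == 0).sum()), "mild": int((dist == 1).sum()),
              "extreme": int((dist == 2).sum())}
    props = {k: v / n for k, v in counts.items()}
    return SeverityReport(props, counts, counts["extreme"])


@dataclasses.dataclass
class DecisionTable:
    """Per-genotype advance/discard decisions under a probability threshold."""

    table: pd.DataFrame
    threshold: float
    discard_fraction: float


def apply_decision_rule(probs: pd.DataFrame, threshold: float = 0.70) -> DecisionTable:
    """Discard genotypes whose low-class probability reaches the threshold.

    ``probs`` needs columns genotype_id and p_low (p_moderate / p_high are
    carried through when present); rows are typically per-genotype pooled
    probabilities or a screening model's output.  The boundary is inclusive:
    p_low >= threshold means discard.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    need = {"genotype_id", "p_low"}
    if not need <= set(probs.columns):
        raise ValueError(f"probability table missing columns {sorted(need - set(probs.columns))}")
    p = probs["p_low"].to_numpy(float)
    if np.any(~np.isfinite(p)) or np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ValueError("invalid low-class probabilities")
    table = probs.copy()
    table["decision"] = np.where(p >= threshold, "discard", "advance")
    table["rule"] = f"p_low>={threshold:g}"
    frac = float((table["decision"] == "discard").mean())
    return DecisionTable(table, threshold, frac)


@dataclasses.dataclass
class DiversitySummary:
    """PC1-PC2 geometry of the advance and discard groups."""

    centroids: pd.DataFrame          # group x (pc1, pc2)
    dispersion: pd.Series            # mean distance to own centroid
    overlap_coefficient: float       # discard points inside advance 95% radius
    flags: list


def diversity_diagnostic(pca: PCAResult, decisions: DecisionTable) -> DiversitySummary:
    """Overlap of advance and discard groups in the marker PCA plane.

    Reports per-group centroids and dispersions on PC1-PC2 and the fraction
    of discard points lying inside the advance group's 95th-percentile radius
    around its centroid; substantial overlap means the decisions are not
    explained by overall genetic similarity alone.
    """
    scores = pd.DataFrame(pca.scores[:, :2], index=pca.genotype_ids, columns=["pc1", "pc2"])
    tbl = decisions.table
    missing = sorted(set(tbl["genotype_id"]) - set(scores.index))
    if missing:
        raise KeyError(f"no PCA scores for decided genotypes: {missing[:5]}")
    flags = []
    centroids, dispersion = {}, {}
    groups = {g: scores.loc[tbl.loc[tbl["decision"] == g, "genotype_id"]].to_numpy()
              for g in ("advance", "discard")}
    for name, pts in groups.items():
        if len(pts) == 0:
            flags.append(f"{name}: empty group")
            centroids[name] = (float("nan"), float("nan"))
            dispersion[name] = float("nan")
            continue
        c = pts.mean(axis=0)
        centroids[name] = tuple(c)
        if len(pts) < 3:
            flags.append(f"{name}: fewer than 3 members, dispersion undefined")
            dispersion[name] = float("nan")
        else:
            dispersion[name] = float(np.linalg.norm(pts - c, axis=1).mean())
    adv, dis = groups["advance"], groups["discard"]
    if len(adv) >= 3 and len(dis) > 0:
        c = adv.mean(axis=0)
        radius = float(np.percentile(np.linalg.norm(adv - c, axis=1), 95,
                                     method="higher"))
        overlap = float((np.linalg.norm(dis - c, axis=1) <= radius).mean())
    else:
        overlap = float("nan")
        flags.append("overlap undefined (advance group too small or discard empty)")
    return DiversitySummary(
        centroids=pd.DataFrame(centroids, index=["pc1", "pc2"]).T,
        dispersion=pd.Series(dispersion),
        overlap_coefficient=overlap,
        flags=flags)


def pooled_probabilities(preds: pd.DataFrame) -> pd.DataFrame:
    """Average out-of-fold class probabilities per genotype across repetitions."""
    cols = ["p_low", "p_moderate", "p_high"]
    out = preds.groupby("genotype_id", as_index=False)[cols].mean()
    out[cols] = out[cols].div(out[cols].sum(axis=1), axis=0)
    return out


def report_frames(preds: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Assemble the standard report tables from pooled predictions."""
    cm = confusion_matrix(preds)
    per_class = class_metrics_table(cm)
    overall = overall_metrics(cm, per_class)
    sev = severity_analysis(preds)
    overall_rows = {
        "accuracy": overall.accuracy,
        "ci95_lower": overall.accuracy_ci95[0],
        "ci95_upper": overall.accuracy_ci95[1],
        "kappa": overall.kappa,
        "nir": overall.nir,
        "p_acc_gt_nir": overall.p_acc_gt_nir,
        **overall.macro,
    }
    for cls in CLASS_ORDER:
        overall_rows[f"mcnemar_chi2_{cls}"] = overall.mcnemar.loc[cls, "chi2"]
        overall_rows[f"mcnemar_p_{cls}"] = overall.mcnemar.loc[cls, "p"]
    return {
        "confusion_matrix": cm.to_frame(),
        "class_metrics": per_class.drop(columns=["undefined"]),
        "overall_metrics": pd.DataFrame([overall_rows]),
        "severity": pd.DataFrame([{**sev.proportions,
                                   "n_extreme_high_low": sev.n_extreme_high_low}]),
    }
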