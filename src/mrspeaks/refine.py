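"""Data-driven refinement of the two-step rule scheme.

Given a labelled cohort of ratio vectors, the refinement procedure
re-derives the classifier:

1. one-way ANOVA across the three tumour types discards ratios whose
   means do not differ (P >= 0.05); no multiple-testing correction is
   applied;
2. two-tailed Welch t-tests quantify the pilocytic astrocytoma (PA)
   versus rest and medulloblastoma (MB) versus ependymoma (EP)
   contrasts;
3. ROC AUCs are computed for four contrasts (each class versus all, and
   EP versus MB); AUCs are reported orientation-free (max of a, 1-a)
   with a direction flag;
4. step 1 takes every retained ratio whose PA-versus-rest AUC exceeds
   0.9 (as a conjunction); step 2 takes the single best EP-versus-MB
   ratio, with the next two recorded as check ratios;
5. each selected ratio gets the cutoff maximising sensitivity plus
   specificity (Youden), scanned over midpoints of adjacent unique
   scores plus infinite sentinels, ties broken toward specificity;
6. the resulting scheme is evaluated on the input cohort.

The module follows the statsmodels idiom: build a
:class:`RatioRuleModel` from a cohort table, call :meth:`fit`, and read
estimates, diagnostics and a ``summary()`` off the returned
:class:`RatioRuleResults`.  :func:`refine_scheme` is the one-call
convenience wrapper.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .rules import (
    CLASS_LABELS, RATIO_NAMES, Check, Condition, EvaluationResult,
    RuleScheme, RuleStep, evaluate_scheme,
)

AUC_CONTRASTS = ("pa_vs_all", "ep_vs_all", "mb_vs_all", "ep_vs_mb")


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F statistic and p-value."""
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if len(g) < 2:
            raise ValueError(f"ANOVA group {i} has fewer than 2 observations")
    f, p = stats.f_oneway(*arrays)
    if np.isnan(f):  # all values identical in every group
        return 0.0, 1.0
    return float(f), float(p)


def two_tailed_t(group_a, group_b) -> float:
    """Two-tailed Welch (unequal-variance) t-test p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test groups need at least 2 observations each")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):  # zero variance in both groups
        return 1.0 if float(np.mean(a)) == float(np.mean(b)) else 0.0
    return float(p)


def roc_auc(scores, labels) -> tuple[float, str]:
    """Orientation-free ROC AUC with a direction flag.

    The AUC is the probability that a random positive outscores a random
    negative, ties counting one half.  The returned value is
    ``max(a, 1 - a)``; ``direction`` records whether high (``"high"``)
    or low (``"low"``) scores indicate the positive class.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("ROC AUC needs both classes present")
    a = float(roc_auc_score(labels, scores))
    if a >= 0.5:
        return a, "high"
    return 1.0 - a, "low"


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    direction: str          # positives lie "high" or "low" of the cutoff
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity


def optimal_cutoff(scores, labels, direction: str | None = None) -> CutoffResult:
    """Threshold maximising sensitivity plus specificity.

    Candidates are the midpoints between adjacent sorted unique scores
    plus -inf and +inf sentinels, so the result is reproducible and
    equals an exhaustive scan.  A positive is predicted strictly beyond
    the cutoff (``score > cutoff`` for ``"high"``, ``score < cutoff``
    for ``"low"``), matching the strict comparators of the rule schemes.
    Ties in sensitivity+specificity are broken toward higher
    specificity, then toward the more conservative (extreme) cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("cutoff optimisation needs both classes present")
    if direction is None:
        _, direction = roc_auc(scores, labels)
    if direction not in ("high", "low"):
        raise ValueError(f"direction must be 'high' or 'low', got {direction!r}")

    unique = np.unique(scores)
    candidates = np.concatenate((
        [-np.inf], (unique[:-1] + unique[1:]) / 2.0, [np.inf]))
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)

    best: CutoffResult | None = None
    for t in candidates:
        predicted = scores > t if direction == "high" else scores < t
        sens = float((predicted & labels).sum()) / n_pos
        spec = float((~predicted & ~labels).sum()) / n_neg
        cand = CutoffResult(float(t), direction, sens, spec)
        if best is None or cand.youden > best.youden + 1e-12:
            best = cand
        elif abs(cand.youden - best.youden) <= 1e-12:
            if cand.specificity > best.specificity + 1e-12:
                best = cand
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Report container
# ---------------------------------------------------------------------------

@dataclass
class RefinementReport:
    """Per-ratio diagnostics and the refined rule scheme."""

    anova: pd.DataFrame            # index ratio, columns F, p, retained
    t_tests: pd.DataFrame          # index ratio, columns pa_vs_other, mb_vs_ep
    aucs: pd.DataFrame             # index ratio, columns the four contrasts
    auc_directions: pd.DataFrame   # same shape, "high"/"low"
    step1_ratios: list
    step1_cutoffs: dict            # ratio -> CutoffResult
    step2_ratio: str | None
    step2_cutoff: CutoffResult | None
    step2_checks: list
    scheme: RuleScheme
    evaluation: EvaluationResult
    n_per_class: dict

    def to_dict(self) -> dict:
        return {
            "n_per_class": {k: int(v) for k, v in self.n_per_class.items()},
            "anova": {
                r: {"F": float(row["F"]), "p": float(row["p"]),
                    "retained": bool(row["retained"])}
                for r, row in self.anova.iterrows()
            },
            "t_tests": {
                r: {c: float(row[c]) for c in self.t_tests.columns}
                for r, row in self.t_tests.iterrows()
            },
            "aucs": {
                r: {c: (None if pd.isna(row[c]) else float(row[c]))
                    for c in self.aucs.columns}
                for r, row in self.aucs.iterrows()
            },
            "step1": {
                ratio: {
                    "cutoff": float(res.cutoff),
                    "direction": res.direction,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
                for ratio, res in self.step1_cutoffs.items()
            },
            "step2": None if self.step2_ratio is None else {
                "ratio": self.step2_ratio,
                "cutoff": float(self.step2_cutoff.cutoff),
                "direction": self.step2_cutoff.direction,
                "sensitivity": self.step2_cutoff.sensitivity,
                "specificity": self.step2_cutoff.specificity,
                "checks": list(self.step2_checks),
            },
            "scheme": self.scheme.to_dict(),
            "evaluation": self.evaluation.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class RatioRuleModel:
    """Two-step rule-scheme refinement, fitted to a labelled cohort.

    Parameters
    ----------
    cohort : DataFrame
        Rows are cases; must carry ``true_class`` in {PA, EP, MB} and
        the nine ratio columns.  Rows with other labels are rejected --
        subset rare tumours out first.
    anova_alpha : float
        Discard threshold for the ANOVA prefilter (default 0.05).
    step1_auc_threshold : float
        PA-versus-rest AUC a ratio must exceed to join step 1
        (default 0.9).
    """

    def __init__(self, cohort: pd.DataFrame, *, anova_alpha: float = 0.05,
                 step1_auc_threshold: float = 0.9,
                 min_per_class: int = 4):
        missing = [c for c in RATIO_NAMES if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort is missing ratio columns {missing}")
        bad = set(cohort["true_class"]) - set(CLASS_LABELS)
        if bad:
            raise ValueError(
                f"cohort labels outside {CLASS_LABELS}: {sorted(bad)}")
        counts = cohort["true_class"].value_counts()
        for label in CLASS_LABELS:
            if counts.get(label, 0) < min_per_class:
                raise ValueError(
                    f"need at least {min_per_class} cases of {label}, "
                    f"got {counts.get(label, 0)}"
                )
        # canonical case order so the fit is invariant to row permutations
        self.cohort = cohort.sort_values("case_id").reset_index(drop=True)
        self.anova_alpha = anova_alpha
        self.step1_auc_threshold = step1_auc_threshold

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RatioRuleModel":
        from .simulate import read_cohort_csv

        return cls(read_cohort_csv(path), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "RatioRuleResults":
        cohort = self.cohort
        labels = cohort["true_class"]
        groups = {c: cohort.loc[labels == c] for c in CLASS_LABELS}
        n_per_class = {c: len(g) for c, g in groups.items()}

        anova_rows = []
        for ratio in RATIO_NAMES:
            f, p = anova_oneway(*(groups[c][ratio] for c in CLASS_LABELS))
            anova_rows.append(
                {"ratio": ratio, "F": f, "p": p, "retained": p < self.anova_alpha})
        anova = pd.DataFrame(anova_rows).set_index("ratio")

        t_rows = []
        for ratio in RATIO_NAMES:
            pa = groups["PA"][ratio]
            other = cohort.loc[labels != "PA", ratio]
            t_rows.append({
                "ratio": ratio,
                "pa_vs_other": two_tailed_t(pa, other),
                "mb_vs_ep": two_tailed_t(groups["MB"][ratio], groups["EP"][ratio]),
            })
        t_tests = pd.DataFrame(t_rows).set_index("ratio")

        contrast_labels = {
            "pa_vs_all": (labels == "PA").to_numpy(),
            "ep_vs_all": (labels == "EP").to_numpy(),
            "mb_vs_all": (labels == "MB").to_numpy(),
        }
        ep_mb_mask = labels.isin(["EP", "MB"]).to_numpy()

        auc_values = pd.DataFrame(index=list(RATIO_NAMES),
                                  columns=list(AUC_CONTRASTS), dtype=float)
        auc_dir = pd.DataFrame(index=list(RATIO_NAMES),
                               columns=list(AUC_CONTRASTS), dtype=object)
        for ratio in RATIO_NAMES:
            scores = cohort[ratio].to_numpy(dtype=float)
            for contrast, mask in contrast_labels.items():
                a, d = roc_auc(scores, mask)
                auc_values.loc[ratio, contrast] = a
                auc_dir.loc[ratio, contrast] = d
            a, d = roc_auc(scores[ep_mb_mask],
                           (labels[ep_mb_mask] == "EP").to_numpy())
            auc_values.loc[ratio, "ep_vs_mb"] = a
            auc_dir.loc[ratio, "ep_vs_mb"] = d

        retained = [r for r in RATIO_NAMES if anova.loc[r, "retained"]]

        # step 1: conjunction of all strong PA-versus-rest discriminators
        step1_ratios = [
            r for r in retained
            if auc_values.loc[r, "pa_vs_all"] > self.step1_auc_threshold
        ]
        pa_mask = contrast_labels["pa_vs_all"]
        step1_cutoffs = {
            r: optimal_cutoff(cohort[r].to_numpy(dtype=float), pa_mask,
                              auc_dir.loc[r, "pa_vs_all"])
            for r in step1_ratios
        }

        # step 2: the single best EP-versus-MB separator among the rest,
        # the next two strongest recorded as checks
        step2_candidates = sorted(
            (r for r in retained if r not in step1_ratios),
            key=lambda r: (-auc_values.loc[r, "ep_vs_mb"], RATIO_NAMES.index(r)),
        )
        step2_ratio = step2_candidates[0] if step2_candidates else None
        step2_checks = step2_candidates[1:3]
        step2_cutoff = None
        if step2_ratio is not None:
            mb_labels = (labels[ep_mb_mask] == "MB").to_numpy()
            step2_cutoff = optimal_cutoff(
                cohort.loc[ep_mb_mask, step2_ratio].to_numpy(dtype=float),
                mb_labels)

        steps = []
        if step1_ratios:
            steps.append(RuleStep("PA", tuple(
                Condition(r, ">" if step1_cutoffs[r].direction == "high" else "<",
                          step1_cutoffs[r].cutoff)
                for r in step1_ratios
            )))
        if step2_ratio is not None:
            op = ">" if step2_cutoff.direction == "high" else "<"
            steps.append(RuleStep("MB", (Condition(step2_ratio, op,
                                                   step2_cutoff.cutoff),)))
        scheme = RuleScheme(
            name="refined",
            steps=tuple(steps),
            else_class="EP",
            checks=tuple(Check(r) for r in step2_checks),
            notes="Scheme refined from a labelled cohort by ANOVA prefilter, "
                  "ROC-AUC ranking and Youden cutoff optimisation.",
        )
        evaluation = evaluate_scheme(cohort, scheme)

        report = RefinementReport(
            anova=anova, t_tests=t_tests, aucs=auc_values,
            auc_directions=auc_dir,
            step1_ratios=step1_ratios, step1_cutoffs=step1_cutoffs,
            step2_ratio=step2_ratio, step2_cutoff=step2_cutoff,
            step2_checks=list(step2_checks),
            scheme=scheme, evaluation=evaluation,
            n_per_class=n_per_class,
        )
        return RatioRuleResults(self, report)


class RatioRuleResults:
    """Fit results: diagnostics, the refined scheme and its evaluation."""

    def __init__(self, model: RatioRuleModel, report: RefinementReport):
        self.model = model
        self.report = report

    # estimate-style accessors
    @property
    def scheme(self) -> RuleScheme:
        return self.report.scheme

    @property
    def cutoffs(self) -> dict[str, float]:
        out = {r: res.cutoff for r, res in self.report.step1_cutoffs.items()}
        if self.report.step2_ratio is not None:
            out[self.report.step2_ratio] = self.report.step2_cutoff.cutoff
        return out

    @property
    def aucs(self) -> pd.DataFrame:
        return self.report.aucs

    @property
    def confusion(self) -> pd.DataFrame:
        return self.report.evaluation.confusion

    @property
    def overall_rate_pct(self) -> float:
        return self.report.evaluation.overall_rate_pct

    def scatter_data(self) -> pd.DataFrame:
        """Per-case coordinates on the classification axes (step-1 ratio
        pair and step-2 ratio), for scatterplot export."""
        columns = ["case_id", "true_class"]
        columns += list(self.report.step1_ratios)
        if self.report.step2_ratio is not None:
            columns.append(self.report.step2_ratio)
        seen = list(dict.fromkeys(columns))
        return self.model.cohort[seen].copy()

    def plot_scatter(self, ax=None):
        """Scatter the cohort on the first two selected step-1 ratios."""
        import matplotlib.pyplot as plt

        ratios = list(self.report.step1_ratios)[:2]
        if len(ratios) < 2:
            raise ValueError("need two step-1 ratios for a scatterplot")
        if ax is None:
            _, ax = plt.subplots()
        markers = {"PA": "s", "EP": "o", "MB": "*"}
        for label, sub in self.model.cohort.groupby("true_class"):
            ax.scatter(sub[ratios[0]], sub[ratios[1]],
                       marker=markers.get(label, "."), label=label)
        for ratio, axis in zip(ratios, ("axvline", "axhline")):
            getattr(ax, axis)(self.report.step1_cutoffs[ratio].cutoff,
                              linestyle="--", color="grey")
        ax.set_xlabel(ratios[0])
        ax.set_ylabel(ratios[1])
        ax.legend()
        return ax

    def summary(self) -> str:
        rep = self.report
        lines = []
        lines.append("Two-step ratio rule refinement")
        lines.append("=" * 62)
        counts = ", ".join(f"{c}={rep.n_per_class[c]}" for c in CLASS_LABELS)
        lines.append(f"Cases: {counts}")
        lines.append("")
        lines.append("Per-ratio diagnostics")
        lines.append("-" * 62)
        header = (f"{'ratio':<12}{'ANOVA p':>10}{'t PA|rest':>11}"
                  f"{'t MB|EP':>10}{'AUC PA':>8}{'AUC EP|MB':>10}")
        lines.append(header)
        for ratio in RATIO_NAMES:
            marker = " " if rep.anova.loc[ratio, "retained"] else "d"
            lines.append(
                f"{ratio:<12}{rep.anova.loc[ratio, 'p']:>10.4f}"
                f"{rep.t_tests.loc[ratio, 'pa_vs_other']:>11.4f}"
                f"{rep.t_tests.loc[ratio, 'mb_vs_ep']:>10.4f}"
                f"{rep.aucs.loc[ratio, 'pa_vs_all']:>8.3f}"
                f"{rep.aucs.loc[ratio, 'ep_vs_mb']:>9.3f}{marker}"
            )
        lines.append("(d = discarded by the ANOVA prefilter at "
                     f"P >= {self.model.anova_alpha:g})")
        lines.append("")
        lines.append("Selected scheme")
        lines.append("-" * 62)
        for i, step in enumerate(rep.scheme.steps, start=1):
            conds = " and ".join(str(c) for c in step.conditions)
            lines.append(f"step {i}: {step.label} if {conds}")
        lines.append(f"else: {rep.scheme.else_class}")
        if rep.step2_checks:
            lines.append(f"checks: {', '.join(rep.step2_checks)}")
        lines.append("")
        ev = rep.evaluation
        lines.append("In-sample evaluation")
        lines.append("-" * 62)
        lines.append(ev.confusion.to_string())
        per_class = ", ".join(
            f"{c} {ev.per_class_rate_pct[c]}%" for c in CLASS_LABELS
            if c in ev.per_class_rate_pct)
        lines.append(f"per-class correct: {per_class}")
        lines.append(
            f"overall: {ev.overall_correct[0]}/{ev.overall_correct[1]} "
            f"({ev.overall_rate_pct}%)")
        return "\n".join(lines)


def refine_scheme(cohort: pd.DataFrame, **kwargs) -> RefinementReport:
    """One-call refinement: fit :class:`RatioRuleModel` and return its
    :class:`RefinementReport`."""
    return RatioRuleModel(cohort, **kwargs).fit().report
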