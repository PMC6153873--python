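"""Metabolite ratio vectors and rule-based tumour classification.

The diagnostic scheme works on nine peak-height ratios formed from the
six measured peaks (NAA, Cr, tCho, mIns and the lipid/macromolecule
resonances at 0.9 and 1.3 ppm).  Classification is an ordered two-step
decision rule:

* step 1 assigns pilocytic astrocytoma (PA) when NAA/Cr > 2.22 and
  mIns/NAA < 0.65;
* step 2 assigns medulloblastoma (MB) when mIns/tCho < 0.85;
* everything else is called ependymoma (EP).

Cutoff comparisons are strict, so a ratio sitting exactly on a cutoff
falls through to the next step.  Check ratios (Cr/tCho and NAA/tCho for
the updated scheme) never change the label; they only raise flags.
Schemes are plain data and serialise to YAML, so the published scheme,
a reconstruction of its predecessor and any newly refined scheme all
run through the same engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

RATIO_NAMES: tuple[str, ...] = (
    "cr_tcho", "naa_tcho", "mins_tcho", "naa_cr", "mins_cr",
    "mins_naa", "lmm09_tcho", "lmm13_tcho", "lmm09_lmm13",
)

CLASS_LABELS: tuple[str, ...] = ("PA", "EP", "MB")

PEAK_LONG_NAMES = {
    "naa": "N-acetyl aspartate",
    "cr": "creatine",
    "tcho": "total choline",
    "mins": "myo-inositol",
    "lmm09": "lipids/macromolecules 0.9 ppm",
    "lmm13": "lipids/macromolecules 1.3 ppm",
}

# numerator, denominator peak for each ratio
_RATIO_PARTS = {
    "cr_tcho": ("cr", "tcho"),
    "naa_tcho": ("naa", "tcho"),
    "mins_tcho": ("mins", "tcho"),
    "naa_cr": ("naa", "cr"),
    "mins_cr": ("mins", "cr"),
    "mins_naa": ("mins", "naa"),
    "lmm09_tcho": ("lmm09", "tcho"),
    "lmm13_tcho": ("lmm13", "tcho"),
    "lmm09_lmm13": ("lmm09", "lmm13"),
}


class SchemeConfigError(ValueError):
    """Raised for malformed rule-scheme configurations."""


def compute_ratios_from_heights(heights) -> dict[str, float]:
    """The nine ratios from a mapping of the six peak heights.

    Raises ``ValueError`` naming the offending peak when a denominator
    height is zero or negative.
    """
    for name in ("naa", "cr", "tcho", "lmm13"):
        if heights[name] <= 0:
            raise ValueError(
                f"zero {PEAK_LONG_NAMES[name]} height: "
                "cannot form ratios with a non-positive denominator"
            )
    return {
        ratio: heights[num] / heights[den]
        for ratio, (num, den) in _RATIO_PARTS.items()
    }


def compute_ratios(peaks) -> dict[str, float]:
    """Nine ratios from a measured :class:`~mrspeaks.measure.PeakHeightSet`."""
    return compute_ratios_from_heights(peaks.heights)


def _get_ratio(ratios, name: str) -> float:
    if isinstance(ratios, pd.Series):
        value = ratios[name]
    elif hasattr(ratios, "get"):
        value = ratios.get(name)
        if value is None:
            raise KeyError(name)
    else:
        value = getattr(ratios, name)
    return float(value)


# ---------------------------------------------------------------------------
# Rule schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Condition:
    """One strict-inequality comparison, e.g. ``naa_cr > 2.22``."""

    ratio: str
    op: str  # "<" or ">"
    cutoff: float

    def holds(self, ratios) -> bool:
        value = _get_ratio(ratios, self.ratio)
        return value > self.cutoff if self.op == ">" else value < self.cutoff

    def __str__(self) -> str:
        return f"{self.ratio} {self.op} {self.cutoff:g}"


@dataclass(frozen=True)
class RuleStep:
    """A conjunction of conditions assigning one class label."""

    label: str
    conditions: tuple[Condition, ...]

    def fires(self, ratios) -> bool:
        return all(c.holds(ratios) for c in self.conditions)


@dataclass(frozen=True)
class Check:
    """A ratio consulted after assignment to verify, never override, it.

    ``ranges`` optionally maps a class label to the (lo, hi) interval the
    ratio is expected to occupy for that class; a value outside raises a
    flag on the result.
    """

    ratio: str
    ranges: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RuleScheme:
    """An ordered two-step (or n-step) decision rule with an else-class."""

    name: str
    steps: tuple[RuleStep, ...]
    else_class: str
    checks: tuple[Check, ...] = ()
    notes: str = ""

    def __post_init__(self):
        for step in self.steps:
            for cond in step.conditions:
                if cond.ratio not in RATIO_NAMES:
                    raise SchemeConfigError(
                        f"scheme {self.name!r} references unknown ratio "
                        f"{cond.ratio!r}"
                    )
                if cond.op not in ("<", ">"):
                    raise SchemeConfigError(
                        f"scheme {self.name!r}: comparator must be '<' or '>'"
                    )
        for check in self.checks:
            if check.ratio not in RATIO_NAMES:
                raise SchemeConfigError(
                    f"scheme {self.name!r} check references unknown ratio "
                    f"{check.ratio!r}"
                )

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "steps": [
                {
                    "label": step.label,
                    "conditions": [
                        {"ratio": c.ratio, "op": c.op, "cutoff": float(c.cutoff)}
                        for c in step.conditions
                    ],
                }
                for step in self.steps
            ],
            "else_class": self.else_class,
            "checks": [
                {"ratio": c.ratio, "ranges": {k: list(v) for k, v in c.ranges.items()}}
                for c in self.checks
            ],
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RuleScheme":
        try:
            steps = tuple(
                RuleStep(
                    label=step["label"],
                    conditions=tuple(
                        Condition(c["ratio"], c["op"], float(c["cutoff"]))
                        for c in step["conditions"]
                    ),
                )
                for step in payload["steps"]
            )
            checks = tuple(
                Check(c["ratio"], {k: tuple(v) for k, v in c.get("ranges", {}).items()})
                for c in payload.get("checks", [])
            )
            return cls(
                name=payload["name"],
                steps=steps,
                else_class=payload["else_class"],
                checks=checks,
                notes=payload.get("notes", ""),
            )
        except (KeyError, TypeError) as exc:
            raise SchemeConfigError(f"malformed scheme config: {exc}") from exc

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RuleScheme":
        with open(path, "r", encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise SchemeConfigError(f"{path}: not a scheme mapping")
        return cls.from_dict(payload)


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    step_fired: int           # 1-based step index; 0 means the else-class
    check_flags: tuple[str, ...] = ()
    check_values: dict = field(default_factory=dict)


def classify_with_scheme(ratios, scheme: RuleScheme) -> ClassificationResult:
    """Apply an ordered rule scheme; the first satisfied step assigns."""
    label = scheme.else_class
    step_fired = 0
    for i, step in enumerate(scheme.steps, start=1):
        if step.fires(ratios):
            label = step.label
            step_fired = i
            break
    flags: list[str] = []
    check_values: dict[str, float] = {}
    for check in scheme.checks:
        value = _get_ratio(ratios, check.ratio)
        check_values[check.ratio] = value
        expected = check.ranges.get(label)
        if expected is not None:
            lo, hi = expected
            if not (lo <= value <= hi):
                flags.append(
                    f"{check.ratio}={value:.3f} outside expected "
                    f"[{lo:g}, {hi:g}] for {label}"
                )
    return ClassificationResult(label, step_fired, tuple(flags), check_values)


def classify_updated(ratios) -> ClassificationResult:
    """The updated two-step scheme, hard-coded.

    PA when NAA/Cr > 2.22 and mIns/NAA < 0.65; otherwise MB when
    mIns/tCho < 0.85; otherwise EP.  Cr/tCho and NAA/tCho are recorded
    as check ratios only.
    """
    naa_cr = _get_ratio(ratios, "naa_cr")
    mins_naa = _get_ratio(ratios, "mins_naa")
    mins_tcho = _get_ratio(ratios, "mins_tcho")
    check_values = {
        "cr_tcho": _get_ratio(ratios, "cr_tcho"),
        "naa_tcho": _get_ratio(ratios, "naa_tcho"),
    }
    if naa_cr > 2.22 and mins_naa < 0.65:
        return ClassificationResult("PA", 1, (), check_values)
    if mins_tcho < 0.85:
        return ClassificationResult("MB", 2, (), check_values)
    return ClassificationResult("EP", 0, (), check_values)


# ---------------------------------------------------------------------------
# Shipped schemes
# ---------------------------------------------------------------------------

def load_shipped_scheme(name: str) -> RuleScheme:
    """Load one of the packaged scheme configs by stem name.

    Available: ``updated``, ``original_reconstruction``,
    ``reoptimized_original``.
    """
    ref = resources.files("mrspeaks").joinpath(f"schemes/{name}.yaml")
    with resources.as_file(ref) as path:
        return RuleScheme.from_yaml(path)


UPDATED_SCHEME = RuleScheme(
    name="updated",
    steps=(
        RuleStep("PA", (Condition("naa_cr", ">", 2.22),
                        Condition("mins_naa", "<", 0.65))),
        RuleStep("MB", (Condition("mins_tcho", "<", 0.85),)),
    ),
    else_class="EP",
    checks=(Check("cr_tcho"), Check("naa_tcho")),
    notes="Updated two-step scheme derived from the combined 53-case "
          "multicentre dataset.",
)


# ---------------------------------------------------------------------------
# Cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Confusion matrix and classification rates for a labelled cohort."""

    confusion: pd.DataFrame          # rows true class, columns predicted
    per_class_correct: dict          # label -> (n_correct, n_total)
    per_class_rate_pct: dict         # label -> int percent
    overall_correct: tuple           # (n_correct, n_total)
    overall_rate_pct: float          # one decimal
    pa_vs_rest_correct: tuple        # (n_correct, n_total)
    pa_vs_rest_rate_pct: int
    predictions: pd.DataFrame        # case_id, true_class, predicted, step

    def to_dict(self) -> dict:
        return {
            "confusion": {
                t: {p: int(self.confusion.loc[t, p]) for p in self.confusion.columns}
                for t in self.confusion.index
            },
            "per_class": {
                label: {
                    "n_correct": int(n), "n_total": int(d),
                    "rate_pct": int(self.per_class_rate_pct[label]),
                }
                for label, (n, d) in self.per_class_correct.items()
            },
            "overall": {
                "n_correct": int(self.overall_correct[0]),
                "n_total": int(self.overall_correct[1]),
                "rate_pct": float(self.overall_rate_pct),
            },
            "pa_vs_rest": {
                "n_correct": int(self.pa_vs_rest_correct[0]),
                "n_total": int(self.pa_vs_rest_correct[1]),
                "rate_pct": int(self.pa_vs_rest_rate_pct),
            },
        }


def evaluate_scheme(cohort: pd.DataFrame, scheme: RuleScheme) -> EvaluationResult:
    """Classify every cohort row with ``scheme`` and tally the outcome.

    The cohort must carry the nine ratio columns and a ``true_class``
    column restricted to the three main tumour types.  Per-class rates
    are rounded to the nearest integer percent and the overall rate to
    one decimal, matching the usual reporting convention; raw counts are
    kept alongside so no information is lost to rounding.
    """
    if len(cohort) == 0:
        raise ValueError("cannot evaluate an empty cohort")
    bad = set(cohort["true_class"]) - set(CLASS_LABELS)
    if bad:
        raise ValueError(
            f"cohort contains labels outside {CLASS_LABELS}: {sorted(bad)}; "
            "subset to the three main tumour types first"
        )
    records = []
    for _, row in cohort.iterrows():
        result = classify_with_scheme(row, scheme)
        records.append({
            "case_id": row.get("case_id", ""),
            "true_class": row["true_class"],
            "predicted_class": result.label,
            "step_fired": result.step_fired,
            "flags": "; ".join(result.check_flags),
        })
    predictions = pd.DataFrame(records)
    confusion = pd.crosstab(
        predictions["true_class"], predictions["predicted_class"],
    ).reindex(index=CLASS_LABELS, columns=CLASS_LABELS, fill_value=0)
    confusion.index.name = "true"
    confusion.columns.name = "predicted"

    per_class_correct = {}
    per_class_rate = {}
    for label in CLASS_LABELS:
        total = int(confusion.loc[label].sum())
        if total == 0:
            continue
        correct = int(confusion.loc[label, label])
        per_class_correct[label] = (correct, total)
        per_class_rate[label] = round(100.0 * correct / total)
    n_total = int(len(predictions))
    n_correct = int((predictions["true_class"] == predictions["predicted_class"]).sum())
    overall_pct = round(100.0 * n_correct / n_total, 1)

    true_pa = predictions["true_class"] == "PA"
    pred_pa = predictions["predicted_class"] == "PA"
    pa_correct = int((true_pa == pred_pa).sum())
    pa_pct = round(100.0 * pa_correct / n_total)

    return EvaluationResult(
        confusion=confusion,
        per_class_correct=per_class_correct,
        per_class_rate_pct=per_class_rate,
        overall_correct=(n_correct, n_total),
        overall_rate_pct=overall_pct,
        pa_vs_rest_correct=(pa_correct, n_total),
        pa_vs_rest_rate_pct=pa_pct,
        predictions=predictions,
    )


def ratio_consistency_ok(ratios, tol: float = 1e-6) -> bool:
    """True when the nine ratios are mutually consistent, e.g.
    ``naa_cr * cr_tcho == naa_tcho`` within ``tol`` (relative)."""
    identities = (
        ("naa_cr", "cr_tcho", "naa_tcho"),
        ("mins_cr", "cr_tcho", "mins_tcho"),
        ("mins_naa", "naa_tcho", "mins_tcho"),
    )
    for a, b, c in identities:
        lhs = _get_ratio(ratios, a) * _get_ratio(ratios, b)
        rhs = _get_ratio(ratios, c)
        if not math.isclose(lhs, rhs, rel_tol=tol, abs_tol=tol):
            return False
    return True
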