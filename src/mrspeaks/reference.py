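"""Reference ratio profiles and benchmark cohorts.

Two kinds of fixed inputs live here:

* mean peak-height-ratio profiles for four rare cerebellar tumour types
  (atypical teratoid rhabdoid tumour, diffuse astrocytoma, ganglioglioma
  and a high-grade lesion of undetermined nature) from a multicentre
  1.5-T paediatric short-TE cohort, kept exactly as reported; and

* small engineered cohorts of internally consistent ratio vectors built
  so that the rule schemes reproduce the published multicentre confusion
  counts.  These make the reported classification rates recomputable end
  to end: the cohorts are classified at run time, never tabulated.

Rare-tumour rows are means over one to three cases, so the nine ratios
of a row are not mutually consistent (a mean of ratios is not a ratio of
means) and two lipid/macromolecule ratios of the diffuse astrocytoma are
exactly zero.
"""

from __future__ import annotations

import pandas as pd

from .rules import RATIO_NAMES

# Mean ratio profiles for rare cerebellar tumours (a.u./a.u.).
# ATRT values are means over the reported cases (SEM kept alongside).
RARE_TUMOUR_PROFILES: dict[str, dict[str, float]] = {
    "ATRT": {
        "cr_tcho": 0.123, "naa_tcho": 0.584, "mins_tcho": 0.386,
        "naa_cr": 4.502, "mins_naa": 0.547, "mins_cr": 2.593,
        "lmm09_tcho": 0.661, "lmm13_tcho": 0.838, "lmm09_lmm13": 1.799,
    },
    "diffuse_astrocytoma": {
        "cr_tcho": 1.245, "naa_tcho": 1.129, "mins_tcho": 1.299,
        "naa_cr": 0.907, "mins_naa": 1.150, "mins_cr": 1.043,
        "lmm09_tcho": 0.152, "lmm13_tcho": 0.000, "lmm09_lmm13": 0.000,
    },
    "ganglioglioma": {
        "cr_tcho": 0.651, "naa_tcho": 1.005, "mins_tcho": 0.499,
        "naa_cr": 1.543, "mins_naa": 0.496, "mins_cr": 0.766,
        "lmm09_tcho": 0.283, "lmm13_tcho": 0.448, "lmm09_lmm13": 0.632,
    },
    "high_grade": {
        "cr_tcho": 0.590, "naa_tcho": 0.967, "mins_tcho": 0.872,
        "naa_cr": 1.638, "mins_naa": 0.903, "mins_cr": 1.479,
        "lmm09_tcho": 0.521, "lmm13_tcho": 1.902, "lmm09_lmm13": 0.274,
    },
}

# Standard error of the mean for the ATRT profile.
ATRT_SEM: dict[str, float] = {
    "cr_tcho": 0.050, "naa_tcho": 0.299, "mins_tcho": 0.293,
    "naa_cr": 0.580, "mins_naa": 0.222, "mins_cr": 1.318,
    "lmm09_tcho": 0.451, "lmm13_tcho": 0.515, "lmm09_lmm13": 0.274,
}


def rare_tumour_profiles() -> pd.DataFrame:
    """Rare-tumour mean profiles as a cohort-style table.

    ``true_class`` is ``OTHER:<subtype>`` so these rows are excluded from
    three-class evaluation but can be pushed through the classifiers as
    worked examples.
    """
    rows = []
    for subtype, ratios in RARE_TUMOUR_PROFILES.items():
        row = {"case_id": subtype, "true_class": f"OTHER:{subtype}"}
        row.update({name: ratios[name] for name in RATIO_NAMES})
        row["source_id"] = "reference"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Engineered benchmark cohorts
# ---------------------------------------------------------------------------

# Height templates (a.u.) whose derived ratios land deterministically in a
# given branch of the updated two-step scheme.  All six peak heights are
# given so every row carries a full, internally consistent ratio vector.
_UPDATED_TEMPLATES = {
    # NAA/Cr = 3.0 > 2.22 and mIns/NAA = 0.33 < 0.65  ->  PA on step 1
    "PA": {"naa": 9.0, "cr": 3.0, "tcho": 10.0, "mins": 3.0,
           "lmm09": 2.0, "lmm13": 3.0},
    # step 1 fails, mIns/tCho = 0.4 < 0.85  ->  MB on step 2
    "MB": {"naa": 5.0, "cr": 5.0, "tcho": 10.0, "mins": 4.0,
           "lmm09": 6.0, "lmm13": 9.0},
    # step 1 fails, mIns/tCho = 1.3  ->  EP on the else branch
    "EP": {"naa": 6.0, "cr": 6.0, "tcho": 10.0, "mins": 13.0,
           "lmm09": 3.0, "lmm13": 4.0},
}

# Templates for the reconstructed original scheme
# (step 1: NAA/Cr > 4 and mIns/NAA < 1.35 -> PA;
#  step 2: Cr/tCho < 0.45 -> MB; else EP).
_ORIGINAL_TEMPLATES = {
    "PA": {"naa": 10.0, "cr": 2.0, "tcho": 10.0, "mins": 3.0,
           "lmm09": 2.0, "lmm13": 3.0},
    "MB": {"naa": 5.0, "cr": 3.0, "tcho": 10.0, "mins": 4.0,
           "lmm09": 6.0, "lmm13": 9.0},
    "EP": {"naa": 6.0, "cr": 6.0, "tcho": 10.0, "mins": 13.0,
           "lmm09": 3.0, "lmm13": 4.0},
}

# Published multicentre confusion counts, rows = histopathological truth,
# entries = cases steered into each predicted class.
UPDATED_SCHEME_CONFUSION = {
    "PA": {"PA": 15, "EP": 1, "MB": 0},   # 16 pilocytic astrocytomas
    "EP": {"PA": 0, "EP": 7, "MB": 1},    # 8 ependymomas
    "MB": {"PA": 2, "EP": 1, "MB": 26},   # 29 medulloblastomas
}

# Prospective evaluation of the original scheme on 26 new cases.
ORIGINAL_SCHEME_CONFUSION = {
    "PA": {"PA": 5, "EP": 1, "MB": 3},    # 9 pilocytic astrocytomas
    "EP": {"PA": 0, "EP": 2, "MB": 2},    # 4 ependymomas
    "MB": {"PA": 3, "EP": 0, "MB": 10},   # 13 medulloblastomas
}

# Pilocytic astrocytoma screen (step 1 of the re-optimised original
# cutoffs) on the combined dataset: 14 of 15 PA retained, 4 of the 38
# other tumours wrongly retained.
PA_SCREEN_COUNTS = {
    "PA": {"PA": 14, "rest": 1},
    "rest": {"PA": 4, "rest": 34},
}


def _cohort_from_confusion(confusion: dict, templates: dict,
                           source_id: str) -> pd.DataFrame:
    from .rules import compute_ratios_from_heights

    rows = []
    case = 0
    for true_class, row_counts in confusion.items():
        for predicted, count in row_counts.items():
            ratios = compute_ratios_from_heights(templates[predicted])
            for _ in range(count):
                case += 1
                row = {"case_id": f"{source_id}-{case:03d}",
                       "true_class": true_class}
                row.update(ratios)
                row["source_id"] = source_id
                rows.append(row)
    return pd.DataFrame(rows)


def updated_scheme_reference_cohort() -> pd.DataFrame:
    """53-case cohort reproducing the updated scheme's confusion counts."""
    return _cohort_from_confusion(
        UPDATED_SCHEME_CONFUSION, _UPDATED_TEMPLATES, "multicentre")


def original_scheme_reference_cohort() -> pd.DataFrame:
    """26-case prospective cohort for the reconstructed original scheme."""
    return _cohort_from_confusion(
        ORIGINAL_SCHEME_CONFUSION, _ORIGINAL_TEMPLATES, "prospective")


def pa_screen_reference_cohort() -> pd.DataFrame:
    """53-case cohort for the PA-versus-rest screen of the re-optimised
    original cutoffs (NAA/Cr > 2.22 and mIns/NAA < 1.35)."""
    from .rules import compute_ratios_from_heights

    # Heights that pass / fail the screen.
    pass_heights = {"naa": 9.0, "cr": 3.0, "tcho": 10.0, "mins": 4.0,
                    "lmm09": 2.0, "lmm13": 3.0}     # NAA/Cr 3, mIns/NAA 0.44
    fail_heights = {"naa": 5.0, "cr": 5.0, "tcho": 10.0, "mins": 6.0,
                    "lmm09": 5.0, "lmm13": 7.0}     # NAA/Cr 1
    rows = []
    case = 0
    for true_class, counts in PA_SCREEN_COUNTS.items():
        for predicted, count in counts.items():
            heights = pass_heights if predicted == "PA" else fail_heights
            ratios = compute_ratios_from_heights(heights)
            for _ in range(count):
                case += 1
                label = "PA" if true_class == "PA" else "MB"
                row = {"case_id": f"screen-{case:03d}", "true_class": label}
                row.update(ratios)
                row["source_id"] = "screen"
                rows.append(row)
    return pd.DataFrame(rows)
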