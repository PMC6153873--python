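# Methods

## The classification model

The classifier operates on nine peak-height ratios formed from six peaks
of a 1.5-T short-TE (28–35 ms) single-voxel PRESS spectrum: Cr/tCho,
NAA/tCho, mIns/tCho, NAA/Cr, mIns/Cr, mIns/NAA, LMM0.9/tCho,
LMM1.3/tCho and LMM0.9/LMM1.3. A rule scheme is an ordered list of
steps; each step is a conjunction of strict inequalities on ratios and
assigns one class; cases satisfying no step receive the else-class.
Strictness matters at the boundary: a case with NAA/Cr exactly 2.22
fails step 1 and falls through. Check ratios are consulted after
assignment and can only raise flags, never change the label, because no
published override rule exists.

The updated scheme is: step 1 PA if NAA/Cr > 2.22 and mIns/NAA < 0.65;
step 2 MB if mIns/tCho < 0.85; else EP, with Cr/tCho and NAA/tCho as
checks. Two further configs ship: `reoptimized_original` (the original
three ratios with cutoffs re-optimised on the combined dataset: NAA/Cr
2.22 and mIns/NAA 1.35 in step 1, Cr/tCho 0.45 separating MB from EP in
step 2) and `original_reconstruction` (same structure with the original
NAA/Cr cutoff of 4). Only the original NAA/Cr cutoff is on record; the
reconstruction borrows the other two cutoffs from the re-optimisation
and is labelled as such in its config — results from it are indicative,
not historical.

Classification is scale-invariant by construction: ratios are unchanged
when all six heights are multiplied by a positive constant, so arbitrary
intensity units across scanners are harmless.

## Peak measurement

**Noise** is the standard deviation of linearly detrended intensities in
a peak-free region, by default 4.05–4.45 ppm (present on the default
axis, clear of every peak window and of the water-residual tail). The
region must contain ≥ 32 points.

**Baseline flatness.** A degree-4 Chebyshev polynomial is fitted through
baseline support points (everything at least 0.15 ppm away from any
peak window, below 4.45 ppm). The baseline counts as flat when the fit
never deviates from its own median by more than 2 × noise sd —
"visually flat" operationalised as "within noise". The 0.15-ppm margin
keeps Lorentzian tails, which fall off only quadratically, out of the
support; without it a perfectly clean synthetic spectrum is judged
non-flat from its own line tails.

**Heights.** The apex is the maximum intensity in the peak's window
(defaults: NAA 1.90–2.10, Cr 2.90–3.10, tCho 3.10–3.30, mIns 3.45–3.65,
LMM 0.80–1.00 and 1.20–1.40 ppm; only the centre positions are fixed by
convention, the windows are this package's choice). With a flat
baseline, height = apex − set baseline level (median intensity of the
baseline support). Otherwise height = apex − the linear interpolation
between the nearest flanking local minima of a lightly smoothed
(Savitzky–Golay, 9-point, order 2) trace — the "base of the individual
peak". An apex on a window edge raises a mis-windowing flag; negative
heights are clipped to zero and flagged.

**NAA narrow/broad.** If a local maximum with prominence > 2 × noise sd
exists in 1.95–2.10 ppm, its height is NAA (narrow mode). Otherwise the
broad 2.0–2.5 ppm structure — lipids, macromolecules, glutamate and
glutamine — is all that is present, and the intensity at 2.0 ppm above
baseline stands in (broad mode). The prominence threshold is this
package's quantification of "no sharp peak at 2.0 ppm". Broad-mode NAA
deliberately overestimates true NAA; that bias does not affect the rule
scheme's validity but matters for biological interpretation.

Software measurement is deterministic, so the triplicate manual
measurement of the clinical workflow is replaced by a single computed
value; `measure.window_jitter` reports the height spread under ±0.02 ppm
window perturbation as a robustness surrogate.

## Quality control

1. Cr and tCho must be visually well separated: the minimum intensity
   between the two apexes must fall below 90% of the smaller apex height
   above baseline. The 10% valley-depth criterion quantifies a visual
   judgement and is configurable. At the default 0.03-ppm linewidth the
   valley between Cr and tCho (0.17 ppm apart) is deep; lines merge —
   and QC fails — once the FWHM approaches the peak separation
   (~0.25 ppm).
2. tCho height ≥ 5 × noise sd, inclusive ("at least").

QC is monotone in noise: raising the noise estimate can only flip a pass
into a fail. Failing cases are excluded from classification but logged.

## Refinement

Given a labelled cohort (≥ 4 cases per class):

1. one-way ANOVA per ratio across the three classes; ratios with
   P ≥ 0.05 are discarded. No multiple-testing correction is applied —
   the procedure being codified used none; the prefilter is implemented
   as sequential (ANOVA before the t-tests) although the two could run
   in parallel.
2. Welch two-tailed t-tests (PA vs rest, MB vs EP) for all nine ratios,
   reported as diagnostics. Welch rather than pooled because the class
   sizes and variances are unequal in practice.
3. ROC AUCs for four contrasts (each class vs all; EP vs MB), computed
   with ties counting one half and reported orientation-free
   (max(a, 1−a)) with a direction flag, since a ratio may indicate its
   class from either side.
4. Step 1 = every retained ratio with PA-vs-rest AUC > 0.9, as a
   conjunction; step 2 = the single retained ratio with the highest
   EP-vs-MB AUC (step-1 ratios excluded), the next two strongest
   recorded as check ratios. These selection rules turn a narrative
   procedure ("ratios with AUC greater than 0.9...", "constructed using
   the best ratio alone, with the next as checks") into a deterministic
   algorithm.
5. Cutoffs maximise sensitivity + specificity, scanned over midpoints of
   adjacent sorted unique scores plus ±∞ sentinels; ties break toward
   higher specificity, then toward the more extreme cutoff. Midpoints
   (rather than observed values) make the scan reproducible and
   oracle-checkable; positives are predicted strictly beyond the cutoff,
   matching the schemes' strict comparators.
6. The refined scheme is evaluated on the input cohort (in-sample).

The case order is canonicalised by `case_id` before fitting, so the
report is invariant to row permutations. The implementation delegates
the ANOVA, t-test and AUC computations to scipy/scikit-learn; the test
suite checks the AUC and cutoff machinery against independent
brute-force oracles (exhaustive pairwise comparison, exhaustive
threshold scan).

## Synthetic data

A case is six latent peak heights drawn from class-conditional
log-normal distributions (heights are positive and right-skewed); the
nine ratios are derived from the heights, which makes every generated
ratio vector internally consistent (mIns/NAA ≡ (mIns/tCho)/(NAA/tCho))
and induces realistic correlations between ratios sharing a peak. The
shipped class levels (medians in relative units, log-sd):

| class | NAA | Cr | mIns | tCho | LMM0.9 | LMM1.3 |
|---|---|---|---|---|---|---|
| PA | 0.82 (0.16) | 0.25 (0.16) | 0.38 (0.18) | 1.00 (0.50) | 0.35 (0.40) | 0.45 (0.40) |
| MB | 0.80 (0.16) | 0.50 (0.16) | 0.73 (0.22) | 1.45 (0.22) | 0.85 (0.40) | 1.25 (0.40) |
| EP | 0.85 (0.16) | 0.51 (0.16) | 1.35 (0.22) | 0.95 (0.22) | 0.45 (0.40) | 0.55 (0.40) |

Qualitatively: PA low Cr and mIns, MB high tCho and lipids, EP high
mIns. Per-class ratio statistics of the clinical cohorts are
unpublished, so these levels are modelling choices calibrated once so
that (a) the geometric crossing points of the class-conditional ratio
distributions sit at the published cutoffs — NAA/Cr ≈ 2.2 (PA vs MB),
mIns/NAA ≈ 0.65, mIns/tCho ≈ 0.85 (numerically, the Youden-optimal
thresholds of the generative mixtures are 2.31, 0.69 and 0.85) — and
(b) the cross-metabolite ratios NAA/Cr and mIns/NAA, not their /tCho
components, are the strong PA-vs-rest discriminators. The latter is
achieved by giving PA's tCho a large spread (log-sd 0.5): overall
choline variability blurs every x/tCho ratio while ratios between
metabolites cancel it — the same mechanism that makes NAA/Cr the
discriminator of choice in real data. Under these defaults a large
simulated cohort classifies at ≈ 92% with the updated scheme and ≈ 88%
of PA cases satisfy the step-1 conjunction.

Spectra are rendered as Lorentzian singlets (default FWHM 0.03 ppm,
visually separated Cr/tCho at 1.5 T) at 2.02, 3.03, 3.20 and a
configurable mIns position (default 3.56 ppm, the standard literature
position — it is not pinned by the workflow itself), plus broad
Gaussian humps (FWHM 0.19 ppm) at 0.90 and 1.30 ppm, an optional broad
baseline hump and Gaussian water-suppression residue centred at
4.7 ppm, and white Gaussian noise. The default axis is 0.0–4.5 ppm,
descending, with 901 points (0.005-ppm grid): the grid step is chosen
so every default line centre falls exactly on a grid point, making a
noise-free apex equal the requested height to machine precision. Apex
heights above the true baseline equal the requested heights up to
linewidth-overlap effects (< 1% between Cr and tCho at the default
linewidth). Heights scale the noise-free spectrum linearly.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: scanner-specific post-processing
and baseline correction, phase errors, frequency drift, multiplet
structure (mIns is a singlet here), lactate doublets, chemical-shift
displacement, and inter-centre calibration differences. Recovery and
classification results on synthetic cohorts demonstrate internal
consistency of the pipeline, not clinical accuracy.

## Benchmark cohorts

The published per-case ratios behind the multicentre evaluation are not
available, so the reported classification rates are made recomputable
through engineered cohorts: small tables of internally consistent ratio
vectors constructed (from the published confusion counts) so that each
case lands deterministically in a given branch of the scheme. Evaluating
the updated scheme on the 53-case benchmark yields 48/53 = 90.6% overall
and 94/88/90% per class; the reconstructed original scheme on the
26-case prospective benchmark yields 17/26 = 65.4%; the PA screen under
the re-optimised cutoffs yields 48/53 → 91%. These checks validate the
evaluation arithmetic and the rule engine, not the clinical data. One
printed figure is knowingly ignored: the 64.2% overall rate quoted for
the re-optimised original scheme is inconsistent with its own stated
per-class counts (14 + 7 + 14 of 52), so it is not used as a benchmark.

## Numerical choices and edge cases

* Percentages: per-class rates round to the nearest integer, overall
  rates to one decimal, PA-vs-rest to the nearest integer — matching the
  usual reporting convention; raw numerator/denominator pairs are kept
  alongside every percentage.
* A zero (flat) spectrum measures all heights 0 with noise 0 and a
  degeneracy flag; the choline-SNR check then errors, which `apply_qc`
  converts into a failing check, so such cases never reach
  classification.
* Zero or negative denominator heights make ratio computation fail with
  an error naming the peak.
* t-test of two zero-variance groups with equal means returns p = 1.
* AUC/cutoff routines reject single-class inputs.
* Problem sizes used by the test and acceptance runs — 500 per class for
  accuracy, 200 per class (5 cohorts) for refinement recovery, 100
  spectra for height recovery — give sampling errors comfortably below
  the tolerances being checked (e.g. binomial se ≈ 0.8% at n = 1500).

## Known limitations

* The original scheme's exact historical step structure is partly
  reconstructed (see above); rates computed from it are labelled as such.
* Broad-mode NAA folds macromolecular signal into the NAA height.
* The rare-tumour reference rows are means over one to three cases; the
  nine ratios of a mean row are not mutually consistent, and two lipid
  ratios of the diffuse astrocytoma are exactly zero, so these rows are
  excluded from three-class evaluation and ratio-consistency invariants.
* Refinement evaluates its scheme in-sample, as the procedure it
  codifies did; no cross-validation is performed.
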