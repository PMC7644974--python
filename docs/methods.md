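# Methods

## Mass arithmetic and element-count inference

All masses derive from a fixed table of monoisotopic atomic masses (C, H,
N, O, P, S) with the heavy-isotope differences Δ¹³C = 1.0033548 Da and
Δ¹⁵N = 0.9970349 Da; the table ships as a documented text file
(`isodiel/data/isotope_constants.tsv`). Negative-mode ions are modelled as
[M−zH]ᶻ⁻ with the electron mass included (`(M − z·m_H + z·m_e)/z`); the
electron term is sub-ppm but makes every computed value unambiguous.
Charge defaults to 1 throughout — multiply-charged species are supported
through the `charge` parameter but never assumed.

Element counts are inferred by rounding the observed labeling shift to the
nearest integer multiple of the isotope mass difference and accepting only
if the reconstructed shift matches within a ppm tolerance of the labeled
m/z. With the default 10 ppm tolerance this inversion is exact for up to
60 carbons under ±5 ppm m/z error on both peaks: the rounding margin is
Δ¹³C/2 ≈ 0.5 Da, two orders of magnitude above the worst-case combined
m/z error at metabolite masses.

The natural-abundance mass-isotopologue distribution uses a carbon-only
binomial model (each carbon independently ¹³C with probability 0.0107),
truncated and renormalized. Heavy isotopes of H/N/O/P/S are ignored:
carbon dominates M+1 for polar metabolites and the envelope is used
comparatively, not quantitatively. Labeled extracts are treated as 100%
isotopically enriched by default; enrichment is a generator parameter
(`label_purity`, applied as `purity^nC` to the IS monoisotopic peak) so
imperfect labeling can be simulated.

## Annotation

MS2 annotation is a deliberately small matcher, standing in for the
full-featured external engines a production workflow would use: candidate
library entries are gated on precursor m/z (10 ppm default), fragments are
paired greedily one-to-one within 0.01 Da, and the score is a cosine on
square-root intensities (score ∈ [0,1], 1 for identical spectra,
invariant to global intensity scaling). Acceptance threshold 0.7. These
are configuration defaults, not claims about any particular instrument;
acquisition-mode effects (DDA/SWATH) are not modelled and library spectra
are treated as clean.

## Pairing and quantification

Within one mixed (sample + ¹³C IS) injection, each feature is searched for
a partner at higher m/z with shift ≈ n·Δ¹³C (n in 1–60), retention time
within 0.1 min and mass agreement within 10 ppm. Candidates are ranked by
ppm deviation (ties by RT deviation) and assigned one-to-one, so no peak
is used twice. Only the two monoisotopic peaks enter the ratio;
intermediate isotopologues are ignored. Features matching the [2M−H]⁻
dimer of an annotated compound within tolerance are flagged and excluded
from the untargeted list.

Rows of the abundance matrix are aligned across samples by greedy
single-linkage clustering on m/z (10 ppm) with an RT gate (0.1 min);
duplicate pair assignments for one row and sample raise an error. Rows
missing in more than half the samples are dropped before statistics;
remaining missing entries are excluded pairwise by the tests and imputed
by the row mean only for PCA.

## Growth model

Irradiance is a half-sine: `peak · sin(π·(t−dawn)/photoperiod)` during the
photoperiod, zero in the dark, continuous at dawn and dusk (defaults:
600 µmol photons m⁻² s⁻¹ peak, 14 h photoperiod, 24 h cycle). Growth is
purely light-limited: `d(OD)/dt = μ_peak · I(t)/I_peak · OD`, integrated
with fixed-step classical Runge-Kutta (default step 0.05 h, discretization
error ≪ measurement noise). The analytic check is the half-sine integral:
ln-growth per photoperiod = `μ_peak · 2·photoperiod/π`.

μ(t) is estimated as the centered finite difference of ln(OD) (one-sided
at the ends), after an optional centered moving average of ln(OD) —
default window 3 points; window 1 disables smoothing. On noiseless series
sampled at ≤ 0.1 h this recovers the planted μ(t) to better than 1% of its
peak, with the argmax at mid-photoperiod. The dawn/dusk OD dips seen in
real cultures are reproduced as an optional multiplicative Gaussian dip
(default depth 4%, σ = 0.5 h, centered 1 h after dawn and 1 h before
dusk) — an empirical shape, not a mechanistic model, since the cause of
such dips is an open question.

## Statistics

Inferential tests run on log₂ ratios (variance stabilization for
multiplicative noise); display transforms (replicate averaging,
auto-scaling, geometric-mean normalization) follow standard metabolomics
practice. The ANOVA screen is classical one-way (no Welch correction)
with a conjunctive gate: significant iff p < 0.05 **and** max/min of the
per-condition geometric means > 1.5. The two-condition contrast is an
equal-variance Student's *t* test with the same conjunctive gate. No
multiple-testing correction is applied by default, matching the raw
p-value convention of the screen this reproduces; the p-values are
reported per row so any correction can be applied downstream. The CV gate
keeps rows whose mean intra-condition CV (sample SD/mean of raw ratios)
is ≤ 0.3.

PCA operates on samples after row auto-scaling of the log₂ matrix, via
SVD of the column-centered data; condition ellipses are bivariate-normal
contours scaled by the χ² quantile (2 df) at 95% coverage — a conventional
choice, since "95% region" is underdetermined otherwise. Peaking time is
the argmax over the four diurnal conditions, ties broken in diurnal order
(M < MD < E < MN) with an explicit tie flag.

## Synthetic studies: what they emulate and what they do not

The generator's defaults encode the study design this package targets:
67 annotated metabolites + 47 unannotated biological compounds (114
credentialable features), 50 background decoys, five conditions
(M/MD/E/MN/CL) × 3 replicates, 10% multiplicative peak-area CV, 20%
per-sample lognormal matrix-effect spread, 2 ppm m/z jitter, 0.01 min RT
jitter, OD₇₂₀ sampled every 0.25 h with 0.3% noise and μ_peak = 0.1604 h⁻¹
(ln-growth 1.43 per photoperiod). Replicate count and IS spike amount are
declared defaults, not inferences.

Diurnal classes are assigned round-robin (M-, MD-, E-, MN-peaking, flat).
A class peaking at condition k has true multiplier `amplitude^(1 − d/2)`
with d the circular condition distance, i.e. 8 : 2.83 : 1 at the default
amplitude of 8; CL sits at the geometric mid-level `amplitude^0.5`, and a
heavy-tail option draws occasional amplitudes up to 100-fold. This smooth
profile makes every diurnal compound an ANOVA true positive (8-fold span)
while only MD- and MN-peaking classes differ between MD and CL, giving the
pairwise contrast a non-trivial truth set.

Background decoys are rejection-sampled so that, at widened versions of
the default tolerances, no decoy can form a ¹³C-shift pair with any other
peak; decoy ground truth is therefore unambiguous and false pairings can
arise only from noise. Real data differ in ways the generator does not
attempt: chromatographic peak-shape and coelution structure (one peak per
compound by default; a stress option adds isobars), correlated noise
across metabolites, retention-time drift between runs, in-source
fragments, and real MS2 fragmentation chemistry (templates are random).
Passing tests therefore demonstrate the correctness and calibration of the
arithmetic and statistics under the stated noise model — not performance
on any particular instrument's data.

## Numerical and design choices

* Tolerance defaults (10 ppm, 0.1 min, fragment 0.01 Da) are typical for
  high-resolution TOF data; the resolving power behind any particular
  dataset is configuration, not a constant.
* Tie-breaks are deterministic everywhere (minimal ppm deviation, then
  minimal RT deviation for pairing; diurnal order for peaking ties), so a
  fixed seed yields byte-identical outputs, which the tests assert.
* Zero-variance rows auto-scale to all-zeros with a flag rather than
  raising; non-positive values reaching a log transform raise an error
  naming the offending cell.
* The problem sizes used by the test suite and the acceptance script
  (default-scale studies of ~4200 features, 1000-row null calibrations)
  were chosen as the smallest sizes at which the measured rates are
  stable; all run in seconds.

## Known limitations

Peak picking from raw spectra is upstream of this package — inputs are
peak-picked feature tables. Absolute quantification, adduct enumeration
beyond [M−H]⁻ and 2M−H, isotope fine structure, SWATH deconvolution, and
retention-time prediction are out of scope. The MS2 matcher is a minimal
stand-in and should not be benchmarked against dedicated annotation
engines.
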