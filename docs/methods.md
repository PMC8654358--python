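# Methods

## Denaturation model and fitting

The soluble fraction at gradient value x > 0 is
`f(x) = (1 − Pl)/(1 + exp(−(a/x − b))) + Pl`. For a > 0 the curve falls
from 1 (x → 0⁺) to `Pl + (1 − Pl)/(1 + e^b)`; Pl is the
denaturant-resistant plateau. The model has a pole at x = 0, so the
gradient origin is never fitted: it serves only as the scaling reference
(every protein is divided by its reference channel, making the curve
start at 1 by construction).

Fitting is bounded nonlinear least squares (trust-region reflective) with
analytic Jacobian, from start values (Pl = 0, a = 55, b = 10) for solvent
gradients and (Pl = 0, a = 550, b = 10) for thermal gradients, with a
small retry grid over (a, b) on non-convergence. Bounds are
Pl ∈ [0, 1.5], a > 0, b > 0: positivity keeps the curve non-increasing,
and the loose upper plateau bound prevents pathological fits on flat
profiles while still letting them fail the quality gate. R² is computed
as 1 − RSS/TSS on the normalized values actually fitted. Non-convergence
and too-few-points (< 5 finite values) are reported as flags, never
exceptions.

The melting point is the root of f(x) = 0.5 found by Brent bracketing on
a fixed interval ([3, 21] %AEA for solvent data; the temperature range
for thermal data) with tolerance well below 1e-9; no extrapolation
outside the interval, so a curve that never crosses 0.5 there has an
absent (invalid) melting point. The analytic slope at the melting point
uses an exp(−|z|) formulation to avoid cancellation deep in the curve
tails. A curve passes quality control iff R² > 0.8, plateau < 0.3, and
both melting point and slope are valid with slope < 0 ("valid slope" is
taken to mean present, finite and negative; steepness cutoffs for hit
statistics are applied separately and configurably).

## Normalization

Technical channel-to-channel variance (pipetting) is removed jointly
across experiments. Membership in the normalization set requires, in
every experiment being normalized: the 5th point (8-point curves; 10th of
16) in [0.4, 0.6], the 7th (15th of 16) in [0, 0.3], and the last point
in [0, 0.2]. Per-experiment median curves over the members are fitted
with the sigmoid; the experiment with the best median-curve R² becomes
the reference, and the correction factor of experiment e at gradient g is
fitted-reference(g) / median_e(g), fixed at 1 for the reference point.

Two properties follow. First, corrected member medians of every
experiment lie exactly on the fitted reference curve, so median curves
align across experiments to machine precision. Second, re-running the
procedure on already-normalized data with the *same* membership yields
unit factors exactly; if membership is re-selected, the set shifts
(biases having been removed) and factors can move a few percent at
channels where the median is small — an inherent property of the
fitted-curve-ratio construction, not an error.

Normalization is per joint group as given; by default each table's
experiments are normalized together (and vehicle + treatment jointly in
the shift analysis), matching per-16plex processing.

## Shift statistics and hit calling

ΔC_M = C_M(treatment) − C_M(vehicle), per replicate, defined only when
both curves pass quality control. P-values are empirical: proteins with
valid shifts are ordered by the steeper (more negative) of their two
curve slopes and chunked into bins of 300; within a bin, a robust z-score
uses the bin median and the half-distance between the 84.13th and 15.87th
percentiles (a normal-consistent spread), converted to a two-sided normal
p-value and Benjamini–Hochberg adjusted across proteins. Fewer than 50
valid shifts suppresses p-values with a logged warning.

The four hit requirements (each threshold configurable): (1) the smaller
replicate p-value < 0.05 and the larger < 0.1; (2) the shift has the same
sign in both replicates; (3) both |ΔC_M| exceed the vehicle-vs-vehicle
|C_M difference| (skipped when only one vehicle replicate exists);
(4) the steeper slope of each replicate's pair is < −0.06. A hit must
additionally have adjusted p < 0.001 in both replicates and more than one
peptide. Peptide counts are carried per table (one count per protein per
arm); the gate uses the minimum of the vehicle and treatment counts.
Proteins whose shift is undefined in a replicate are reported with an
absent hit status, and a protein whose curve fits well in one arm but has
no melting point in the other (e.g. stabilized past the gradient) is
flagged for manual inspection rather than silently dropped.

## PISA analysis

Equal-volume pooling of the soluble fractions over a window is modelled
as the mean over the window's gradient values (sums and means differ by a
constant that cancels in every fold change). The default windows are
0–21, 9–19.5, 11–19.75 and 14.25–19.5 %AEA (8 evenly spaced points each),
with a 9–18.625 variant of window 2 also provided; both spacings that
appear in practice are supported rather than adjudicated. Fold changes
are log2(sample / mean of vehicle samples). Proteins with fewer than two
peptides, or with a %CV (100·sd/mean on raw pooled abundances) strictly
above 15 in either group, are removed before testing.

Significance uses a SAM-style statistic on log2 pooled abundances:
d = (mean₁ − mean₂)/(s + S0), where s is the pooled two-sample standard
error and S0 = 0.1 an absolute stabilizing offset (with S0 = 0, d is
exactly the pooled-variance t statistic). The null distribution comes
from 250 group-label permutations drawn with replacement (seeded) from
the distinct arrangements (70 for 4 vs 4). For a candidate cut t, the
estimated FDR is the median permutation count of |d*| ≥ t over the
observed count of |d| ≥ t; the chosen cut is the most permissive with
estimated FDR ≤ 0.05, and per-protein q-values are the monotonized
estimated FDR at each protein's own |d|.

Expected window fold changes are predicted from fitted curves as
log2(Σ treated / Σ vehicle) over the window, with the gradient origin
evaluated as 1 (the scaling reference). For a stabilizing shift the
predicted fold change grows from window 1 to window 4 provided the
melting transition lies within the windows' span and the plateau is small
(roughly C_M ≳ 13 %AEA, Pl ≲ 0.1 for the default windows); for earlier
melters or high plateaus the later windows sample mostly plateau and the
amplification saturates — the window ladder is informative precisely for
proteins melting inside it.

## Synthetic data

The generator emulates processed protein-level tables: melting
concentrations lognormal above 7 %AEA with sample median 10.2 and support
inside (7, 21) (σ = 0.45, resampled at the edges); plateaus
0.28·Beta(1.2, 6); steepness b ~ N(10, 1.5) clipped to [6, 14]; the scale
a derived from (C_M, Pl, b) via the closed form. A configurable fraction
(default 0.25) is non-sigmoidal, drawn equally from three archetypes:
flat solvent-resistant profiles, partial melters with plateau in
[0.35, 0.75], and erratic non-monotone profiles. Base intensities are
log-uniform over three orders of magnitude; peptide counts are
1 + Poisson(7) with a 5% fraction forced to a single peptide to exercise
the peptide filter.

Planted target shifts translate the 0.5-crossing exactly: the treatment
curve keeps Pl and b and rescales a to C_M + ΔC_M (error if the shifted
crossing leaves the model domain). Measurement noise is multiplicative
lognormal per channel (default 5% CV — chosen so simulated per-group %CVs
concentrate below the 15% filter, matching the envelope observed in real
pooled experiments), a per-channel pipetting bias uniform in ±10%
(removable by normalization), and a small per-sample scale jitter (2%)
for pooled PISA samples. All randomness flows from one seed split per
stage, so every table is bit-reproducible.

What the generator does not emulate: peptide/spectrum-level structure,
missing-value mechanisms beyond failed reference scaling, correlated
protein complexes, and day-to-day gradient drift (representable only as a
global gradient offset applied by the caller). Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
noise model, not robustness to every pathology of real data.

## Problem sizes and numerical choices

The validation suite and `scripts/acceptance.py` use proteomes of
400–2000 proteins at 8 gradient points in duplicate (full-curve null
runs: 2000 proteins; power runs: 700 proteins with 40 planted ±3–4 %AEA
targets; PISA runs: 1500–2000 proteins, 4 vs 4 samples), sizes at which
the binned empirical null is well populated (≥ 1000 valid shifts) while a
complete run stays in the minutes range on a single CPU. Planted targets
are drawn from quantifiable melters (C_M in the well-covered 8–14 %AEA
band, > 1 peptide) so the planted shift is expressible on the gradient.
Root finding uses xtol 1e-12; least-squares tolerances are 1e-12 with at
most 200 function evaluations per start; ties in the reference-experiment
choice resolve to the first experiment in design order.

## Known limitations

- Peptide counts are per table, not per replicate; real 16plex designs
  with per-replicate counts should supply the minimum count.
- The empirical shift test needs a large background of unshifted
  proteins; on small panels (< 50 valid shifts) p-values are withheld.
- The permutation FDR has the granularity of 250 label draws; with 4 + 4
  samples the 70 distinct arrangements limit how finely the null tail is
  resolved.
- Dose–response (concentration-series) modelling is out of scope;
  concentrations are analyzed as separate PISA contrasts.
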