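# Methods

This note documents the models, estimators, defaults and numerical choices
behind `cofrac_pmi`, and what the synthetic benchmarks do and do not show
about real data.

## Elution model and deconvolution

A feature's elution profile over an ordered fraction series is modelled as
a sum of Gaussian peaks in fraction coordinates,
A·exp(−(x−μ)²/2σ²), with σ defaulting to 1.5 fractions — the visual width
of well-behaved SEC peaks on a 48-fraction gradient. Fraction coordinates
are 1-based indices over the label list in file order; plate-style labels
are never parsed. Profiles are first max-normalised per replicate
(all-zero profiles are flagged, not divided), averaged element-wise, and
re-normalised.

Peak picking on the mean profile: moving-average smoothing (window 3
fractions), local maxima with prominence ≥ 5% of the profile maximum and
apex separation ≥ 2 fractions (maxima at the array edges are recovered
explicitly, since plain local-maximum detection misses them), region
boundaries at the minima between adjacent apexes, and a least-squares
Gaussian per region (`scipy.optimize.curve_fit`, centre bounded to the
region ± 1 fraction, σ ∈ [0.1, 20]). Candidates are dropped — with a
warning, never a pipeline failure — when the fit does not converge, the
region spans < 3 fractions, or σ̂ ∉ [0.5, 10] fractions. All thresholds sit
in `PeakPickingParams`.

Replicate consistency: a peak of the mean profile is kept only when its
*observed apex* recurs as a local maximum within ± 1 fraction in ≥ 2 of 3
replicates. The observed apex, not the fitted centre, is compared: when two
overlapping components merge into one region, the least-squares centre sits
between them and would spuriously fail the replicate check. Two planted
peaks are resolved reliably from ≥ ~5–6 fractions of separation (≈ 4σ);
closer states (e.g. oligomers at 138 vs 88 kDa) can merge into one broad
peak, which is a resolution limit of the gradient, not of the fitter.

## Mass calibration and oligomeric state

Reference proteins of known mass define a least-squares line
log₁₀(mass) = a·fraction + b (slope required negative; R² reported).
A peak's apparent mass is 10^(a·μ̂+b); positions outside the calibrated span
are extrapolated and flagged. The oligomeric state ratio is apparent over
monomeric mass; > 1.5 calls the peak multimeric. The ratio is
scale-invariant, and the 1.5 cut sits far enough from both 1 (monomer) and
2 (dimer) that a centre error of ± 0.3 fractions (≈ 5% in mass) does not
flip calls.

## Co-elution scoring, threshold choice and FDR

Scores are Pearson correlations between fitted single-peak profiles
(the Gaussian inside its support, zero outside) over the
protein-containing window, fractions 1–38 by default. Metabolite signal
beyond that window is treated as the free (unbound) pool and never scored.
A correlation is computed only for vectors with ≥ 3 nonzero entries and
nonzero variance; undefined combinations are excluded rather than scored 0.
A feature pair's score is the max over its peak pairs, so a single
co-eluting peak suffices; called edges are reported qualitatively and PCC
is never used to rank them — with co-elution evidence, magnitude above
threshold says little about affinity.

The threshold is chosen on a ROC of known-interaction scores against a
random-pair null: each of 100 iterations draws as many random
metabolite–protein pairs as the known set holds, uniformly without
replacement and excluding known pairs; pairs never co-scored carry the
floor −1. TPR(t) is the fraction of known pairs ≥ t, FPR(t) the mean
fraction of null pairs ≥ t, AUC the trapezoid over (FPR, TPR). At the
operating threshold (0.7),

FDR(t) = m̄_null / (m̄_null + m_true),  fold-enrichment = m_true / m̄_null,

where m̄_null is the mean per-iteration null-positive count. This
estimator describes the *known-pair operating point* — the expected share
of chance co-elutions among calls when true and random candidates are
weighed 1:1 — not the error rate of the full network (see the benchmark
section).

## Synthetic data generator

`simulate_fractionation` emulates the reference experiment: 48 fractions,
proteins confined to the first 38 (≈ 5.2 MDa at fraction 1 down to 20 kDa
at fraction 38 through the calibration line), 3 biological replicates.
Each protein elutes at the fraction its monomeric — or, for complex
members, complex — mass implies, with a 30% chance of a second peak at a
2–4× multimer position when ≥ 4 fractions away. Planted PMI metabolites
get a bound peak exactly co-located (pre-noise) with the partner's main
peak plus a free-pool peak beyond the protein span (40% of the amplitude
by default); unplanted metabolites carry only the free pool. Noise is
multiplicative lognormal, mean-preserving, with configurable CV
(default 15%; the reference experiment does not state a per-feature noise
magnitude, so the CV is a free simulation parameter at a value typical of
label-free LC-MS), and intensities below a detection floor (100, against
peak amplitudes of ~10⁵·⁵–10⁶·⁵) are censored to zero. Identical seeds
give bitwise-identical datasets.

What the generator does *not* emulate: retention-time drift, asymmetric
(tailing) peaks, correlated noise across fractions, missingness beyond the
detection floor, and shared metabolite pools between bound states. Passing
benchmarks therefore show the pipeline's statistical machinery is correct
under the stated model, not that real chromatograms are this clean.

## The standard benchmark and its two FDR readings

The demo benchmark (200 proteins, 30 metabolites, ten 3-member complexes,
20 planted PMIs, 3 replicates, 15% CV) packs ~250 protein peaks of σ = 1.5
into 38 fractions. Two such peaks correlate above 0.7 whenever their
centres are within ≈ 1.6 fractions, so any metabolite peak overlaps
~10–20 proteins besides its planted partner — exactly as in real
co-fractionation data, where one dipeptide peak co-elutes with hundreds of
proteins. The ground-truth evaluation therefore separates called edges
into three classes: *recovered* (planted), *artifacts* (the protein has a
true peak within 2.5 fractions of the planted partner's peak — it
genuinely co-elutes and no co-fractionation analysis could reject it), and
*false* (calls not explained by real overlap). `run_demo` reports
sensitivity, the realized FDR over resolvable calls (false/(recovered+false)),
the strict called-vs-planted rate (`realized_fdr_strict`, dominated by
artifacts by construction), and the null-based estimate. The 2.5-fraction
artifact window is the centre distance at which two σ = 1.5 Gaussians still
correlate ≈ 0.5. Note the null-based estimate (~10%) and the resolvable
realized FDR (~0%) measure different things and should not be expected to
coincide: the former prices chance co-elution at the operating point, the
latter counts outright mistakes.

## Thermal proteome profiling

Melting curves use f(T) = (1−p)/(1+exp(b−a/T)) + p (midpoint at T = a/b;
≈ 1 at low T; plateau p bounded in [0, 0.3] by default — typical TPP
plateaus). Fits are multi-start least squares: one data-driven start
(midpoint from the half-amplitude crossing) plus 5 randomised restarts
with fixed sub-seeds; proteins whose fits fail in either condition are
excluded from testing (and from the BH family) with a log entry.

The condition test is the nested F-test: RSS₀ from one curve pooled over
conditions, RSS₁ the sum of per-condition fits (each seeded additionally
with the pooled optimum, which enforces RSS₁ ≤ RSS₀ up to optimiser
tolerance; a numerically zero RSS₀ short-circuits to F = 0). Degrees of
freedom are theoretical — d₁ = 3 extra parameters, d₂ = n − 6 — which for
nonlinear fits is approximate; the empirically rescaled degrees of freedom
of the original curve-testing method are intentionally out of scope, and a
condition-label permutation p-value (`nparc_test(..., n_permutations=N)`)
is available when the F-approximation is in doubt. On
the simulated 10-temperature ladder (37–67 °C, 2 replicates, additive
noise sd 0.02) the test is nonetheless well calibrated (type-I error
≈ 0.047 at α = 0.05) with power ≈ 1 for a 3 °C shift. Benjamini–Hochberg
adjustment is delegated to `statsmodels` and cross-checked against the
step-up definition in the tests.

## Affinity purification

Log2 bead intensities are compared bait-vs-control per coupling
orientation with Welch t-tests and BH across proteins; a protein is
enriched when q ≤ 0.05 and log2FC ≥ 1 in at least one orientation (the
source experiments do not state the rule; "either orientation" is the
default, "both" behind a flag). Evidence intersection is plain set
algebra: support ≥ 2 of {SEC, AP, TPP} defines the interactome, 3 of 3
high confidence.

## Binding and enzymology fits

Dose–response fits use the 1:1 quadratic isotherm
f₀ + (f₁−f₀)·[(K_d+P_t+L) − √((K_d+P_t+L)² − 4P_tL)]/(2P_t), exact at
fixed labelled-target concentration P_t and within 1% of the hyperbola
when P_t ≤ K_d/100; the hyperbolic model is available behind a flag. The
binding model and normalisation used by instrument software are not
standardised, so this convention is documented rather than inferred.
Initial guesses come from the extreme-dose responses and the
half-amplitude crossing. A fit is flagged unreliable — the operational
meaning of "no interaction could be measured" — when the optimiser fails,
K̂_d exceeds the top ladder concentration, or the amplitude |f₁−f₀| falls
below 3× the residual noise. Reaction rates are least-squares slopes
within a user-chosen time window (no automatic linearity detection);
percent inhibition is 100·(1 − rate_treated/rate_control). Labelling
series multiply isotope enrichment (percent input auto-detected and
recorded) by total intensity; log2 ratios to t₀ require a positive
baseline and report later zeros as missing.

## Problem sizes and determinism

Benchmark sizes (500 deconvolution profiles, 300 null + 150 shifted
melting curves, 100 dose ladders, one 200 × 30 fractionation) give stable
estimates in well under a minute each on a single CPU. Every stochastic
step takes an explicit seed; `run_demo` and `run_promis` write
deterministic, byte-reproducible tables, and the run config (with hash and
seed) is serialised alongside outputs.

## Known limitations

- Peaks closer than ~4σ merge; oligomeric states with < 2× mass separation
  near the column's shallow region cannot be resolved.
- The FDR estimator is an operating-point summary, not a network error
  rate; network edges need orthogonal evidence.
- Theoretical F-test degrees of freedom can become anticonservative at
  noise levels or temperature grids far from the simulated regime; the
  permutation mode is the robust (but much slower) alternative.
- The AP model assumes roughly Gaussian log-intensities and complete
  observations; missing-value-aware models (as used for real pulldown
  data) are out of scope.
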