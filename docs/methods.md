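# Methods

## Quantification model

Two physically independent qPCR reactions are run on aliquots of the
same DNA extract: a wild-type-specific reaction (allele Cq `Cq_wt`) and
a mutant-specific reaction (`Cq_mut`), each co-amplifying the
single-copy reference gene RNase P (`Cq_RP,wt`, `Cq_RP,mut`). Under
per-cycle doubling, Cq is linear in the log2 of starting template, so
the difference of allele Cqs estimates the log2 allele ratio and

    mut% = 100 / (2^-(ΔCq) + 1),          ΔCq  = Cq_wt − Cq_mut
    mut% = 100 / (2^-(ΔΔCq) + 1),         ΔΔCq = (Cq_wt − Cq_RP,wt) − (Cq_mut − Cq_RP,mut)

If `W` and `M` are the wild-type and mutant copy numbers and the Cq of
each reaction is `c0 − log2(copies)`, then `ΔCq = log2(M/W)` and the
formula returns exactly `100·M/(M+W)` — the estimator is the copy
fraction itself, no standard curve involved. The corrected form only
differs by the reference terms, which cancel template-input differences
between the two tubes; when the reference Cqs are equal the two
formulas coincide (tested as an algebraic identity).

Assumptions the formulas inherit from the comparative-Cq method:

1. near-equal amplification efficiencies in the two reactions, close
   to 1 (a common efficiency `E ≠ 1` rescales `ΔCq` by
   `ln 2 / ln(1+E)`, biasing estimates away from 50% — the simulator
   tests quantify this, and the slope-equality analysis exists to
   verify the premise);
2. stable reference-target abundance in both tubes (violations are
   surfaced as warnings, not errors);
3. allele-specific primers that amplify the wrong allele only after a
   long delay (handled by the Cq cut-off, below).

## Classification rules

`classify_result` applies, in order: a failed wild-type reaction is an
**invalid sample** (error — it cannot be called negative); an
undetermined mutant reaction, or one at/after the Cq cut-off, is
**not detected** (the cut-off treats Cq ≥ 42 as wrong-allele
crosstalk; the single false positive motivating the rule sat exactly
at 42, so the boundary is inclusive and configurable); otherwise the
percent is computed, and the reporting limits partition it into
**not detected** (< LOD), **detected below LOQ** (LOD ≤ p < LOQ,
percent retained but flagged non-reportable), and **quantified**
(≥ LOQ). A not-detected result never carries a percent. Reference-Cq
imbalance beyond 1 cycle, or reference Cq above 30, raises warnings
that travel with the result into output files.

Default policy values — cut-off 42 of 45 cycles, LOD 0.15%, LOQ
1.16%, reference checks at 1 cycle / Cq 30 — are the validated values
of the JAK2 V617F assay and are all overridable via `QcPolicy` or the
run config.

Percent rendering: two decimals at ≥ 1%, four significant digits below
1% (trace results like 0.001526% keep their digits); computation is
always full precision.

## Copy-number arithmetic

DNA input normalisation uses absolute quantification of RNase P:
`copies = 10^((Cq − intercept)/slope)` inverts the calibration line
(the packaged line is `Cq = −3.26·log10(copies) + 29.75`; note its
slope implies an efficiency of 102.7% — a published figure of 102.4%
for the same line evidently came from the unrounded slope). Copies
convert to concentration as
`ng/µL = copies × 0.0033 ng (haploid genome) / 2 (dsDNA) / 5 µL
(input volume)`; 7576 copies ≈ the 25 ng per reaction used throughout.

## Probit limit of detection

Replicate detection counts at decreasing mutant-allele levels are fit
by maximum-likelihood probit regression, `P(detect) = Φ(a + b·dose)`,
and the LOD is the level at 95% fitted detection probability,
`(Φ⁻¹(0.95) − a)/b`, with a 95% Wald interval by the delta method on
the dose scale.

**Dose metameter.** The default dose is the *linear* percent, not its
log10. This was decided by back-checking both candidates against the
packaged panel's published probability-of-detection column: the linear
dose reproduces the entire column (0.937/0.284/0.049/0.015/0.007
fitted vs 0.939/0.280/0.047/0.013/0.006 published) and the published
LOD and CI; the log10 dose does not (LOD 0.161, probability 0.38 at
the 0.073% level). `dose_scale="log10"` remains available — it is the
more common choice when levels span many decades — but the linear
scale is what this panel's original analysis used. The CI is a Wald
interval; fiducial (Fieller) intervals, the default of some commercial
packages, will differ slightly in small panels.

Complete separation (no partially detected level between the all-miss
and all-hit regions) leaves the slope unidentified; the fit raises a
diagnostic error rather than returning a silent estimate. Tests check
the MLE against an independent nested-grid likelihood search and the
CI against parameter-recovery simulations.

## Limit of quantification

Each dilution level is assessed for (a) detection in at least
⌈0.85·n⌉ of n replicates (8 of 9 in the reference design) and (b) no
significant bias: a one-sample t test of the observed percents against
the nominal level, two-sided α = 0.05. The LOQ is the lowest level
passing both whose every lower level fails; if none qualifies the
result is explicitly undefined. Levels can be supplied as raw
replicate observations or as printed (mean, sd, n) summaries, since
published evidence often survives only as summaries.

## Precision

A balanced day × replicate design (default 9 days × 2) is decomposed
by one-way random-effects ANOVA with day as the factor: within-run
variance is the within-day mean square, the between-day component is
`max(0, (MS_between − MS_within)/n_rep)` (truncated at zero), total is
their sum, and each CV is `100·√var / grand mean`. Unbalanced designs
are rejected rather than approximated.

## Method comparison and agreement

Quantitative agreement reports Pearson r (with two-sided p), OLS of
test on reference (slope, intercept, R²), and Bland–Altman statistics
on differences `d = test − reference`: bias = mean(d), limits of
agreement bias ± 1.96·SD(d), and a t-based 95% CI of the bias.
Positive bias therefore means the test method or specimen reads
higher. Published agreement intervals of this width are limits of
agreement, not CIs of the mean, which is why both are reported. A
subgroup split at a reference threshold (default 20% mutant allele)
mirrors low- vs high-burden analyses. Qualitative agreement is
total / positive / negative percent agreement from the 2×2 table,
with empty strata reported as undefined rather than 0 or 100. No
multiplicity correction is applied anywhere; each analysis answers its
own question.

## Simulator

`SimulationConfig` generates one sample's Cq quartet from a
mechanistic model:

| parameter | default | meaning |
|---|---|---|
| `true_mutant_fraction` | — | p, fraction of mutant alleles |
| `total_allele_copies` | 7576 | N, alleles per reaction (25 ng at 0.0033 ng/haploid genome) |
| `efficiency_wt`, `efficiency_mut` | 1.0 | per-cycle efficiency of each reaction |
| `single_copy_cq` | 42.0 | c0, Cq of one template copy |
| `rp_single_copy_cq` | 42.0 | same for RNase P (gives reference Cq ≈ 29 at N = 7576) |
| `noise_sd` | 0.15 | Gaussian Cq noise, cycles |
| `crosstalk_delta` | 18.0 | wrong-allele extension delay, cycles (∞ = perfectly specific) |
| `total_cycles` | 45.0 | censoring: later Cqs report undetermined |
| `sampling` | stochastic | Binomial(N, p) allele draw, shared by the pair; `deterministic` uses m = N·p |

Cq = `c0 − ln(T)/ln(1+E) + ε` with effective templates
`m + w·2^-Δ` (mutant reaction) and `w + m·2^-Δ` (wild-type reaction);
an effective template below one copy is undetermined. The binomial
draw is shared between the paired reactions because both are pipetted
from one extract; per-reaction variation enters only through the Cq
noise. The default crosstalk delay of 18 cycles pushes wrong-allele
signals past 45 cycles for typical inputs, making false positives
rare — a plausibility choice, not an estimate, as the phenomenon was
observed only once in the reference data. Dilution series rescale the
drawn copies (serial dilution of one extract); detection panels count
replicates whose mutant reaction amplified before the Cq cut-off — the
raw positive-signal criterion, since the LOD estimated *from* the
panel cannot gate it. Paired blood/serum cohorts give serum a true
fraction of `logistic(logit(p) + δ)`, δ = 0.25 by default: a
phenomenological enrichment that vanishes at 0% and 100% and is
largest mid-range, calibrated to give a cohort-mean serum-minus-blood
bias of roughly 4 points for a mid-range cohort. It models no
coagulation mechanism.

Every function consumes randomness from a single seeded generator in a
documented order (subjects → pair binomial → the four Cq noises), so
identical seeds give bit-identical outputs.

**What the simulator does not emulate** — and hence what passing tests
do not show about real data: no per-cycle fluorescence kinetics or Cq
calling; no PCR inhibitors or extraction losses; no single-molecule
amplification stochasticity beyond the binomial template draw, so
near-zero levels fail by running out of copies rather than by the
gradual linearity loss real assays show (its simulated LOQ is set by
the detection prerequisite, and its intrinsic LOD, ≈0.04%, is better
than the validated 0.15% of the physical assay); Cq noise is
homoscedastic in cycles, whereas real low-template reactions are
noisier.

## Problem sizes and numerical choices

Stochastic tests run at modest, fixed sizes chosen to make their
Monte-Carlo error small relative to the asserted tolerances: 18
replicates for recovery checks (the design size of the precision
experiment), 9×2 precision designs, 35-subject paired cohorts
(matching the positive stratum of the reference comparison), 400-day
designs for variance-component recovery, and 4000–5000 differences
for limits-of-agreement coverage. All are seeded. Probit fits use
IRLS (statsmodels GLM) with the separation check described above;
variance components truncate at zero; slope comparisons use the
extra-sum-of-squares F test globally and pooled-variance t tests
pairwise, with exact-fit series (zero residual) short-circuited to
p = 1 or 0. Standard-curve fits require ≥ 3 points spanning ≥ 1
decade by default (relax `min_log10_span` for short 2-fold series).

## Known limitations

- The LOD CI method (Wald/delta) is one of several defensible choices;
  only the point estimate is treated as canonical.
- The serum-enrichment parameter δ is phenomenological; it reproduces
  the magnitude and fraction-dependence of the specimen bias, not its
  biology.
- The CSV reader accepts only the tidy export dialect; vendor exports
  must be pre-mapped.
- Efficiency estimation assumes a log-linear dilution response; it is
  not robust to points below one template copy (those come back
  undetermined and are dropped by `standard_curve_points`).
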