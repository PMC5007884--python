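# Methods

This note documents the statistical model behind `dropval`, the choices
made where the design was genuinely open, and what the tests do and do not
demonstrate.

## Quantification model

A ddPCR well partitions the PCR mix into `A` accepted droplets of volume
`Vd` (default 0.834 nL, the value measured for this instrument/supermix
combination; relative standard uncertainty 1.8 %). Copy occupancy per
droplet is Poisson with mean λ = c_PCR·Vd, so the probability of a
negative droplet is e^(−λ) and the estimator inverts the observed negative
fraction. We use the finite-partition form

    copies = ln(1 − P/A) / ln(1 − 1/A),   c_PCR = copies/(A·Vd),

with natural logarithms (any common base cancels in the ratio, but only ln
makes the familiar approximation `c ≈ −ln(1 − P/A)/Vd` exact in the large-A
limit; for A ≥ 10⁴ the two agree to < 0.01 % relative — property-tested).
`P = A` (saturation) has no finite estimate and is flagged, not guessed.
Concentrations are copies/µL; `Vd` is carried in nL with an explicit 10⁻³
conversion. Dilution factors are gravimetric: masses over densities, the
pre-sample-mix density defaulting to 1.0353 g/mL. (The source record of
that density reads "g/L", which is physically impossible for an aqueous
supermix; we treat it as g/mL and note the assumption here.)

## Classification, rain, and QC

Cluster boundaries are defined as mean ± 4·SD, so "rain" is any droplet
strictly between the negative cluster's upper and the positive cluster's
lower boundary; droplets exactly on a boundary belong to their cluster.
Four re-analyses bracket the threshold ambiguity: midpoint threshold
(routine), low threshold (all rain positive), high threshold (all rain
negative), and rain removal (rain dropped from both P and A). Ties at a
threshold count positive — the convention is arbitrary, documented, and
covered by a test.

Cluster estimation is 1-D two-means (iterated midpoint splitting), which
automates the analyst's by-eye clustering; a manual per-plate threshold can
be supplied instead, and one threshold applies to all wells of a plate.

Well QC implements three exclusion rules: (i) fewer than 10,000 accepted
droplets (exact on the count, amplitude-free); (ii) cluster means "clearly
different" from the rest of the plate — operationalised, since no number is
stated anywhere, as a robust z-score versus the plate median scaled by
1.4826·MAD with default cutoff 5; (iii) ≥ 5 % of accepted droplets below
the negative cluster's lower boundary. Without amplitudes, rules (ii)–(iii)
are reported "not evaluated" rather than silently passed.

## Validation statistics

Per concentration level, replicate `c_sample` values grouped per run enter
a one-way ANOVA (implemented directly from the sums of squares — it is the
primitive everything else builds on — and verified in tests against an
independent brute-force oracle and scipy's F statistic). Relative
repeatability and run-to-run components follow the mean-square
decomposition; when `MS_between < MS_within` the run component is clamped
to zero and flagged (a negative variance estimate means the run effect is
indistinguishable from zero). For unbalanced designs `n̄` is the arithmetic
mean of group sizes, matching the "average number of replicates per run"
convention rather than the ISO 5725-3 effective n₀; the difference is
negligible at the mild imbalance (12/16/12) of the reference design.

Per-level components pool by root mean square. Bias per level is
`(c̄_meas − c_cert)/c_cert`; its uncertainty combines the pooled precision
uncertainty with the certified relative standard uncertainties
(certificates state expanded uncertainties at k = 2, so
`u_cert,rel = (U_cert/2)/c_cert` — this convention reproduces the
published 5.4 % bias uncertainty, confirming the reading), averaged as
`Σu²/n_cert` under the root. A bias is significant only when its magnitude
exceeds `U_bias = 2·u_bias`.

The combined expanded uncertainty uses `s_run²/n_run` for the run term,
consistent with the precision-uncertainty formula; the alternative reading
`(s_run/n_run)²` of the combined formula is available behind
`run_term="ratio"` and coincides for `n_run = 1`, which covers every value
the budget is checked against. The threshold component `s_thres` (ANOVA of
threshold-variant results grouped per replicate) joins the budget only
near the working-range limits, where rain has leverage.

One published inconsistency is carried as-is: at the quantification-limit
level the published precision uncertainty (5.0 %) does not follow from the
published repeatability (17.0 %, s_run = 0, 23 results in 2 runs) through
the precision formula (≈ 3.5 %). Where the published chain is reproduced
(reference tables, acceptance script) the 5.0 % is used as an input;
`loq_assess` on raw data always computes the formula honestly.

## Stochastic theory

Two closed forms: the sampling component `1/√T_sampled` (Poisson CV of the
copies drawn into the mix volume, default 20 µL) and the distribution
component `√((e^λ − 1)/A)/λ`, the delta-method SD of λ̂ = −ln(1 − P/A)
under `P ~ Binomial(A, 1 − e^(−λ))`. The conventional cause-tree picture
adds them in quadrature, and `stochastic_curve` reports all three. Note,
however, that Poisson thinning makes two-stage sampling (mix, then
droplets) statistically identical to placing a Poisson number of copies
directly in the analysed volume; the per-well replicate SD therefore equals
the distribution component *alone*, which is why `stochastic_rel_std`
returns it and why the observed 16.9 % replicate scatter at 2.5 cp/µL
matches the 16.8 % distribution term rather than the 22 % quadrature sum.
Monte-Carlo tests pin the distribution formula to within 2–3 % relative
over λ ∈ [0.1, 3].

The theoretical minimum LOD follows the stated zero-copy criterion: the
concentration at which the analysed volume contains no copy with
probability α, `c = −ln(α)/(A·Vd)`, giving 0.239 cp/µL at 15,000 droplets
and 0.359 at 10,000 (α = 0.05). The reference text prints 0.32 and 0.44
for these cases; those values do not follow from the criterion as stated
and their derivation is not reconstructible, so the implementation follows
the criterion and reports the discrepancy here rather than fitting the
printed numbers. A simulation test confirms the implemented criterion:
at c_LOD, 95 % of simulated wells contain at least one copy.

## Synthetic data generator

`simulate_well` draws: accepted droplets A ~ round(Normal(17,000, 1,000))
truncated below at 1 (the instrument spec only says "around 17,000"; the
SD of 1,000 is a realistic instrument scatter chosen once); total copies
K ~ Poisson(c·A·Vd); occupancy by K uniform droplet-index draws (exactly
the multinomial scatter); amplitudes from the negative (1764 ± 135) or
positive (5418 ± 212) cluster. Cluster draws are truncated at ±4 SD so
cluster membership and the rain band are mutually exclusive by
construction — with zero rain the threshold variants agree exactly, which
keeps the "no rain ⇒ no threshold uncertainty" identity sharp instead of
approximate. Rain re-assigns a Binomial(A, rain_fraction) subset a uniform
amplitude strictly between the boundaries: no quantitative rain model is
available (it is genuinely unknown whether rain droplets contain a copy),
so uniform is the maximum-ignorance choice and rain behaviour is
property-tested (monotonicity, negligibility at 0.1 % of positives) rather
than matched to numbers.

Run and assay effects are multiplicative Normal(1, σ) factors drawn per
run/assay. The 1.8 % droplet-volume uncertainty is a *systematic*
assigned-volume uncertainty; it enters the budget as u_Vd and perturbs
simulated volumes only when `perturb_volume=True` is requested — always-on
per-run volume noise would manufacture a spurious run effect and break the
null case (with no run effect, MS_between ≤ MS_within in ≈ half of seeds,
which a test verifies).

What the generator does not emulate: amplification chemistry and
efficiency, droplet coalescence, inhibitors, non-Gaussian cluster shapes,
inter-channel crosstalk. Passing tests therefore demonstrate the
*statistical* pipeline — estimator bias, variance components, budget
arithmetic — not robustness to instrument artefacts beyond the three QC
rules.

## Problem sizes and numerical choices

Test and acceptance-script simulations use 60–200 wells (up to 10,000
count-only wells where only counts matter) — sizes chosen so sampling
error stays a small fraction of the tolerances being checked while the
whole suite runs in well under a minute. Recovery checks use intervals
derived from the sampling distribution of an SD estimate (e.g. a 5 % run
effect over 10 runs has a ≈ 24 % relative SD, hence the [3 %, 7 %]
interval, checked over multiple fixed seeds). A between-assay component
estimated from only two groups has a single degree of freedom and cannot
be recovered to within ±2 points with 90 % probability; the assay-recovery
test therefore uses six simulated assays. Through-origin regression
reports r² on the uncentred total sum of squares (the standard no-intercept
convention; stated because r² conventions differ). Relative quantities are
fractions internally and percentages only at the I/O boundary.

## Known limitations

No between-laboratory reproducibility (single-laboratory scope), no duplex
classification (single channel), no Bayesian/bootstrap alternatives to the
ANOVA decomposition, no parsing of proprietary instrument binary exports
(CSV dialect only).
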