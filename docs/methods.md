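# Methods

## The thermodynamic transcription model

The model predicts a relative mRNA synthesis rate at each embryo position
(percent embryo length, default grid 35.5–92.5% in 0.5% steps) from an
enhancer sequence, an open-chromatin mask, per-TF position weight matrices
(PWMs), and TF concentration profiles.

**Sites.** Every window on either strand scoring at least the PWM threshold
(default: consensus score − 6 bits, configurable) and lying fully within
accessible chromatin is a modeled site. Coordinates are 0-based, half-open.
PWM scores are log-odds in bits against a uniform background; count
matrices convert with pseudocount 0.5.

**Occupancy.** A site's statistical weight at a position is
w = K_eq·2^(score − max score)·[TF], the standard bits-to-Boltzmann
convention with one tunable association scale per TF. Fractional
occupancies are exact expectations under the partition function over all
configurations of mutually non-overlapping bound sites; a cooperativity
factor ω multiplies each configuration once per co-bound, non-overlapping
partner pair whose centers lie within the stated range. Without
cooperativity, marginals come from a forward/backward interval dynamic
program (the configuration set factorizes around any bound site); with
cooperativity, from an exact set-state DP over a sliding window whose
horizon covers both site extents and the cooperativity range, rerun with
each site forced bound. Both routes agree with brute-force enumeration to
1e-9 on instances of up to 12 sites (this is asserted in the tests and
re-measured by the acceptance script).

**Regulatory mechanisms.** Bound repressors quench nearby bound
activators multiplicatively: f_eff(a) = f(a)·Π_q (1 − E_q·f(q)) over
repressor sites q within the quench range (center-to-center distance).
A factor carrying a coactivation rule does not quench; each of its sites
instead contributes α·f·g, where g = 1 − Π(1 − f(partner)) is the
probability that at least one partner-activator site is bound within
range. Net activation is N = Σ α·f_eff over activator sites plus the
coactivated contributions, and the synthesis rate is the saturating law

    rate = R_max · σ(β·(N − N₀)),    σ = logistic.

The logistic stands in for a diffusion-limited Arrhenius law with
competition; it preserves the monotone, saturating, threshold-like
behavior those mechanisms imply, and all rate constants sit behind
`RateParams` so another functional form can be substituted. Displayed
expression profiles subtract the N = 0 baseline and rescale to a maximum
of 1 (an all-baseline profile is reported as zeros); perturbation
statistics use the raw rate, whose logarithm is floored at
ε = 10⁻⁶ × the wild-type profile maximum, because the log of an
arbitrarily silenced output is otherwise unbounded.

## Perturbation protocols

*TF levels.* One TF is multiplied everywhere by s = exp(A·X),
X ~ U(−1, 1); Var(log s) = A²/3 analytically. The headline magnitude is
A = 0.1; the full published protocol spans A = 0 to 3 in steps of 0.1 with
10,000 replicates each (310,000 simulations), which the package enumerates
but the desk-scale drivers subsample. ρ is the ratio of the variance of
the log output fold-change (relative to the unperturbed output at the same
position) to Var(log s).

*Sequence.* r positions are drawn uniformly **without replacement** from
accessible bases and each substituted by one of the three alternate bases
with equal probability; r spans 1 to 10% of the accessible length on an
approximately geometric 30-point integer grid. Note the fitted saturation
law is the with-replacement form as printed; the discrepancy is real but
small (hit probability 0.41625 vs 0.40951 at n = 100, n₀ = 10, r = 5) and
is reported explicitly by the acceptance script rather than hidden.

*Deterministic scans.* The single-nucleotide scan computes, per accessible
base, the population variance of the floored log output over the three
substitutions (wild type excluded — the outcome space of the r = 1
protocol). The count of "sensitive nucleotides" from such a track places
the threshold inside the largest gap of the sorted sensitivity
distribution, the conventional choice when sensitivities are strongly
heterogeneous. The pairwise scan evaluates all nine substitution
combinations per base pair, subsampling pairs when their number exceeds a
cap.

## Saturation fitting and classification

`fit_saturation` minimizes squared deviation from
V(r) = V₀(1 − (1 − n₀/n)^r) (+ c₀ + c₁·r with both non-negative when error
terms are enabled) over n₀ ∈ [0, n] and V₀ ∈ [0, 4·max observed], using
seeded generalized simulated annealing (`scipy.optimize.dual_annealing`,
up to 2×10⁴ evaluations) followed by a Nelder–Mead polish; n is fixed
externally (the accessible length for sequence fits, the element length
for MPRA fits). Fits are unweighted by default; per-point weights are
exposed. r_half derives from the fitted n₀ via
r_half = −1/log₂(1 − n₀/n). A curve is classified r-robust versus
distributed by comparing the saturating fit against a through-origin
linear fit with small-sample-corrected AIC; |ΔAICc| < 2 (or an all-zero
curve) is indeterminate.

MPRA fits default to inverse-variance weighting (weights 1/y²): each
point is itself a sample variance whose sampling error scales with its
value, and unweighted fits of the four-parameter error-adjusted model left
n₀ and c₁ weakly identified against each other.

## The synthetic stripe system

The default fixture emulates the gap-gene configuration around the second
*even-skipped* stripe: eight factors — an anterior activator gradient
(bcd-like, α = 3), a coactivated anterior factor (hb-like, α = 0.5, gated
by bcd), weak broad activators (cad-like, dst-like), and repressors whose
domains flank the stripe (gt-like anterior + posterior, kr-like central,
kni-like posterior, tll-like terminal; quench efficiency 0.9). PWMs are
generated at 1.6 bits mean information per column with heterogeneous
non-consensus probabilities (a Dirichlet draw interpolated toward the
consensus point mass), so the three alternates of a base score
differently, as in measured motifs. The 240-bp element carries 13 planted
consensus sites; quenching is element-wide (240 bp) because the element is
far shorter than the kb-scale loci the range convention comes from. Rate
parameters R_max = 1, N₀ = 4, β = 4 put the wild-type peak high on the
saturating law while deep damage falls to the log floor.

Run through the model, this configuration expresses a single interior
stripe peaked at 40.5% embryo length with both flanks below 10% of peak.
Its sensitivity geography reproduces the qualitative findings the
formalism predicts: ρ for the anterior-border repressor (gt) is ~47 at
the border and ~0.2 at the peak; the single-base scan finds fewer
sensitive nucleotides at the peak (6) than at the interstripe (8); the
interstripe variance-vs-r curve saturates and classifies r-robust, while
at the peak, over the protocol's r ≤ 10% window on this short element,
the variance is still rising and the classifier reports the linear
regime — the element is too short for the peak curve to saturate within
the protocol's range, a scale effect of the 240-bp fixture, not of the
formalism.

What the generators do *not* emulate: measured atlas noise structure,
chromatin-state dynamics, indels (MPRA mutation counts are taken as
given), phylogenetic correlation between species in alignments (species
are independent given the planted conservation profile), and position
effects in MPRA barcodes. Passing tests therefore demonstrate the
correctness and statistical power of the machinery under the stated
generative assumptions, not agreement with any particular measured
dataset.

## Toy systems with known truth

The r-robust toy system has n parameters of which the first n₀ are
sensitive; its output rule log M = w·log s_(lowest perturbed sensitive
index) realizes non-cumulative sensitivity exactly, and mean-zero
symmetric log-scales make Var(log M) = P(≥1 sensitive hit)·V₀ exact with
V₀ = w²A²/3. Because the output law depends only on the hit indicator and
one i.i.d. scale, the sampler draws a hypergeometric hit count and a
single uniform — an exact, fast equivalent of the literal subset draw,
which is retained (`sample_toy_system_explicit`) and cross-checked in the
tests. The geometric-mean system realizes distributed robustness with
Var(log M) = V_K·r/n² in expectation.

## MPRA analysis

Barcode tables carry (barcode, mutation count r, DNA/RNA UMI counts per
replicate). Barcodes must be observed in the DNA pool in **all**
replicates (the stricter reading of an ambiguous protocol sentence;
`mode="any"` is exposed). Expression is (RNA + ½)/(DNA + ½) — a standard
continuity correction, configurable — and each replicate's Var(log
expression) per r enters the curve only when the stratum holds ≥ 100
barcodes. The generator plants latent log-expressions with variance
V₀(1 − (1 − n₀/n)^r) + c₀ + c₁·r shared across replicates and realizes
counts by Poisson sampling at mean depth 50 UMIs; recovery runs use
r = 1..60 (10% of the n = 600 element, mirroring the sequence protocol's
r span) with 10⁵ barcodes.

## Design

Sequence design fixes the model and anneals a uniform-random sequence of
the requested length (fully accessible) under single-base proposals and
Metropolis acceptance; the objective is the RMS deviation between the
rescaled predicted profile and the target over the grid, accepted at
rms ≤ 0.10 by default within a budget of 200×length evaluations. The
temperature cools geometrically by 0.98 per stage with stages sized so
the total decay spans three decades across the budget — cooling tied to
sequence length alone left the search effectively isothermal at realistic
budgets. The published protocol's grid (10 designs at every length
200–1000 bp) enumerates 8010 tasks; the desk-scale driver runs a small
slice and the grid size is checked by enumeration.

## Conservation

Per-base conservation is the percent of non-reference species carrying
the reference nucleotide in that alignment column (gaps mismatch;
columns where the reference is gapped carry no coordinate and are
skipped). The association with sensitivity compares mean conservation of
the n₀ most-sensitive bases against all others and reports a Spearman
rank correlation (mid-ranks for ties, asymptotic two-sided p; flagged
undefined on constant input).

## Problem sizes and determinism

Every stochastic routine takes an explicit seed, and replicate streams
split deterministically from it; identical inputs give bit-identical
outputs. The analysis drivers and acceptance script use desk-scale sizes
chosen to make each stage's statistical claim testable in seconds to a
few minutes: 10⁴ replicates per r for toy recovery (20 planted-truth
simulations), 10⁶ draws for the sampling-gap measurement, 10⁵ replicates
for the distributed laws, 2×10³ replicates per position for stripe ρ and
variance curves, 10⁵ barcodes for MPRA recovery, and 200 random
instances for the occupancy cross-check.
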