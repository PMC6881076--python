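# regrobust

Robustness analysis of enhancer-driven gene regulation: how many nucleotides
of a regulatory sequence actually matter, and how fragile is gene expression
to fluctuations in transcription-factor (TF) levels?

Developmental enhancers are *robust yet fragile*: expression tolerates most
random mutations, but a handful of sensitive nucleotides — and TF
fluctuations at expression-domain borders — can change output drastically.
`regrobust` implements the quantitative machinery for studying this on a
sequence-level thermodynamic model of transcription (patterned on the
regulation of *Drosophila even-skipped* stripe 2), together with seeded
synthetic-data generators so every analysis runs end to end without external
downloads. It is aimed at computational biologists studying regulatory
robustness, mutational scanning, and MPRA saturation mutagenesis.

## The formalism

A property *M* of *n* parameters is ***r*-robust** when only a small number
*n₀* of parameters are individually sensitive and their effects are not
cumulative. Selecting *r* of *n* parameters at random hits at least one
sensitive parameter with probability 1 − (1 − n₀/n)^r, so the log-variance
of the output follows the saturation curve

    Var(log M) = (1 − (1 − n₀/n)^r) · V₀,

and the half-saturation point obeys n₀ = n·(1 − 2^(−1/r_half)). In
contrast, a **distributed-robust** property (e.g. the geometric mean
M = (K₁⋯K_n)^{1/n}) shows Var(log M) = V_K·r/n², linear in *r* and equal to
V_K/n at full perturbation. Sensitivity to a single input is measured by
the robustness ratio

    ρ = Var(log fold-change output) / Var(log fold-change input),

with ρ < 1 robust and ρ > 1 sensitive; inputs are perturbed by the fold
ratio s = exp(A·X), X ~ U(−1, 1), so Var(log s) = A²/3.

For sequences, the parameters are nucleotides: the model maps an enhancer
(FASTA + open-chromatin BED mask) and TF concentration profiles along the
anterior–posterior axis to a relative mRNA synthesis rate per position via
thermodynamic occupancy of PWM-predicted binding sites (steric competition,
pairwise cooperativity), short-range quenching of activators by bound
repressors, partner-gated coactivation, and a saturating rate law on the
net activation *N*.

## Layout

- `src/regrobust/` — the library: `model` (thermodynamic model), `perturb`
  (TF and sequence perturbation, sensitivity scans), `robustats` (saturation
  fits, ρ, classification), `design` (in silico enhancer design by
  annealing), `mpra` (barcode-level saturation-mutagenesis analysis),
  `conservation` (alignment conservation vs sensitivity), `synthdata`
  (seeded generators for every input).
- `analysis/01…07_*.py` — numbered drivers that run the study end to end on
  the synthetic stripe system and write tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline quantities from scratch.

## Worked example

Fit the sensitive-parameter count of a toy r-robust system (n = 1000
parameters of which 20 are sensitive), from 10,000 Monte-Carlo perturbation
replicates per *r*:

```python
from regrobust.perturb import default_r_grid
from regrobust.robustats import fit_saturation, classify_robustness
from regrobust.synthdata import ToyRRobustSystem, toy_curve

system = ToyRRobustSystem(n=1000, n0=20)
curve = toy_curve(system, default_r_grid(1000), A=1.0, n_reps=10_000, seed=42)
fit = fit_saturation(curve, seed=0)
print(f"fitted n0 = {fit.n0:.1f} (planted 20), V0 = {fit.V0:.3f} "
      f"(analytic {system.V0(1.0):.3f}), r_half = {fit.r_half:.1f}")
print(f"curve classified as: {classify_robustness(curve)}")
```

prints

```
fitted n0 = 19.7 (planted 20), V0 = 0.342 (analytic 0.333), r_half = 34.8
curve classified as: r_robust
```

The fitted n₀ recovers the planted count of sensitive parameters; V₀
matches the analytic per-hit variance A²/3; and the model-comparison
classifier recognizes the saturating (r-robust) shape against the linear
distributed alternative.

The full synthetic study — stripe prediction, ρ scans, variance-vs-r
curves, sensitive-nucleotide maps, design, MPRA, conservation — is run by
the numbered scripts:

```bash
python analysis/01_stripe_model.py
python analysis/02_tf_robustness.py
# ...
```

Each prints what it found and writes its tables to `results/`.

## A note on the CLI

A thin `regrobust` command exposes the pipeline for shell use
(`predict`, `mutate`, `perturb-tf`, `fit`, `design`, `mpra`, `conserve`,
`synth`); every subcommand is a wrapper over the library functions above.
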