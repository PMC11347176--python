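# apollon

Computational toolkit for characterizing colorimetric kinase deoxyribozymes
discovered by in vitro selection from doped libraries — in particular the
analyses behind the Apollon motif, a self-phosphorylating DNA enzyme that
turns the colorless substrate pNPP into the yellow product pNP (read out as
absorbance at 405 nm).

It is written for people who run or reanalyze selection experiments: it
simulates doped-pool reselections, processes sequencing reads into
unique-sequence tables, quantifies per-position conservation and pairwise
covariation to infer secondary structure, scores stem-pairing potential
against exact chance nulls, and fits the kinetic and assay statistics used
to characterize the enzymes.

## What it computes

- **Doped-pool simulation.** A library synthesized from an L-nt reference
  with per-position mutation probability *d* (default 21%, uniform over the
  three non-reference bases). Selection rounds apply per-molecule Bernoulli
  survival with probability equal to the molecule's activity, then
  multinomial reamplification; activity is a two-level (or graded) function
  of conserved-core identity and stem-forming ability.
- **Conservation.** Position × base profiles (read- or unique-weighted),
  information content IC = 2 − H (bits), consensus and merged
  high-information "core" ranges, and a doping-rate estimator
  (mean over positions of 1 − f(reference base)).
- **Covariation.** Mutual information of the joint base distribution at each
  position pair, a pairing-consistency fraction among double deviants, a
  Monte-Carlo p-value against matched unselected pools sampled from the
  doping model, and Benjamini–Hochberg q-values. Double and triple mutant
  cycles: R = (A_m12·A_wt)/(A_m1·A_m2), with R ≫ 1 indicating a restored
  (compensatory) interaction.
- **Stem statistics.** Pairing potential k (formable Watson–Crick or G·T
  pairs) of each variant against a stem; the exact chance distribution of k
  under doped synthesis is Poisson-binomial over per-pair complementarity
  probabilities (each obtained by enumerating the 16 dinucleotide outcomes).
  Imino-proton signal expectations: one signal per canonical pair, two per
  G–T/T–G pair.
- **Kinetics and assays.** Michaelis–Menten fitting
  V₀ = V_max[S]/(K_m+[S]), k_cat = V_max/[E], k_obs(S) = k_cat·S/(K_m+S);
  Hill fits y = top·xⁿ/(K½ⁿ+xⁿ) for cooperative metal titrations;
  background-subtracted signal-to-noise and sensor fold-activation;
  turnover counting against a single-turnover control; blank + 3 SD
  detection limits.

## Worked example

```python
import numpy as np
from apollon.doped_pool import (DopingModel, FitnessModel, SelectionConfig,
                                run_selection, simulate_kinetics)
from apollon.structmodel import apollon_reference, apollon_structure
from apollon.covary import covariation_scan
from apollon.kinetics import APOLLON_2, fit_mm

ref = apollon_reference()
structure = apollon_structure()
model = DopingModel(ref, rate=0.21)

fitness = FitnessModel(stems=(("Stem1", 4), ("Stem3", 8)),
                       active_level=1.0, background_level=0.01)
cfg = SelectionConfig(pool_size=20_000, rounds=3, reads_per_round=5_000, seed=11)
result = run_selection(model, fitness, structure, cfg)
print("survival per round:", [f"{f:.3f}" for f in result.survival_fractions])

scan = covariation_scan(result.round_tables[-1], model, n_null=200, seed=3)
for r in sorted(scan, key=lambda r: -r.mi)[:4]:
    print(f"({r.i:2d},{r.j:2d})  MI={r.mi:.3f}  pairing={r.pairing_consistency:.2f}  q={r.q:.3f}")

data = simulate_kinetics(APOLLON_2, np.geomspace(1e-6, 1.5e-3, 8), 0.05, seed=1)
fit = fit_mm(data)
print(fit.summary())
```

prints

```
survival per round: ['0.028', '0.664', '0.994']
(41,63)  MI=0.313  pairing=1.00  q=0.005
( 4,21)  MI=0.282  pairing=1.00  q=0.005
(45,59)  MI=0.270  pairing=1.00  q=0.005
(43,61)  MI=0.210  pairing=1.00  q=0.005
Michaelis-Menten fit
  converged       True
  Vmax            8.234e-06 +/- 1e-05 M/min
  Km              0.03997 +/- 0.05 M
  kcat            8.234 min^-1
  kcat/Km         206 M^-1 min^-1
  kobs(max [S])   0.2979 min^-1
  non-saturating  True (Km vs max [S] = 0.0015 M)
```

The survival fractions rise from 2.8% to ~100% as stem-forming variants take
over the pool. The four highest-MI position pairs are all planted stem pairs
and their double deviants are fully complementary (pairing = 1.00). The
kinetic fit runs in the non-saturating regime — V_max and K_m individually
carry large uncertainties, but the well-identified quantities are the
catalytic efficiency k_cat/K_m (≈ 206 M⁻¹ min⁻¹ here) and k_obs at the
highest tested substrate concentration (≈ 0.30 min⁻¹ at 1.5 mM).

## Command line

The same stages are scriptable via the `apollon` console command:
`simulate-pool`, `select`, `process-reads`, `profile`, `covary`, `stems`,
`fit-kinetics`, `assay-stats`. Each subcommand accepts a YAML config
(unknown keys rejected; flags override) and writes TSV files with a
provenance header recording version, seed and parameters. See
`examples/demo_selection.yaml`:

```bash
apollon select --config examples/demo_selection.yaml --out-dir rounds/
apollon covary --table rounds/round_3.tsv --n-null 200 --seed 3 --out scan.tsv
```

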