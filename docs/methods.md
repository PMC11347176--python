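# Methods

This note documents the models behind the package, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter.

## Doped-library model

A doped library is synthesized from a reference sequence of length L with a
fixed per-position substitution probability *d*. The packaged default is
d = 0.21 on an 85-nt reference, matching the mutagenesis rate used to build
the reselection libraries for this family of deoxyribozymes. The synthesis
mixture over the three non-reference bases is not reported; the default is
uniform (1/3 each) and is exposed as `DopingModel.alt_dist`. Positions
mutate independently, which is the intended behavior of doped synthesis and
the assumption behind every null distribution in the package.

Under this model the base distribution at a position with reference base r
is P(r) = 1 − d and P(b) = d/3 for each other base. Two consequences used
throughout:

- the information content of an unselected position is
  2 − H(0.79, 0.07, 0.07, 0.07) ≈ 0.926 bits at d = 0.21;
- the complementarity probability of a pair of positions is obtained
  exactly by enumerating the 16 dinucleotide outcomes (≈ 0.699 for a
  reference Watson–Crick pair at d = 0.21 with G·T allowed, ≈ 0.749 for a
  reference G–T pair, which has two high-probability complementary
  outcomes).

## Selection model

Selection is per-molecule Bernoulli survival with probability equal to the
molecule's activity, followed by multinomial resampling back to the working
pool size (unbiased PCR) and multinomial sampling of a fixed number of
sequencing reads from the survivors. The generative fitness is deliberately
simple: a variant is fully active iff it matches a conserved-core consensus
within a mismatch tolerance and can form a minimum number of pairs in each
required stem; everything else sits at a background level (default 0.01
relative activity). A graded mode scales activity with the fraction of
satisfied constraints for power studies.

What this emulates: enrichment dynamics (survival fractions rising over
rounds as in a real reselection), conservation signatures at constrained
positions, and compensatory covariation at stem positions. What it does not
emulate: reaction chemistry and incubation-time stringency (absorbed into
the activity scale), polymerase and sequencing errors (doping dominates),
ligation/gel recovery yields, and real pool complexity — a wet-lab library
has ~1e14 molecules while the simulator works at 1e4–1e5. Tests that pass on
these pools show the statistical machinery is correct and calibrated, not
that it would have the same power at any real dataset's depth and diversity.

Desk-scale defaults used by the test suite and acceptance script: pool size
20,000–50,000, 3–4 rounds, 5,000–8,000 reads per round. These sizes were
chosen as the smallest at which the planted structure is comfortably
recoverable; they are the package's stated study conditions.

## Read processing

Reads are processed substitution-only: primers are located by Hamming
distance (default tolerance 2), read pairs are merged over the longest
overlap whose mismatch fraction passes (higher Phred quality wins
disagreements), and the length filter keeps only the modal surviving length.
Indel-containing reads are dropped rather than aligned because every
downstream analysis indexes positions on a constant-length mutagenized
region. Phred+33 is assumed; no quality trimming is performed.

## Conservation and core extraction

Profiles are read-weighted by default (after selection, abundance carries
the activity signal); unique-sequence weighting is available since read and
unique totals are both reported for such experiments without
stating which weighting produced the logo. Information content uses no
small-sample correction. The "core" is the set of positions with IC at or
above a threshold, reported as merged 1-based ranges. The default threshold
is 1.0 bit; the core-recovery analyses in the tests use 1.2 bits, chosen to
sit between the doped background (≈ 0.93 bits at d = 0.21, plus sampling
noise at realistic read depths) and the information content of selected
positions (≥ 1.35 bits under the packaged study conditions). Consensus ties
are broken by fixed base order (A < C < G < T) and flagged.

The doping-rate estimator (mean over positions of one minus the reference
base frequency, with its standard error from the across-position variance)
is unbiased only on unselected pools; selection depletes non-reference bases
at constrained positions and the estimate then reflects residual diversity,
not synthesis.

## Covariation statistic and null

The covariation statistic is mutual information of the joint base
distribution at a position pair, reported with a pairing-consistency
fraction: among sequences deviating from the reference at both positions,
the read-weighted fraction whose bases are complementary (Watson–Crick, plus
G·T when enabled, the default). MI was chosen because it is assumption-free
about which joint changes matter, while the pairing-consistency fraction
makes "consistent with base pairing" explicit. Significance comes from a
Monte-Carlo null: unselected pools of matched read depth sampled from the
doping model, p = (1 + #{null MI ≥ observed}) / (n_null + 1). The add-one
estimator keeps p > 0 and approximately uniform under the null (verified by
a KS test over 1000 null scans in the acceptance suite; the residual KS
statistic ≈ 0.01 reflects the discreteness of a 100-draw Monte-Carlo grid).
Benjamini–Hochberg q-values are reported across all L(L−1)/2 pairs.

Joint counts for all pairs are computed as 16 position-by-position matrix
products of one-hot encodings, which keeps a full 85-nt scan with 200 null
pools near ten seconds on one CPU.

Mutant cycles use the ratio R = (A_m12·A_wt)/(A_m1·A_m2), which is 1 under
multiplicative independence and invariant to rescaling all activities. The
default rescue threshold is 5; ratios below 1 are called aggravating. Triple
cycles use the third-order ratio over the 2³ cube,
(A_m123·A_m1·A_m2·A_m3)/(A_m12·A_m13·A_m23·A_wt). Zero activities are
floored at 0.001 × A_wt (configurable) and flagged, so ratios stay defined.

## Structure model and pairing nulls

A structure model is a set of named stems of typed base pairs (canonical or
G–T/T–G wobble). Pairing potential k of a variant against a stem counts the
stem pairs at which the variant's bases are complementary; G·T counts by
default because the modeled structure itself contains G–T pairs. The chance
distribution of k for one doped molecule is Poisson-binomial over the exact
per-pair probabilities and is computed by convolution; the probability that
m independent molecules all reach k ≥ t is tail(t)^m. Expected imino-proton
signal counts are one per canonical pair and two per wobble pair (the two
tautomers of a G–T pair each resonate); terminal-pair fraying is ignored.

The packaged 85-nt reference and three-stem model (4 + 4 canonical pairs in
Stems 1 and 2, 4 canonical + 4 wobble in the 8-pair Stem 3, total 12
canonical + 4 wobble) is a synthetic reconstruction: the reference structure diagram
is graphical, so only its stated facts are honored — core at positions 1–8
and 34–64, a Stem 1 pair at (3, 22), four deletable canonical Stem 2 pairs,
an 8-pair near-invariant Stem 3, and the 12 + 4 pair composition. Analyses
that depend only on composition (signal counts: 20 full, 16 after Stem 2
deletion) are coordinate-free; coordinate-dependent tests treat the fixture
as the planted ground truth of a simulation, not as the real molecule.

## Kinetics

Initial-rate data are fitted to V₀ = V_max[S]/(K_m + [S]) by nonlinear
least squares with both parameters bounded positive, k_cat = V_max/[E], and
k_obs(S) = k_cat·S/(K_m + S). Weighting assumes a constant coefficient of
variation (each observation's sigma proportional to its rate), the usual
error model for initial rates spanning decades of substrate; ordinary least
squares is available. Initialization uses the Hanes–Woolf linearization
([S]/V₀ regressed on [S]), which is exact on noiseless data and avoids
stalling on the V_max–K_m ridge when the design is non-saturating; it falls
back to (max rate, median [S]) when degenerate. Convergence tolerances are
1e-12; a K_m collapsing below 10⁻³ of the smallest tested concentration
(plateau data) is flagged unconverged. When fitted K_m exceeds the largest
tested [S], the result is flagged non-saturating: individual V_max and K_m
are then poorly identified and the quantities to report are k_cat/K_m (the
initial slope) and k_obs at a tested concentration (on-data interpolation).

The packaged enzyme presets encode the reported characterization of the two
isolates at 1 µM enzyme over 1 µM–1.5 mM substrate, a regime reported as
non-saturating. Since the two reported observables (k_cat/K_m ≈ 200
M⁻¹ min⁻¹ and k_obs ≈ 0.3 min⁻¹ at 1.5 mM) are exactly simultaneous only as
K_m → ∞, the preset fixes K_m = 30 mM (20× the highest tested concentration,
clearly non-saturating) and k_cat = 6.15 min⁻¹, splitting the rounding error
evenly: k_cat/K_m = 205 M⁻¹ min⁻¹ and k_obs(1.5 mM) = 0.293 min⁻¹. The
initial-isolate preset has the same K_m and 10-fold lower k_cat, matching
the reported 10-fold efficiency gap. Synthetic replicates use 8 log-spaced
concentrations and 5% multiplicative Gaussian noise truncated at zero.

Hill fits use y = top·xⁿ/(K½ⁿ + xⁿ) with the bottom fixed at zero and
n ∈ (0, 20]; reported zinc titrations give coefficients between 2.7
and 3.8 without printing the equation, so the four-parameter-minus-one form
is this package's choice. Assay arithmetic: signal-to-noise and sensor
fold-activation subtract the buffer blank from numerator and denominator
(undefined when the control does not exceed the blank); turnovers are the
ratio of background-subtracted signals against a matched single-turnover
control; the detection limit is the smallest tested concentration whose
mean signal exceeds blank + 3 SD, a conventional rule adopted because the
reported limits state no formula. Beer–Lambert conversion requires an
explicit molar absorptivity — none is hard-coded.

## Known limitations

- The fitness model is a caricature: real activity landscapes are graded and
  epistatic beyond stem/core logic.
- The covariation null conditions on the doping model, not on the observed
  marginal frequencies; after strong selection the null is conservative for
  highly conserved positions (few double deviants carry the signal).
- The read-processing chain is a desk-scale stand-in, not a replacement for
  production trimmers/mergers; it handles substitutions only.
- Detection limits depend on the tested concentration grid; the rule reports
  a tested concentration, never an interpolated one.
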