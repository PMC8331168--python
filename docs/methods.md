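# Methods

## Scope and model

prmkit implements the computational core of a label-free targeted-proteomics
workflow.  The measurement model is deliberately simple: for each targeted
transition (peptide, precursor charge, fragment ion) the signal in a sample is
a chromatographic peak whose integrated area is proportional to

    protein amount x fragment response x charge-state fraction
                   x occupancy (or 1 - occupancy) for phospho/nonphospho forms.

Relative quantities are therefore ratios in which the response factors cancel:
protein abundance ratios cancel peptide/fragment responses between samples, and
the stoichiometry P = 100 Σpt / (Σt + Σpt) assumes the phospho and nonphospho
forms of one peptide have equal summed response over the targeted fragments.
The synthetic-data generator enforces that assumption by construction (one
fragment pattern shared by both forms), which is exactly the structure the
analysis needs to be unbiased; with form-specific responses P becomes a
response-weighted, monotone transform of the true occupancy — a known
limitation of label-free occupancy estimates in general.

## Synthetic data generator

The generator emulates a genotype x condition x replicate design (default
n = 3 per cell, the common design for targeted plant stress panels):

- **Peaks**: exponentially modified Gaussians; `tau = 0` reduces exactly to a
  Gaussian, so the closed form area = amplitude · sigma · sqrt(2π) anchors the
  integration tests.  Defaults: sigma 0.05 min with ±10% per-peptide jitter,
  tau 0.02 min — ~10-s-wide, mildly tailing nano-LC peaks.
- **Grid**: fixed 0.01-min step over a 0–60 min gradient; chromatograms are
  materialized only inside each transition's 3-min scheduling window.  At
  sigma ≥ 5 grid steps the trapezoid error is far below every test tolerance.
- **Noise**: per-point multiplicative log-normal with mean 1 and a stated CV
  (default demo value 10%), applied to signal plus baseline; additive constant
  baseline (2 a.u.) with a linear drift (0.02 a.u./min).  Negative values
  cannot occur (log-normal), matching count-like intensity data.
- **Library**: fragment response patterns drawn once per peptide from a
  Dirichlet (concentration 2) scaled by a log-normal response factor, then
  frozen — fixed "spectral library" semantics.  iRT values are drawn once per
  peptide and mapped to RT by a configurable linear calibration; phospho forms
  elute 2 iRT units earlier.
- **Charge states**: 2+ carries 65% and 3+ 35% of each peptide's signal, for
  both phospho and nonphospho forms.
- **RNG**: one root seed; every stream (library, iRT, peak shape, per-trace
  noise) derives from it by CRC32-named sub-seeding, so identical
  (config, seed) pairs are byte-identical and partial re-runs reproduce.

What the generator does *not* emulate: ion statistics/shot noise, co-eluting
interferences, isotope envelopes, missed-cleavage background, RT drift between
runs, or biological replicate variation beyond the injected cell means.
Passing recovery tests therefore demonstrates that the arithmetic and peak
processing are unbiased under the stated noise model, not that the pipeline is
robust to matrix effects in real data.

## Targeting layer

Tryptic digestion cleaves after K/R except before P.  Proteotypic selection
keeps fully tryptic 7–25-mers unique in the background proteome, without
methionine (oxidation is a variable modification in the emulated searches) and
without overlap with annotated modification sites; requiring fewer than three
eligible peptides is an error naming the protein.  Ranking is by descending
summed library intensity with alphabetical tie-breaks, so selection is
deterministic and order-independent.  Fragment m/z uses monoisotopic residue
masses, y = residues + water + proton(s), b = residues + proton(s), phospho
+79.96633 Da; cross-checked in tests against an independent mass library.

## Peak processing

Baseline is the mean of the lowest intensity decile in the window (robust as
long as the peak occupies < 90% of it).  The apex is the raw maximum within
expected RT ± window/2; a peak is called only when apex − baseline exceeds 3×
the MAD-based trace noise (conventional 3σ detection).  Boundaries extend
outward to the first point at ≤ 1% of the baseline-subtracted apex or the
first local minimum, whichever comes first; the local-minimum test runs on a
5-point moving-average copy so point noise does not truncate flanks, while
integration (trapezoidal, baseline-subtracted, clipped at zero) always uses
the raw trace.  A failed call yields area 0 with a `no_peak` flag rather than
a missing value, keeping the abundance and stoichiometry sums defined; flags
propagate into the output tables.

## Quantification conventions

- The abundance sum runs over *all* targeted peptides (three or four).
- Reference normalization divides by the arithmetic mean of the reference
  (wild-type, or wild-type control) replicates, matching how replicate means
  are usually plotted; a geometric mean was rejected for simplicity.
- Stoichiometry sums fragments and both charge states of both forms; if both
  totals are zero the result is undefined (flagged NaN), not a number.

## Statistics

Student's t uses pooled variance (the classical "Student's t test", not
Welch).  Zero pooled variance is handled by convention: p = 1 for equal means,
p = 0 with a warning otherwise.  Tukey HSD p-values come from statsmodels; the
compact letter display is an insert-and-absorb construction whose defining
invariant — two groups share a letter iff their adjusted p ≥ alpha — is
verified exhaustively in tests.  The Kruskal-Wallis post hoc is rank-based
Fisher LSD (Conover's procedure: t statistics on mean ranks with the
ties-corrected variance and N − k degrees of freedom), Bonferroni-adjusted
over all pairs and gated on omnibus significance (classical LSD protection);
whether raw-data or rank-based LSD was intended is ambiguous in typical
figure-legend wording, and the rank-based choice is consistent with the
nonparametric omnibus.

qPCR NRQ: RQ_{g,s} = E_g^(mean Cq − Cq), normalization factor = geometric mean
of reference-gene RQs, NRQ = RQ/NF.  Centering uses the across-sample mean Cq
per gene (a configurable calibrator sample is provided).  Standard errors
propagate technical-replicate SDs of the Cq means by a first-order delta
method, including the covariance term when the gene is itself a reference.
The per-sample Cq-shift invariance of NRQ is exact only when all efficiencies
are equal; with unequal efficiencies a residual of order (E_g − Ē)·δ remains.

## Conservation

Jukes-Cantor is generalized to k = 20 states, d = −(19/20) ln(1 − (20/19) p),
the standard Poisson-corrected form for proteins; p uses pairwise gap
deletion, and p ≥ 19/20 raises a saturation error.  UPGMA uses size-weighted
averaging with ties broken by the lexicographically smallest pair of cluster
representatives, making topologies deterministic and taxon-order independent;
an independent naive re-implementation and ultrametric-recovery checks guard
it.  Bootstrap resamples alignment columns with replacement and scores each
original clade by the percentage of replicates containing the same leaf set.
Column similarity takes the modal non-gap residue as consensus (ties by
BLOSUM62 self-score, then alphabetically), scores each residue against it with
BLOSUM62 ≥ threshold (default 1), and bands the percentage as exactly-100 /
[80, 100) / [60, 80) / below-60 — half-open intervals, since the verbal band
edges overlap; gaps are excluded from the percentage and all-gap columns are
uncolored with an undefined percent.  The motif scanner accepts residue
letters, `x` wildcards and bracketed alternatives, dash-separated or not, and
reports overlapping matches via lookahead.

## Problem sizes

The demo study used throughout the tests and the acceptance script targets two
proteins (three proteotypic peptides each at 2+/3+ with three fragments, plus
one phospho/nonphospho pair) over 12 samples — 576 chromatograms of ~300
points.  Stochastic recovery uses 100 independent simulations of a 2-genotype
× 3-replicate design at CV 10%; the bootstrap demonstration uses 6 taxa × 200
columns × 1,000 replicates; null calibration uses 10,000 simulated t tests.
These sizes give stable estimates (binomial/Monte-Carlo error well inside the
asserted bounds) while keeping a full run in tens of seconds.

## Known limitations

- No cross-run RT alignment, interference removal, smoothing beyond the
  boundary-search average, or co-elution deconvolution.
- Occupancy estimates assume equal phospho/nonphospho response; real
  ionization differences bias P (see above).
- The Kruskal-Wallis omnibus with n = 3 per group is coarse (minimum
  achievable p ≈ 0.027 for k = 3), so letter displays on tiny samples are
  conservative.
- The conservation module consumes a precomputed MSA; alignment quality is the
  caller's responsibility.
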