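# Methods

## Model

The substitution process on each branch is a continuous-time Markov chain on
the 61 sense codons of the universal nuclear genetic code (stop codons are
trimmed from input CDS and are outside the state space; codons are ordered
lexicographically over T < C < A < G, a fixed documented constant).  For
codons *i* and *j* differing at exactly one nucleotide position,

    q_ij = pi_j · kappa^{I[transition]} · omega^{I[nonsynonymous]} / s ,

zero for multi-position changes, diagonal set so rows sum to zero, and the
normaliser `s` chosen so that `-sum_i pi_i q_ii = 1`: one unit of branch
length is one expected substitution per codon at equilibrium, making branch
lengths comparable across nested models that share frequencies.  The chain
is time-reversible (`pi_i q_ij = pi_j q_ji`), so the likelihood does not
depend on root placement along a branch.

Equilibrium frequencies default to F3x4: the product of position-specific
observed nucleotide frequencies over the three codon positions, restricted
to sense codons and renormalised.  Counts ignore missing states; any
unobserved nucleotide receives a floor of 1e-6 before renormalisation so no
sense codon has probability zero.  `equal` and `F1x4` (pooled positions)
modes are available; the mode, like all tolerances and bounds, lives in one
`FitOptions` object.

Gaps, ambiguous nucleotides, and untranslatable triplets are missing data:
their partial-likelihood vectors are all ones, the exact marginalisation.

## Branch classes and hypothesis tests

Gene trees around the WGD carry five branch classes — `0` (pre-duplication
backbone, including the branch into the WGD node), `a1`/`b1` (the two
branches immediately following the WGD), `a2`/`b2` (all later branches in
each paralogous clade).  A partition maps classes to free omegas; nested
partition pairs define the tests R1–R4 (each adds exactly one free omega,
hence chi-square with 1 df):

* R1: single omega vs `omega_0 | omega_wgd`;
* R2: R1-alt vs `omega_0 | omega_{a1,b1} | omega_{a2,b2}`;
* R3: R2-alt vs splitting `a1` from `b1`;
* R4: R1-alt vs `omega_{a1,a2} | omega_{b1,b2}`.

Kappa is shared across branch classes (one kappa per orthogroup, the usual
branch-model convention; the split is only in omega).  Named variants of R2
and R3 that appear in some analyses without a published definition are
supported as user-defined custom partitions rather than guessed.

Orthogroup-level labels derive from the tests: rate-change (R1 rejected);
strong purifying selection when the fitted non-WGD omega in the R1
alternative is below 0.02; the slow clade under R4 is the one with the
smaller fitted omega.  "Average dN/dS of a branch set" is reported as the
ML omega of that branch class, not a per-branch average, because the
branch model estimates exactly one omega per class.  Multiple testing uses
raw p < 0.05 per test by default; a Benjamini–Hochberg flag exists but is
off.

## Likelihood, gradients, optimisation

Alignment log-likelihoods use Felsenstein pruning over site patterns
(duplicate columns compressed with weights), with per-node rescaling of
partials to prevent underflow on larger trees.  Transition probabilities
come from the eigendecomposition of the symmetrised generator
`S = D^{1/2} Q D^{-1/2}` (D = diag(pi)); rows of `P(t)` are clipped to
[0, 1] and renormalised so they sum to one within 1e-10 on every path, with
scipy's scaling-and-squaring as a fallback if the spectral reconstruction
ever fails its own contract.

The gradient of the log-likelihood is analytic in *all* parameters: branch
lengths via the standard inner/outer partial-vector identity, kappa and the
omegas via the Daleckii–Krein (Frechet) derivative of the matrix
exponential in the eigenbasis.  One gradient costs about five likelihood
evaluations regardless of the number of parameters, which is what makes the
replicate counts below cheap.  Gradients are verified against central
finite differences in the test suite.

Fits maximise jointly over kappa, the free omegas, and all branch lengths
with L-BFGS-B on log-transformed parameters; bounds omega in [1e-4, 10],
kappa in [0.01, 100], branch lengths in [1e-6, 50]; relative lnL tolerance
1e-7.  `n_starts` counts total optimizer starts (default 2: the default
start plus one jittered restart, jitter seeded from `FitOptions.seed`, so
fits are deterministic).  In the cascade every alternative is warm-started
from its null's optimum; since L-BFGS-B is monotone this guarantees
`lnL_alt >= lnL_null` and hence a non-negative LRT up to roundoff (small
negatives are clamped at 1e-6; anything worse triggers a refit and then an
explicit optimiser-failure error).  Branch lengths on input trees are
ignored for fitting (always re-estimated); they matter only for simulation.
The two branches meeting at the root are individually weakly identified
under reversibility (only their sum matters); both are class `0`, so no
omega inference is affected.

## Tree construction

Per-orthogroup gene trees are built from the species topology, never
inferred de novo: the post-WGD species subtree is duplicated into clades A
and B below the WGD node, leaves are renamed to sequence names
(`species|copyTag|geneID`), species without a sequence are pruned
clade-locally (degree-2 nodes collapsed with lengths summed; a collapse
that would merge two differently classed branches is an error surfaced to
the caller), and classes are assigned from the WGD node.  When copies are
untagged, clade A is the child whose lexicographically smallest leaf name
sorts first, a deterministic tie-break.  Orthogroups with pre-WGD paralogy
inside non-WGD species are rejected with a diagnostic.  Newick text is
parsed through dendropy; branch classes are not serialised, so trees read
back from Newick are relabeled from the copy tags in their leaf names.

## Filters and back-translation

The primary filter keeps orthogroups with >= 13 sequences, >= 3 non-WGD
sequences, and both A and B copies in the focal species when one is set.
The alternative-dataset filter requires >= 6 sequences and caps the
per-sequence fraction of undetermined (non-ACGT) nucleotides at 0.05 — the
cap is configurable because no canonical value exists.  Stop trimming
removes exactly one terminal stop; internal stops are errors.
Back-translation expands each aligned amino-acid column to its source
codon (protein gap -> missing codon) and verifies the CDS translation
residue-for-residue, naming the sequence and 1-based position on mismatch.

## Synthetic data

The generator emulates the study design, not any particular dataset:
caterpillar outgroup backbones (the shape of the yeast species phylogeny)
with a duplicated post-WGD subtree, branch lengths i.i.d. exponential with
mean 0.15 substitutions/codon (immediate post-WGD branches drawn from the
same law), kappa = 2, and default cohort sizes of 5 post-WGD species x 2
copies + 3 outgroups = 13 sequences — the minimum passing the default
filter.  Scenario omegas sit inside realistic yeast ranges (non-WGD rates
below 0.2, post-WGD around 0.1–0.5): constant (all 0.1), symmetric shift
(0.05 -> 0.3), acceleration-then-deceleration (0.05, burst 0.4, settle
0.15), asymmetric deceleration (0.1, burst 0.4/0.4, settle 0.1 vs 0.5),
asymmetric acceleration (burst 0.15 vs 0.6).  Sequences evolve by exact
per-branch transition sampling from the root equilibrium draw —
distributionally equivalent at the leaves to event-level (Gillespie)
simulation and much faster; stop codons cannot occur because they are not
states.  Equilibrium frequencies default to equal in simulation.  All
generators are pure functions of (spec, seed).

Property tables emulate the confound structure of real yeast annotation:
functional category probabilities depend on whether the scenario changes
rate (regulators enriched, ribosomal proteins depleted among rate-changers)
and properties depend on category — abundance log-normal around
category-specific medians (regulatory 30, enzyme 200, ribosomal 1000,
other 100 ppm; sigma_log 1), disorder negative-binomial, fitness one minus
an exponential cost, CAI a noisy decreasing function of the true clade
omega.  A `coupling` knob adds a direct verdict -> abundance effect;
coupling 0 (default) makes properties independent of the verdict given
category.  What passing tests show is therefore that the *statistics* layer
reproduces the qualitative signature (significant overall difference,
non-significant within categories); real data differ in ways the generator
does not emulate — alignment error, gene conversion between paralogs, gene
loss, non-stationary codon usage, and correlated properties.

## Problem sizes and numerical checks

The validation suite runs: 100 random small instances of pruning vs
exhaustive ancestral-state enumeration (tolerance 1e-8, with transition
matrices shared so the check isolates the summation; the matrices
themselves are verified against a hand-built generator at 1e-12 and a
truncated Taylor series at 1e-8); 1000 random rate-matrix invariant draws;
200 constant-rate replicates (8 taxa, 300 codons, omega = 0.1) for R1
type-I calibration at alpha = 0.05; 20 replicates for omega recovery under
a 0.05 -> 0.3 shift plus a neutral 2000-codon recovery; and 30 + 30
replicates (300–500 codons, 13 sequences) for the R3/R4 asymmetry
discrimination pattern.  The whole suite completes in a few minutes on one
CPU; `scripts/acceptance.py` re-runs a scaled version of the same analyses
(60 type-I replicates, 30 shift replicates, 15 + 15 asymmetry replicates)
chosen to keep a fresh end-to-end run short while leaving the measured
rates stable.

## Known limitations

One omega per branch class and per gene: no site heterogeneity, no
positive-selection site tests, no empirical codon models, no among-site
rate variation, no bootstrap intervals on omega (LRTs and point estimates
only).  Gene conversion, hybridization, gene loss, and alignment error are
out of scope of the inference machinery and of the generator.  The
undetermined-nucleotide threshold and the CAI reference weights are inputs,
not estimates.
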