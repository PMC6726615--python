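# Methods

This note documents the models and algorithms implemented in `distfold`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about behaviour on real
predictions.

## Distance representation

Distances between Cβ atoms (Cα for glycine) are binned into 20 channels:
[3.5, 4.5) Å, 0.5-Å bins to 8 Å, 1-Å bins to 19 Å, and an unbounded final
bin for ≥ 19 Å. Intervals are half-open below; distances under 3.5 Å are
clamped into the first bin (the representation places no mass below
3.5 Å). The final bin's nominal "center" of 20 Å is bookkeeping only: pairs
whose maximum-likelihood bin is the final bin are excluded from
distance-error statistics (cutoff 15 Å on the max-likelihood bin center)
and never produce bounds.

Raw directional predictor scores are symmetrized per pair by
softmax(*O* + *O*ᵀ) over the 20 channels — read as pre-softmax scores, so
symmetrization both enforces the symmetry of the distance matrix and
ensembles the two triangle predictions. Contact probability is the summed
mass in bins wholly below the cutoff (8 Å default, must be a bin edge);
contact ranking excludes |i−j| < 5 and breaks ties lexicographically so
results are reproducible.

## Restraint derivation

*Distance bounds* grow accretively from the maximum-likelihood bin,
absorbing whichever adjacent bin is more likely until the cumulative
likelihood reaches the threshold (0.4 default). Ties extend toward shorter
distances (determinism; compactness-conservative). The unbounded bin never
participates: pairs whose max bin is the final bin emit nothing, and if
the threshold cannot be met from bounded bins alone no bound is emitted,
so every emitted bound has cumulative likelihood ≥ threshold and upper
edge ≤ 19 Å (19.0 is attained exactly when the interval reaches the
[18, 19) bin). Pairs with |i−j| < 2 are skipped (covered by bonded
geometry).

Each bound also carries a confidence weight
(cum − span/20) / (1 − span/20): its excess cumulative likelihood over an
uninformative uniform prediction of the same bin span. An exactly uniform
distribution — which accretes the first eight bins to a cumulative of
exactly 0.40 — gets weight 0. The weight scales the bound's energy in the
builder and gates its participation in the embedding (≥ 0.2); it does not
affect which bounds exist or how satisfaction is counted.

*H-bond restraints* are emitted per asymmetric donor(N-row) →
acceptor(O-column) cell ≥ 0.85, with a flat-bottom N–O well of
2.7–3.2 Å. The well geometry is a package choice: published protocols fix
H···O and N···O targets from high-resolution crystal survey values without
printing them, and at backbone resolution a single N–O well captures the
constraint without explicit hydrogens. Satisfaction counting uses the
N–O ≤ 3.5 Å criterion that also defines H-bond ground truth.

*Torsion restraints* cover φ and ψ only (ω predictions are not used as
constraints); deviations come from the predictor's per-angle error
estimates, floored at 5° so a zero error estimate cannot produce a rigid
constraint.

The pipeline applies one cross-channel filter before building: an H-bond
restraint whose pair has contact probability < 0.5 in the current
distogram is dropped, and only the highest-likelihood acceptor per donor
is kept (an amide donates one H-bond). A genuine backbone H-bond implies
spatial proximity, so this only removes restraints the distance channel
contradicts; without it, a handful of confidently wrong map cells can
dominate the quadratic potential and collapse the build.

## Model building

Building replaces a general-purpose restrained-dynamics engine with a
transparent three-stage procedure whose functional form is this package's
own:

1. **Bound completion.** Sparse bounds become full L×L lower/upper
   matrices: a sequential ladder (Cα 3.8 ± 0.2 Å chained; the embedding of
   the Cβ network uses a looser 3.8–6.9 Å step), triangle-inequality
   tightening of uppers (Floyd–Warshall), and a 3.5-Å hard-sphere floor on
   non-bonded lowers. Contradictions (smoothed upper below a stated lower)
   are relaxed with a warning rather than failing the build.
2. **Embedding.** A distance matrix sampled uniformly within the smoothed
   bounds is embedded by classical metric-matrix scaling (top three
   eigen-axes). The embedding is reflection-blind, so each run yields a
   mirror pair. The embedded reference-atom trace is then pulled into the
   bound network by an annealed minimization over a two-point (Cβ + Cα)
   model — restraints act on the atoms they actually constrain, which
   avoids the ±1–3 Å Cβ/Cα frustration a Cα-only trace would suffer. The
   first phase omits the hard-sphere floor so the chain may pass through
   itself while the topology sorts out. Because every trace term depends
   only on pairwise distances, the mirror of an optimized trace is equally
   optimal: the hand whose Cα 4-mer torsions look right-handed in compact
   windows is kept (or both behaviours are available via the mirror mode).
3. **Refinement.** A full backbone (N, Cα, C, O, Cβ) is placed around the
   trace with ideal bond geometry and annealed against the total energy:
   soft square wells for distance bounds and H-bonds (quadratic to a 1-Å
   violation, linear beyond — bounded tails keep wrong bounds from
   dominating), circular flat-bottom wells for torsions, stiff harmonic
   bonded terms (bond angles encoded as 1–3 distances so all bonded terms
   stay pairwise), a chirality term (side-chain improper volume pushed
   toward the L-configuration plus a left-handed-helix penalty on compact
   Cα windows), and a soft-clash floor at 2.2 Å. Restraint wells are
   narrowed by a 0.05-Å margin so converged models sit strictly inside the
   stated bounds. Annealing is geometric cooling (12 stages, 1.0 → 0.01)
   with temperature-scaled coordinate noise injected between stages and
   line-searched L-BFGS descent within them, so energy is non-increasing
   across checkpoints inside a stage; a noise-free basin-hopping polish
   finishes each model. All gradients are analytic (torsion gradients in
   the Blondel–Karplus form, verified against finite differences in the
   test suite). Runs are deterministic per seed.

A model whose final energy exceeds 100 plus 5 per restraint is flagged
unconverged rather than rejected: under heavy restraint frustration a
large converged energy is expected and informative.

## Ensembles, selection, iteration

An ensemble is a set of independent embed+build runs sorted by total
energy (default size 20; the iteration experiments below use 3 to keep
desk-scale runs short). Clustering is greedy leader clustering on pairwise
TM-score (threshold 0.6; the metric and threshold are package choices made
for scale independence). The representative of the largest cluster is the
member with the lowest internal quality score — restraint-violation energy
plus clash count, this package's stand-in for external statistical
potentials — with deterministic tie-breaks.

The pipeline runs the predictor unseeded in iteration 1, derives dihedral
restraints once and reuses them unchanged, and in later iterations passes
the previous representative to the predictor (whose Cβ distance matrix
conditions the next prediction) and re-derives distance and H-bond
restraints. Three iterations are the default. On predictor failure the run
aborts carrying the partial trace.

## TM-score

TM-score is computed on Cα atoms with the standard distance scale
d0 = 1.24·(L−15)^⅓ − 1.8 (floored at 0.5), normalized by the reference
length, with the fixed 1:1 residue correspondence (sequence-independent
alignment is out of scope). The superposition search seeds Kabsch fits
from contiguous fragments (all ≥3-subsets for chains of ≤ 8 residues) and
iteratively regrows the aligned set from close residues; only proper
rotations are used, so mirror images score strictly below 1 on chiral
structures.

## Effective sequence counts

Neff is the greedy leader cluster count at 62% identity; Nf at 80%, with
an optional √L normalization flag (the convention attached to the Nf
variant is not settled, hence the flag). Identity counts matches over
columns where at least one row is non-gap; columns gapped in both rows are
ignored. This is a transparent re-statement of what external clustering
tools compute — their word-filter heuristics and exact denominator
conventions are not reproduced, and cluster counts can differ slightly
from theirs on gappy alignments.

## Accuracy estimation

Features per model: sequence length, Neff, and the sum and mean over pairs
of the first-iteration distogram likelihood at the bin selected by the
model's own Cβ distance (distances ≥ 19 Å select the final bin). The
network is 4 → 10 → 10 → 10-softmax with SELU hidden activations and
per-feature standardization; training is full-batch cross-entropy with
Adam at a maximum learning rate 10⁻³ against the TM-score discretized into
ten ranges (the top class closed above). Training repeats over random
70/15/15 splits (100 by default); the returned network is the
best-validation one and the summary reports mean test precision/recall of
the fold call (expected TM > 0.5 vs observed TM > 0.5). The expected
TM-score is the probability-weighted mean of the range midpoints
0.05 … 0.95. Desk-scale labels come from the synthetic pipeline where
truth is known; no claim is made about reproducing accuracy-estimator
statistics obtained on large curated model sets.

## The synthetic oracle

The oracle replaces the trained predictors. Toy natives are ideal-geometry
backbones built from secondary-structure strings (helix −57°/−47°, strand
−120°/120°, coil sampled from a broad allowed region) with coil torsions
rejection-sampled until the chain is self-avoiding (non-local reference
atoms ≥ 3.6 Å) — without this a random-coil "native" can clash with
itself and violate its own binned distances.

Distogram noise: per-pair bin mass is the Gaussian integral over each bin
around the true distance (σ = `distance_sigma`; the final bin receives the
≥ 19 Å tail), a seeded `corruption_rate` fraction of pairs is replaced by
exactly uniform distributions, and when a seed model is supplied, σ shrinks
by (1 − `seed_coupling`) for pairs whose seed distance is within 2 Å of
the truth — so iteration genuinely adds information only where the
previous model was right. Bin-integral masses (rather than density at bin
centers) make the zero-noise limit exact: all mass lands in the true bin.
H-bond truth assigns each donor at most one acceptor — the nearest O
within 3.5 Å (an idealized rigid helix also has N–O pairs at offsets 2–3
marginally under the cutoff; the geometric detector reports those, the
oracle's truth map does not). Torsions get wrapped Gaussian noise with the
σ echoed back as the error estimate.

The moderate-noise study condition used in the iteration experiment is
σ = 1.2 Å, corruption 0.1, torsion σ = 0.3 rad, seed coupling 0.6: the
predictor is informative but imperfect and roughly half the emitted bounds
are single-bin-accurate.

**What the oracle does not emulate.** Errors are independent across pairs;
real predictor errors are strongly correlated (and, unlike exact-uniform
corruption, real uninformative outputs are diffuse rather than flat, and
tend to favour the unbounded bin). Consequently the desk-scale tests
establish the machinery — thresholds honoured, closure at zero noise,
improvement under seed feedback, mirror discrimination — not performance
on real predictions. Problem sizes (toys of 24–60 residues, ensembles of
3–10, 20 targets in the iteration experiment) are chosen so the full suite
runs in minutes on one core.

## Numerical notes and limitations

- Flat-bottom satisfaction is counted with a 10⁻⁹ tolerance; the builder's
  0.05-Å well margin exists so optimizer output does not sit exactly on a
  bound edge.
- The embedding can fail (rank < 3) on degenerate sampled matrices; it
  retries with fresh samples before reporting.
- `smooth_bounds` relaxes contradictory lower bounds with a warning; under
  heavy corruption many such contradictions are expected and benign.
- Fold topologies buildable from toy secondary-structure strings are
  helix-dominated; strand pairing is not restrained (no explicit
  beta-sheet H-bond topology in the toy generator), so sheet-rich folds
  are under-represented in the test bed.
- Multi-domain targets, sequence-independent structural alignment, and
  all-atom refinement are out of scope.
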