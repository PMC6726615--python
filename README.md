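# distfold

Protein model generation from predicted inter-residue distance
distributions. `distfold` implements the model-building half of a
distance-based structure-prediction pipeline: it converts per-residue-pair
probability distributions over binned Cβ–Cβ distances (*distograms*),
hydrogen-bond donor/acceptor likelihood maps, and backbone torsion
predictions into NOE-like restraints, builds backbone models by distance
geometry and restrained simulated annealing, iterates prediction and
building with seed-model feedback, and estimates the accuracy of the
result. The deep-learning predictor itself is a pluggable interface; a
synthetic oracle emulates its outputs from toy reference structures with
controllable noise, so every stage runs and is testable offline.

It is aimed at method developers who want a transparent, dependency-light
reference for the restraint-generation and model-building machinery that
sits between a distance predictor and a folded model.

## The method

**Distograms.** For residues *i, j* the predictor emits a likelihood vector
over 20 distance bins: [3.5, 4.5) Å, seven 0.5-Å bins to 8 Å, eleven 1-Å
bins to 19 Å, and an unbounded final bin. Raw directional scores *O* are
symmetrized per pair as softmax(*O* + *O*ᵀ). Contact probabilities are the
mass in bins below 8 Å.

**Restraints.** A distance bound for a pair starts at its
maximum-likelihood bin and grows accretively — always absorbing the more
likely neighbouring bin, never the unbounded bin — until the cumulative
likelihood reaches 0.4; the enclosing bin edges become a flat-bottom
[lower, upper] restraint between Cβ atoms (Cα for glycine), so less
confident predictions yield wider bounds and every upper bound stays
≤ 19 Å. H-bond restraints are emitted for asymmetric donor(N)→acceptor(O)
map cells ≥ 0.85. φ/ψ predictions become dihedral restraints whose
deviations come from the predictor's own error estimates; ω is not used.

**Building.** Bounds are completed by triangle-inequality smoothing,
embedded by classical metric-matrix scaling, pulled into the bound network
at trace resolution, dressed with an ideal-geometry backbone, and annealed
against a soft-square-well restraint potential with bonded-geometry,
chirality and clash terms. Both mirror images are considered per ensemble
member (distance information cannot distinguish them); the hand with the
better right-handed-helix signature is kept. Ensembles are clustered by
TM-score, a representative of the largest cluster is selected by an
internal quality score, and its Cβ distance matrix seeds the next
prediction round; three iterations are the default.

**Accuracy estimation.** A 4-feature network (length, effective sequence
count Neff, and the sum and mean of first-iteration distogram likelihoods
at the bins the model's own distances select) with two 10-unit SELU hidden
layers and a 10-way softmax over TM-score ranges yields an expected
TM-score (midpoint average); expected TM > 0.5 calls the fold correct.
Neff is the greedy cluster count at 62% sequence identity (80% for the Nf
variant).

## Worked example

```python
from distfold import (OracleConfig, OraclePredictor, PipelineConfig,
                      make_toy_fold, random_fold_spec, run_pipeline)

native = make_toy_fold(random_fold_spec(36, rng_seed=103), 103)
predictor = OraclePredictor(native, OracleConfig(
    distance_sigma=1.2, corruption_rate=0.1, torsion_sigma=0.3,
    seed_coupling=0.6, rng_seed=3))
cfg = PipelineConfig(iterations=3, ensemble_size=3, rng_seed=3)
rep, trace = run_pipeline(native.sequence, predictor, cfg, reference=native)
for e in trace.entries:
    print(f"iteration {e.iteration}: {e.restraint_counts['bounds']} bounds, "
          f"TM to native {e.tm_to_reference:.2f}")
```

prints (seeds fixed, so exactly reproducible):

```
iteration 1: 319 bounds, TM to native 0.43
iteration 2: 323 bounds, TM to native 0.82
iteration 3: 338 bounds, TM to native 0.67
```

Iteration 1 builds from unseeded predictions (noise σ = 1.2 Å, 10% of pairs
uninformative) and lands near the fold-recognition border; feeding the
representative's Cβ distance matrix back into the predictor sharpens the
distributions where the model was right, and later iterations recover the
fold (TM > 0.5 — by convention the same fold as the target). The bound
count changes between iterations because each round re-derives restraints
from its own predictions.

The same pipeline is available from a shell:

```sh
distfold synth --length 36 --seed 103 --distance-sigma 1.2 --out target/
distfold run --inputs target/ --out models/
```

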