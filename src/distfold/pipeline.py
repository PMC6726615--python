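"""Ensemble clustering, representative selection, and the iterative
predict -> build -> reseed loop.

Each iteration converts predictor outputs into restraints, builds an
ensemble, clusters it by structural similarity (greedy leader clustering on
pairwise TM-score), and selects a representative from the largest cluster by
an internal quality score. From the second iteration on, the predictor is
conditioned on the previous representative's CB distance matrix, so better
models sharpen the next round's predictions. Dihedral restraints are
computed once in the first iteration and reused throughout. Three iterations
are the default.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .builder import BuilderConfig, Ensemble, build_ensemble, energy_breakdown
from .distogram import distogram_to_contacts
from .restraints import (RestraintSet, distogram_to_bounds,
                         hbond_map_to_restraints, torsions_to_restraints)
from .structio import Model, cb_distance_matrix, tm_score, write_pdb

logger = logging.getLogger("distfold")

__all__ = [
    "PipelineConfig", "IterationTrace", "PipelineError", "cluster_ensemble",
    "select_representative", "quality_score", "run_pipeline",
    "cb_distance_matrix",
]


@dataclass
class PipelineConfig:
    iterations: int = 3
    ensemble_size: int = 20
    cluster_threshold: float = 0.6   # TM-score to the cluster leader
    builder: BuilderConfig = field(default_factory=BuilderConfig)
    rng_seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iteration count must be >= 1")


@dataclass
class IterationEntry:
    iteration: int
    seed_model: Model | None
    restraint_counts: dict
    ensemble_energies: list
    representative: Model
    tm_to_reference: float | None = None


@dataclass
class IterationTrace:
    entries: list = field(default_factory=list)
    final_ensemble: Ensemble | None = None

    def __len__(self):
        return len(self.entries)

    def to_json(self) -> str:
        rows = []
        for e in self.entries:
            rows.append({
                "iteration": e.iteration,
                "restraint_counts": e.restraint_counts,
                "ensemble_energies": [round(x, 4) for x in e.ensemble_energies],
                "representative_energy": e.representative.energy,
                "tm_to_reference": e.tm_to_reference,
            })
        return json.dumps(rows, indent=1)


class PipelineError(RuntimeError):
    """Raised when the predictor fails mid-run; carries the partial trace."""

    def __init__(self, message: str, trace: IterationTrace):
        super().__init__(message)
        self.trace = trace


def cluster_ensemble(e: Ensemble, threshold: float = 0.6) -> list[list[int]]:
    """Greedy leader clustering of an ensemble on pairwise TM-score.

    Models are visited in ensemble (energy) order; each joins the first
    cluster whose leader it matches with TM >= threshold, else founds a new
    cluster. Clusters are returned as index lists, ordered by size
    (descending) then leader energy (ascending)."""
    if len(e) == 0:
        raise ValueError("ensemble is empty")
    clusters: list[list[int]] = []
    for idx, m in enumerate(e.models):
        for cl in clusters:
            if tm_score(m, e.models[cl[0]]) >= threshold:
                cl.append(idx)
                break
        else:
            clusters.append([idx])
    clusters.sort(key=lambda cl: (-len(cl), e.models[cl[0]].energy["total"]))
    return clusters


def quality_score(m: Model, restraints: RestraintSet,
                  cfg: BuilderConfig | None = None) -> float:
    """Internal single-model quality score: restraint-violation energy plus
    the soft-clash energy (lower is better). This is the package's stand-in
    for external statistical potentials when ranking within a cluster."""
    terms = m.energy if m.energy is not None else \
        energy_breakdown(m, restraints, cfg)
    violation = terms["distance"] + terms["hbond"] + terms["torsion"]
    clash_pairs = terms["clash"]
    return violation + clash_pairs


def select_representative(e: Ensemble, clusters: list[list[int]],
                          restraints: RestraintSet | None = None) -> Model:
    """Representative of the largest cluster: the member with the lowest
    internal quality score; ties break by total energy, then ensemble
    index."""
    top = clusters[0]
    rset = restraints if restraints is not None else RestraintSet()

    def key(idx):
        m = e.models[idx]
        return (quality_score(m, rset, e.config), m.energy["total"], idx)

    return e.models[min(top, key=key)]


def filter_hbonds(hbonds: list, distogram, min_contact_prob: float = 0.5,
                  unique_donor: bool = True) -> list:
    """Cross-channel consistency filter for H-bond restraints.

    A genuine backbone H-bond implies spatial proximity, so restraints whose
    residue pair has a contact probability (distogram mass below 8 A) under
    ``min_contact_prob`` are dropped; optionally only the highest-likelihood
    acceptor per donor survives (an amide N donates a single H-bond). This
    keeps spurious high-likelihood map cells from distorting the build."""
    cmap = distogram_to_contacts(distogram)
    kept = [h for h in hbonds
            if cmap.probabilities[h.donor_res - 1, h.acceptor_res - 1]
            >= min_contact_prob]
    if unique_donor:
        by_donor = {}
        for h in kept:
            cur = by_donor.get(h.donor_res)
            if cur is None or h.likelihood > cur.likelihood:
                by_donor[h.donor_res] = h
        kept = sorted(by_donor.values(),
                      key=lambda h: (h.donor_res, h.acceptor_res))
    return kept


def run_pipeline(sequence: str, predictor, cfg: PipelineConfig,
                 reference: Model | None = None
                 ) -> tuple[Model, IterationTrace]:
    """Run the iterative modelling loop.

    ``predictor`` must expose ``predict(seed_model=None, iteration=0)``
    returning an object with ``distogram`` (symmetric), ``hbond_map``
    (L x L) and ``torsions`` (angle-name -> (values, errors)) attributes —
    the synthetic oracle predictor satisfies this. Iteration 1 runs the
    predictor unseeded; later iterations pass the previous representative as
    the seed model and regenerate distance and H-bond restraints, while the
    first iteration's dihedral restraints are reused unchanged. When
    ``reference`` is given, each entry records the representative's TM-score
    against it. Returns the final representative and the full trace; the
    final ensemble rides on the trace.
    """
    trace = IterationTrace()
    seed_seq = np.random.SeedSequence(cfg.rng_seed)
    iter_seeds = seed_seq.spawn(cfg.iterations)
    torsion_restraints = None
    representative = None
    ensemble = None

    for it in range(cfg.iterations):
        try:
            out = predictor.predict(seed_model=representative, iteration=it)
        except Exception as exc:  # predictor failure -> partial trace
            raise PipelineError(
                f"predictor failed at iteration {it + 1}: {exc}", trace
            ) from exc
        bounds = distogram_to_bounds(out.distogram, sequence)
        hbonds = filter_hbonds(hbond_map_to_restraints(out.hbond_map),
                               out.distogram)
        if torsion_restraints is None:
            torsion_restraints = torsions_to_restraints(out.torsions)
        rset = RestraintSet(
            bounds=bounds, hbonds=hbonds, torsions=torsion_restraints,
            provenance={"iteration": it + 1},
        )
        bcfg = BuilderConfig(**{
            **cfg.builder.__dict__,
            "ensemble_size": cfg.ensemble_size,
            "rng_seed": int(iter_seeds[it].generate_state(1)[0] % (2 ** 31)),
        })
        ensemble = build_ensemble(rset, bcfg, sequence)
        clusters = cluster_ensemble(ensemble, cfg.cluster_threshold)
        representative = select_representative(ensemble, clusters, rset)
        entry = IterationEntry(
            iteration=it + 1,
            seed_model=trace.entries[-1].representative if trace.entries else None,
            restraint_counts={"bounds": len(bounds), "hbonds": len(hbonds),
                              "torsions": len(torsion_restraints)},
            ensemble_energies=[m.energy["total"] for m in ensemble.models],
            representative=representative,
            tm_to_reference=(tm_score(representative, reference)
                             if reference is not None else None),
        )
        trace.entries.append(entry)
        logger.info("iteration %d: %d bounds, %d hbonds, best energy %.2f",
                    it + 1, len(bounds), len(hbonds),
                    ensemble.models[0].energy["total"])

    trace.final_ensemble = ensemble
    return representative, trace


def write_pipeline_outputs(out_dir, representative: Model,
                           trace: IterationTrace) -> None:
    """Write final/per-iteration PDBs and the trace JSON under ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "final.pdb").write_text(write_pdb(representative))
    for e in trace.entries:
        (out / f"iteration_{e.iteration}.pdb").write_text(
            write_pdb(e.representative))
    (out / "trace.json").write_text(trace.to_json())
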