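"""Synthetic targets and a noise-controllable predictor oracle.

The oracle stands in for the trained distance / H-bond / torsion predictors:
given a reference ("native") structure it emits the same output contracts —
a symmetric L x L x 20 distogram, an asymmetric L x L H-bond donor/acceptor
likelihood map, and per-residue phi/psi/omega predictions with error
estimates — with controllable noise, so the whole restraint-derivation,
model-building and iteration machinery can be exercised offline.

Noise model: per-pair bin mass is the Gaussian integral over each distance
bin around the true CB-CB distance (sigma = ``distance_sigma``); a seeded
``corruption_rate`` fraction of pairs is replaced by uninformative uniform
distributions. When a seed model from a previous iteration is supplied, the
effective sigma shrinks by (1 - ``seed_coupling``) for pairs whose seed
distance lies within 2 A of the truth, so iteration can genuinely add
information (the oracle's analogue of feeding the seed's CB distance matrix
back into the predictor).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .distogram import BinScheme, Distogram, default_bin_scheme
from .structio import (Model, backbone_from_torsions, cb_distance_matrix,
                       dihedral, phi_psi)

# Ideal backbone torsions per secondary-structure state (radians)
HELIX_PHI, HELIX_PSI = math.radians(-57.0), math.radians(-47.0)
STRAND_PHI, STRAND_PSI = math.radians(-120.0), math.radians(120.0)

SEED_AGREEMENT_TOL = 2.0  # A: seed distance within this of truth sharpens


@dataclass
class OracleConfig:
    distance_sigma: float = 1.0        # A
    corruption_rate: float = 0.0       # fraction of pairs made uninformative
    hbond_true_likelihood: float = 0.95
    hbond_false_likelihood: float = 0.02
    torsion_sigma: float = 0.1         # radians
    seed_coupling: float = 0.5         # in [0, 1]
    rng_seed: int = 0

    def __post_init__(self):
        if self.distance_sigma <= 0:
            raise ValueError("distance_sigma must be positive")
        for name in ("corruption_rate", "hbond_true_likelihood",
                     "hbond_false_likelihood", "seed_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class ToyFoldSpec:
    ss: str                      # per-residue H/E/C
    sequence: str | None = None  # defaults to poly-Ala
    perturbation_rmsd: float = 0.0

    def __post_init__(self):
        if self.sequence is None:
            self.sequence = "A" * len(self.ss)
        if len(self.sequence) != len(self.ss):
            raise ValueError("sequence and secondary structure lengths differ")


MIN_CB_SEPARATION = 3.6   # self-avoidance: reference-atom floor, A
MIN_ATOM_SEPARATION = 2.4


def _self_avoidance(m: Model) -> float:
    """Smallest non-local (|i-j| >= 2) reference-atom distance, with the
    all-atom floor folded in (scaled so one shared acceptance threshold
    applies)."""
    cb = m.cb_or_ca()
    L = len(m)
    iu, ju = np.triu_indices(L, k=2)
    dcb = np.linalg.norm(cb[iu] - cb[ju], axis=1).min()
    atoms = np.concatenate([m.n, m.ca, m.c, m.o], axis=0)
    res = np.tile(np.arange(L), 4)
    d = np.linalg.norm(atoms[:, None, :] - atoms[None, :, :], axis=2)
    far = np.abs(res[:, None] - res[None, :]) >= 2
    datom = d[far].min()
    return min(dcb, datom * (MIN_CB_SEPARATION / MIN_ATOM_SEPARATION))


def make_toy_fold(spec: ToyFoldSpec, rng_seed: int = 0,
                  max_tries: int = 60) -> Model:
    """Ideal-geometry backbone from a secondary-structure string.

    Helix residues use (-57, -47) degrees, strand residues (-120, 120), coil
    residues seeded samples from a broad allowed region. Coil torsions are
    rejection-sampled until the chain is self-avoiding (no non-local
    reference atoms closer than 3.6 A), so a toy native always satisfies the
    binned distance range. An optional global coordinate perturbation brings
    the model to roughly the requested RMSD from the ideal build.
    Deterministic for a fixed seed.
    """
    if len(spec.ss) < 10:
        raise ValueError("toy folds need at least 10 residues")
    bad = set(spec.ss) - set("HEC")
    if bad:
        raise ValueError(f"unknown secondary-structure state(s): {sorted(bad)}")
    rng = np.random.default_rng(rng_seed)
    L = len(spec.ss)
    has_coil = "C" in spec.ss
    best = None
    best_sep = -np.inf
    for _ in range(max_tries):
        phi = np.empty(L)
        psi = np.empty(L)
        for i, s in enumerate(spec.ss):
            if s == "H":
                phi[i], psi[i] = HELIX_PHI, HELIX_PSI
            elif s == "E":
                phi[i], psi[i] = STRAND_PHI, STRAND_PSI
            else:
                phi[i] = rng.uniform(math.radians(-150.0), math.radians(-60.0))
                psi[i] = rng.uniform(math.radians(-60.0), math.radians(160.0))
        cand = backbone_from_torsions(spec.sequence, phi, psi)
        sep = _self_avoidance(cand)
        if sep > best_sep:
            best, best_sep = cand, sep
        if sep >= MIN_CB_SEPARATION or not has_coil:
            break
    m = best
    if spec.perturbation_rmsd > 0:
        sigma = spec.perturbation_rmsd / math.sqrt(3.0)
        for arr in (m.n, m.ca, m.c, m.o):
            arr += rng.normal(0.0, sigma, arr.shape)
        m.cb += rng.normal(0.0, sigma, m.cb.shape)
    return m


def random_fold_spec(length: int, rng_seed: int = 0,
                     states: str = "HC") -> ToyFoldSpec:
    """A seeded secondary-structure layout: alternating structured segments
    (6-14 residues) and short coils (2-5), for varied toy topologies."""
    rng = np.random.default_rng(rng_seed)
    ss = []
    structured = True
    while len(ss) < length:
        if structured:
            s = states[rng.integers(0, len(states))] if len(states) > 1 else states
            ss.extend(s * int(rng.integers(6, 15)))
        else:
            ss.extend("C" * int(rng.integers(2, 6)))
        structured = not structured
    return ToyFoldSpec(ss="".join(ss[:length]))


# ---------------------------------------------------------------------------
# Oracle predictors
# ---------------------------------------------------------------------------

def oracle_distogram(native: Model, cfg: OracleConfig,
                     seed_model: Model | None = None,
                     scheme: BinScheme | None = None,
                     rng_seed: int | None = None) -> Distogram:
    """Noisy distogram around the native CB-CB distances (see module
    docstring for the noise model). Symmetric and normalized; bitwise
    deterministic for fixed inputs and seed."""
    scheme = scheme or default_bin_scheme()
    if seed_model is not None and len(seed_model) != len(native):
        raise ValueError("seed model length does not match native")
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    L = len(native)
    dtrue = cb_distance_matrix(native)

    sigma = np.full((L, L), cfg.distance_sigma)
    if seed_model is not None:
        dseed = cb_distance_matrix(seed_model)
        good = np.abs(dseed - dtrue) <= SEED_AGREEMENT_TOL
        sigma[good] *= max(1.0 - cfg.seed_coupling, 1e-3)

    edges = scheme.edges.copy()
    edges[0] = -np.inf  # short distances clamp into the first bin
    # mass per bin: Gaussian integral between consecutive edges
    z = (edges[None, None, :] - dtrue[:, :, None]) / sigma[:, :, None]
    cdf = norm.cdf(z)
    p = np.diff(cdf, axis=2)
    # guard against fully-degenerate rows (sigma -> 0 numerics)
    row_sum = p.sum(axis=2, keepdims=True)
    flat = row_sum[:, :, 0] <= 0
    if np.any(flat):
        idx = scheme.bin_of(dtrue[flat])
        p[flat] = np.eye(scheme.n_bins)[idx]
        row_sum = p.sum(axis=2, keepdims=True)
    p = p / row_sum

    if cfg.corruption_rate > 0:
        iu, ju = np.triu_indices(L, k=1)
        hit = rng.random(len(iu)) < cfg.corruption_rate
        uniform = np.full(scheme.n_bins, 1.0 / scheme.n_bins)
        p[iu[hit], ju[hit]] = uniform
        p[ju[hit], iu[hit]] = uniform
    p[np.arange(L), np.arange(L)] = 1.0 / scheme.n_bins
    return Distogram(p, scheme)


def oracle_hbonds(native: Model, cfg: OracleConfig,
                  cutoff: float = 3.5, min_separation: int = 2,
                  rng_seed: int | None = None) -> np.ndarray:
    """Asymmetric donor(row) -> acceptor(column) likelihood map.

    Ground truth assigns each donor amide N at most one acceptor: the nearest
    carbonyl O within ``cutoff`` (an amide donates a single H-bond). True
    cells get ``hbond_true_likelihood``, the rest ``hbond_false_likelihood``;
    a seeded ``corruption_rate`` fraction of cells is flipped between the two
    levels.
    """
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    L = len(native)
    diff = native.n[:, None, :] - native.o[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    ii, jj = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    d = np.where(np.abs(ii - jj) >= min_separation, d, np.inf)
    truth = np.zeros((L, L), dtype=bool)
    nearest = d.argmin(axis=1)
    ok = d[np.arange(L), nearest] <= cutoff
    truth[np.arange(L)[ok], nearest[ok]] = True

    hmap = np.where(truth, cfg.hbond_true_likelihood, cfg.hbond_false_likelihood)
    if cfg.corruption_rate > 0:
        flip = rng.random((L, L)) < cfg.corruption_rate
        hmap = np.where(flip,
                        np.where(truth, cfg.hbond_false_likelihood,
                                 cfg.hbond_true_likelihood),
                        hmap)
    return hmap


def oracle_torsions(native: Model, cfg: OracleConfig,
                    rng_seed: int | None = None) -> dict:
    """Per-residue phi/psi/omega predictions with error estimates.

    True backbone torsions plus wrapped-Gaussian noise of ``torsion_sigma``;
    the reported per-angle error estimate equals ``torsion_sigma``. Undefined
    terminal angles stay NaN.
    """
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    L = len(native)
    phi, psi = phi_psi(native)
    omega = np.full(L, np.nan)
    if L >= 2:
        omega[1:] = dihedral(native.ca[:-1], native.c[:-1], native.n[1:],
                             native.ca[1:])
    out = {}
    for name, vals in (("phi", phi), ("psi", psi), ("omega", omega)):
        noisy = vals + rng.normal(0.0, cfg.torsion_sigma, L) \
            if cfg.torsion_sigma > 0 else vals.copy()
        noisy = np.mod(noisy + np.pi, 2.0 * np.pi) - np.pi
        noisy[noisy == -np.pi] = np.pi
        noisy[~np.isfinite(vals)] = np.nan
        errors = np.full(L, max(cfg.torsion_sigma, 1e-9))
        out[name] = (noisy, errors)
    return out


# ---------------------------------------------------------------------------
# Synthetic MSAs
# ---------------------------------------------------------------------------

_ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


def make_msa(n_seqs: int, length: int, mutation_rate: float = 0.1,
             rng_seed: int = 0):
    """Star-topology alignment: a random root sequence plus copies mutated at
    a per-site substitution rate (substitutions always change the residue, so
    copy-to-root identity has expectation 1 - mutation_rate)."""
    from .msa_stats import MSA

    if n_seqs < 1:
        raise ValueError("n_seqs must be >= 1")
    rng = np.random.default_rng(rng_seed)
    root = _ALPHABET[rng.integers(0, 20, size=length)]
    rows = [root.tobytes().decode()]
    for _ in range(n_seqs - 1):
        seq = root.copy()
        hit = rng.random(length) < mutation_rate
        for pos in np.flatnonzero(hit):
            choices = _ALPHABET[_ALPHABET != seq[pos]]
            seq[pos] = choices[rng.integers(0, len(choices))]
        rows.append(seq.tobytes().decode())
    return MSA(rows, target_index=0)


# ---------------------------------------------------------------------------
# Predictor interface backed by the oracle
# ---------------------------------------------------------------------------

@dataclass
class PredictorOutput:
    distogram: "Distogram"
    hbond_map: np.ndarray
    torsions: dict


class OraclePredictor:
    """Pluggable predictor backed by the synthetic oracle.

    Exposes the interface the pipeline expects: ``predict(seed_model=None,
    iteration=0)``. Per-iteration noise realizations are derived
    deterministically from the config seed and the iteration index.
    """

    def __init__(self, native: Model, cfg: OracleConfig):
        self.native = native
        self.cfg = cfg

    def predict(self, seed_model: Model | None = None,
                iteration: int = 0) -> PredictorOutput:
        base = np.random.SeedSequence([self.cfg.rng_seed, iteration])
        s_dist, s_hb, s_tor = [int(s.generate_state(1)[0] % (2 ** 31))
                               for s in base.spawn(3)]
        return PredictorOutput(
            distogram=oracle_distogram(self.native, self.cfg,
                                       seed_model=seed_model, rng_seed=s_dist),
            hbond_map=oracle_hbonds(self.native, self.cfg, rng_seed=s_hb),
            torsions=oracle_torsions(self.native, self.cfg, rng_seed=s_tor),
        )
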