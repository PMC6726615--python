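"""Restrained model building: bound smoothing, metric-matrix embedding, and
simulated-annealing refinement of a flat-bottom restraint potential.

The builder turns a :class:`~distfold.restraints.RestraintSet` into backbone
models in three stages:

1. ``smooth_bounds`` completes the sparse pairwise bounds into full L x L
   lower/upper matrices: a sequential CA ladder is chained along the
   backbone, upper bounds are tightened by the triangle inequality
   (all-pairs shortest path), and lower bounds are floored at a hard-sphere
   distance for non-bonded pairs.
2. ``embed_initial`` samples a distance matrix uniformly within the smoothed
   bounds and embeds it by classical metric-matrix scaling (top three
   eigen-axes); both mirror images are available since the embedding is
   reflection-blind.
3. ``refine`` places a full ideal-geometry backbone on the CA trace and
   anneals it against the total energy: flat-bottom quadratic distance and
   H-bond wells, circular torsion wells, stiff harmonic bonded-geometry
   terms (bond angles encoded as 1-3 distances so all bonded terms stay
   pairwise), a chirality term (side-chain improper volume plus a
   right-handedness penalty on compact CA 4-mers), and a soft-clash
   repulsion. Each annealing stage injects temperature-scaled coordinate
   noise and then descends by gradient steps with backtracking, so energy is
   non-increasing across the checkpoints inside a stage.

An ensemble run embeds and refines both mirror images per member (briefly),
keeps the lower-energy hand, finishes it on the full schedule, and sorts the
resulting models by total energy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import structio as sio
from .restraints import RestraintSet
from .structio import Model

logger = logging.getLogger("distfold")

CA_STEP = 3.8          # sequential CA-CA distance, A
CA_STEP_TOL = 0.2
NONBONDED_FLOOR = 3.5  # lower-bound floor for non-bonded pairs, A
CLASH_FLOOR = 2.2      # accepted-model clash criterion, A

#: Signed volume ((N-CA) x (C-CA)) . (CB-CA) of an ideal L-residue; the
#: chirality term penalizes residues whose volume rises above L_VOLUME_MAX
#: toward the D configuration.
L_VOLUME = -2.49
L_VOLUME_MAX = -1.0
HELIX_WINDOW_CUTOFF = 7.2  # CA(i)-CA(i+3) distance marking a helix-like turn


@dataclass
class BuilderConfig:
    t_start: float = 1.0
    t_end: float = 0.01
    n_stages: int = 12
    steps_per_stage: int = 40       # max minimizer iterations per stage
    noise_scale: float = 0.15       # A of coordinate noise per unit sqrt(T)
    weights: dict = field(default_factory=lambda: {
        "distance": 1.0, "hbond": 1.0, "torsion": 0.3,
        "geometry": 5.0, "chirality": 2.0, "clash": 2.0,
    })
    ensemble_size: int = 20
    rng_seed: int = 0
    mirror_mode: str = "both"       # both | keep | mirror
    clash_floor: float = CLASH_FLOOR
    energy_ceiling: float = 100.0   # unconverged above this plus the
    ceiling_per_restraint: float = 5.0  # ... per-restraint allowance
    polish_iterations: int = 500    # minimizer iterations per polish hop
    restraint_margin: float = 0.05  # A: wells narrowed so optima sit strictly
                                    # inside the stated bounds
    soft_switch: float = 1.0        # A: restraint violation beyond which the
                                    # quadratic well continues linearly (a
                                    # soft square well robust to wrong bounds)

    def __post_init__(self):
        if self.n_stages < 1 or self.steps_per_stage < 1:
            raise ValueError("schedule needs at least one stage and step")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


# ---------------------------------------------------------------------------
# Bound smoothing
# ---------------------------------------------------------------------------

def smooth_bounds(bounds: list, L: int, pad: float = 0.0,
                  chain_upper: float = CA_STEP + CA_STEP_TOL,
                  chain_lower: float = CA_STEP - CA_STEP_TOL,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Complete sparse pairwise bounds into full L x L (lower, upper)
    matrices (see module docstring). ``pad`` widens input bounds by that many
    Angstroms each way. The sequential ladder defaults to the CA step
    (3.8 +/- 0.2 A chained); embedding the CB reference-atom network instead
    passes the looser CB step. Contradictory bounds (smoothed upper below a
    lower) are relaxed with a warning rather than rejected.
    """
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    upper = chain_upper * sep.astype(float)
    lower = np.where(sep > 1, NONBONDED_FLOOR, 0.0)
    lower[sep == 1] = chain_lower
    np.fill_diagonal(lower, 0.0)

    for b in bounds:
        if b.lower > b.upper:
            raise ValueError("inconsistent bound: lower > upper")
        i, j = b.i - 1, b.j - 1
        lo = max(b.lower - pad, NONBONDED_FLOOR)
        hi = b.upper + pad
        upper[i, j] = upper[j, i] = min(upper[i, j], hi)
        lower[i, j] = lower[j, i] = max(lower[i, j], lo)

    # triangle-inequality tightening (Floyd-Warshall on the upper matrix)
    for k in range(L):
        via = upper[:, k, None] + upper[None, k, :]
        np.minimum(upper, via, out=upper)

    bad = upper < lower
    if np.any(bad):
        n_bad = int(bad.sum() // 2)
        logger.warning("smooth_bounds: relaxed %d contradictory lower bound(s)",
                       n_bad)
        lower[bad] = np.minimum(lower[bad], upper[bad])
    return lower, upper


# ---------------------------------------------------------------------------
# Metric-matrix embedding
# ---------------------------------------------------------------------------

def embed_distances(d: np.ndarray, mirror: bool = False) -> np.ndarray:
    """Classical multidimensional scaling of a full distance matrix onto the
    top three eigen-axes. Exact distances reproduce the generating
    coordinates up to rigid motion and reflection."""
    L = d.shape[0]
    d2 = np.asarray(d, dtype=float) ** 2
    j = np.eye(L) - np.full((L, L), 1.0 / L)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    top = np.argsort(evals)[::-1][:3]
    lam = np.clip(evals[top], 0.0, None)
    if np.count_nonzero(lam > 1e-9) < 3:
        raise np.linalg.LinAlgError("embedding rank below 3")
    x = evecs[:, top] * np.sqrt(lam)
    if mirror:
        x = x.copy()
        x[:, 2] *= -1.0
    return x


def embed_initial(lower: np.ndarray, upper: np.ndarray, rng_seed: int = 0,
                  mirror: bool = False, max_retries: int = 3) -> np.ndarray:
    """Coarse CA trace: distances sampled uniformly within the smoothed
    bounds (symmetrically), then metric-matrix embedding. A degenerate
    spectrum triggers a jittered retry before being reported."""
    rng = np.random.default_rng(rng_seed)
    L = lower.shape[0]
    iu, ju = np.triu_indices(L, k=1)
    for attempt in range(max_retries + 1):
        u = rng.random(len(iu))
        d = np.zeros((L, L))
        vals = lower[iu, ju] + u * (upper[iu, ju] - lower[iu, ju])
        d[iu, ju] = vals
        d[ju, iu] = vals
        try:
            return embed_distances(d, mirror=mirror)
        except np.linalg.LinAlgError:
            if attempt == max_retries:
                raise
            logger.warning("embed_initial: degenerate spectrum, retrying")


# ---------------------------------------------------------------------------
# Full-backbone placement on a CA trace
# ---------------------------------------------------------------------------

def backbone_on_trace(sequence: str, ca: np.ndarray) -> Model:
    """Rough full backbone around a CA trace; ideal-geometry harmonic terms
    during refinement finish the job."""
    L = len(sequence)
    nan = np.full((L, 3), np.nan)
    m = Model(sequence, nan.copy(), np.asarray(ca, dtype=float), nan.copy(),
              nan.copy(), nan.copy())
    sio._fill_missing(m)
    return m


# ---------------------------------------------------------------------------
# Energy model
# ---------------------------------------------------------------------------

class _EnergyModel:
    """Precompiled energy terms over the flat atom vector of a model."""

    def __init__(self, sequence: str, rset: RestraintSet, cfg: BuilderConfig):
        self.sequence = sequence
        self.cfg = cfg
        L = len(sequence)
        self.L = L

        # flat atom layout
        self.atom_index = {}
        names = []
        for i, aa in enumerate(sequence):
            for nm in ("N", "CA", "C", "O") + (() if aa == "G" else ("CB",)):
                self.atom_index[(i, nm)] = len(names)
                names.append((i, nm))
        self.atom_names = names
        self.n_atoms = len(names)
        self.atom_res = np.array([r for r, _ in names])

        ai = self.atom_index

        def ref_atom(i, preferred):  # CB with CA fallback for glycine
            return ai[(i, preferred)] if (i, preferred) in ai else ai[(i, "CA")]

        # --- flat-bottom restraint pairs (distance + hbond) ---
        fb_i, fb_j, fb_lo, fb_hi, fb_w, fb_cat = [], [], [], [], [], []
        wd = cfg.weights["distance"]
        for b in rset.bounds:
            fb_i.append(ref_atom(b.i - 1, b.atom_i))
            fb_j.append(ref_atom(b.j - 1, b.atom_j))
            fb_lo.append(b.lower); fb_hi.append(b.upper)
            fb_w.append(wd * getattr(b, "weight", 1.0)); fb_cat.append(0)
        wh = cfg.weights["hbond"]
        for h in rset.hbonds:
            fb_i.append(ai[(h.donor_res - 1, "N")])
            fb_j.append(ai[(h.acceptor_res - 1, "O")])
            fb_lo.append(h.target - h.halfwidth)
            fb_hi.append(h.target + h.halfwidth)
            fb_w.append(wh); fb_cat.append(1)
        self.fb_i = np.array(fb_i, dtype=int)
        self.fb_j = np.array(fb_j, dtype=int)
        self.fb_lo = np.array(fb_lo)
        self.fb_hi = np.array(fb_hi)
        margin = np.minimum(cfg.restraint_margin,
                            0.25 * (self.fb_hi - self.fb_lo))
        self.fb_lo = self.fb_lo + margin
        self.fb_hi = self.fb_hi - margin
        self.fb_w = np.array(fb_w)
        self.fb_cat = np.array(fb_cat, dtype=int)

        # --- harmonic bonded-geometry pairs (bonds + 1-3 angle distances) ---
        def d13(r1, r2, theta):
            return math.sqrt(r1 * r1 + r2 * r2 - 2 * r1 * r2 * math.cos(theta))

        hp = []
        wg = cfg.weights["geometry"]
        for i, aa in enumerate(sequence):
            hp.append((ai[(i, "N")], ai[(i, "CA")], sio.BOND_N_CA))
            hp.append((ai[(i, "CA")], ai[(i, "C")], sio.BOND_CA_C))
            hp.append((ai[(i, "C")], ai[(i, "O")], sio.BOND_C_O))
            hp.append((ai[(i, "N")], ai[(i, "C")],
                       d13(sio.BOND_N_CA, sio.BOND_CA_C, sio.ANGLE_N_CA_C)))
            hp.append((ai[(i, "CA")], ai[(i, "O")],
                       d13(sio.BOND_CA_C, sio.BOND_C_O, sio.ANGLE_CA_C_O)))
            if aa != "G":
                hp.append((ai[(i, "CA")], ai[(i, "CB")], sio.BOND_CA_CB))
                hp.append((ai[(i, "N")], ai[(i, "CB")],
                           d13(sio.BOND_N_CA, sio.BOND_CA_CB,
                               sio.ANGLE_N_CA_CB)))
            if i + 1 < L:
                hp.append((ai[(i, "C")], ai[(i + 1, "N")], sio.BOND_C_N))
                hp.append((ai[(i, "CA")], ai[(i + 1, "N")],
                           d13(sio.BOND_CA_C, sio.BOND_C_N, sio.ANGLE_CA_C_N)))
                hp.append((ai[(i, "C")], ai[(i + 1, "CA")],
                           d13(sio.BOND_C_N, sio.BOND_N_CA, sio.ANGLE_C_N_CA)))
                hp.append((ai[(i, "O")], ai[(i + 1, "N")],
                           d13(sio.BOND_C_O, sio.BOND_C_N,
                               2.0 * math.pi - sio.ANGLE_CA_C_O
                               - sio.ANGLE_CA_C_N)))
                hp.append((ai[(i, "CA")], ai[(i + 1, "CA")], CA_STEP))
        self.hp_i = np.array([a for a, _, _ in hp], dtype=int)
        self.hp_j = np.array([b for _, b, _ in hp], dtype=int)
        self.hp_d0 = np.array([d for _, _, d in hp])
        self.hp_w = np.full(len(hp), wg)

        # --- torsion restraints (phi/psi quadruples) ---
        tq, tt, td = [], [], []
        for t in rset.torsions:
            r = t.residue - 1
            if t.angle == "phi":
                if r == 0:
                    continue
                quad = (ai[(r - 1, "C")], ai[(r, "N")], ai[(r, "CA")],
                        ai[(r, "C")])
            else:
                if r == L - 1:
                    continue
                quad = (ai[(r, "N")], ai[(r, "CA")], ai[(r, "C")],
                        ai[(r + 1, "N")])
            tq.append(quad); tt.append(t.target); td.append(t.deviation)
        self.tor_quads = np.array(tq, dtype=int).reshape(-1, 4)
        self.tor_target = np.array(tt)
        self.tor_dev = np.array(td)
        self.tor_w = cfg.weights["torsion"]

        # --- chirality: CB impropers + CA 4-mer handedness windows ---
        imp = [(ai[(i, "N")], ai[(i, "CA")], ai[(i, "C")], ai[(i, "CB")])
               for i, aa in enumerate(sequence) if aa != "G"]
        self.imp_quads = np.array(imp, dtype=int).reshape(-1, 4)
        ca_idx = np.array([ai[(i, "CA")] for i in range(L)], dtype=int)
        self.ca_idx = ca_idx
        self.hand_quads = np.stack([ca_idx[:-3], ca_idx[1:-2],
                                    ca_idx[2:-1], ca_idx[3:]], axis=1) \
            if L >= 4 else np.empty((0, 4), dtype=int)
        self.chir_w = cfg.weights["chirality"]

        # --- clash exclusions: same or adjacent residues ---
        self.clash_w = cfg.weights["clash"]
        self.clash_floor = cfg.clash_floor

    # -- evaluation ---------------------------------------------------------

    def energy_grad(self, x: np.ndarray, with_grad: bool = True):
        g = np.zeros_like(x) if with_grad else None
        terms = {}

        # flat-bottom pairs
        e_dist = e_hb = 0.0
        if len(self.fb_i):
            diff = x[self.fb_i] - x[self.fb_j]
            d = np.linalg.norm(diff, axis=1)
            d = np.maximum(d, 1e-9)
            below = np.maximum(self.fb_lo - d, 0.0)
            above = np.maximum(d - self.fb_hi, 0.0)
            viol = below + above
            e_well, de_well = _soft_well(viol, self.cfg.soft_switch)
            e_pair = self.fb_w * e_well
            e_dist = float(e_pair[self.fb_cat == 0].sum())
            e_hb = float(e_pair[self.fb_cat == 1].sum())
            if with_grad:
                sign = np.sign(above - below)
                coef = self.fb_w * de_well * sign / d
                gv = coef[:, None] * diff
                np.add.at(g, self.fb_i, gv)
                np.add.at(g, self.fb_j, -gv)
        terms["distance"] = e_dist
        terms["hbond"] = e_hb

        # harmonic geometry pairs
        diff = x[self.hp_i] - x[self.hp_j]
        d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
        dev = d - self.hp_d0
        terms["geometry"] = float((self.hp_w * dev ** 2).sum())
        if with_grad:
            coef = 2.0 * self.hp_w * dev / d
            gv = coef[:, None] * diff
            np.add.at(g, self.hp_i, gv)
            np.add.at(g, self.hp_j, -gv)

        # torsion wells
        e_tor = 0.0
        if len(self.tor_quads):
            phi, grads = _dihedral_and_grad(x, self.tor_quads, with_grad)
            delta = np.mod(phi - self.tor_target + np.pi, 2 * np.pi) - np.pi
            excess = np.maximum(np.abs(delta) - self.tor_dev, 0.0)
            e_tor = float(self.tor_w * (excess ** 2).sum())
            if with_grad:
                dedphi = 2.0 * self.tor_w * excess * np.sign(delta)
                _scatter_quad_grads(g, self.tor_quads, grads, dedphi)
        terms["torsion"] = e_tor

        # chirality
        e_chir = 0.0
        if len(self.imp_quads):
            a = x[self.imp_quads[:, 0]]; ca = x[self.imp_quads[:, 1]]
            c = x[self.imp_quads[:, 2]]; cb = x[self.imp_quads[:, 3]]
            u = a - ca; v = c - ca; w = cb - ca
            s = np.einsum("ij,ij->i", np.cross(u, v), w)
            exc = np.maximum(s - L_VOLUME_MAX, 0.0)
            e_chir += float(self.chir_w * (exc ** 2).sum())
            if with_grad:
                coef = (2.0 * self.chir_w * exc)[:, None]
                gu = coef * np.cross(v, w)
                gv_ = coef * np.cross(w, u)
                gw = coef * np.cross(u, v)
                np.add.at(g, self.imp_quads[:, 0], gu)
                np.add.at(g, self.imp_quads[:, 2], gv_)
                np.add.at(g, self.imp_quads[:, 3], gw)
                np.add.at(g, self.imp_quads[:, 1], -(gu + gv_ + gw))
        if len(self.hand_quads):
            dturn = np.linalg.norm(x[self.hand_quads[:, 0]]
                                   - x[self.hand_quads[:, 3]], axis=1)
            compact = dturn < HELIX_WINDOW_CUTOFF
            if np.any(compact):
                quads = self.hand_quads[compact]
                tau, grads = _dihedral_and_grad(x, quads, with_grad)
                neg = np.maximum(-np.sin(tau), 0.0)
                e_chir += float(self.chir_w * (neg ** 2).sum())
                if with_grad:
                    dedtau = 2.0 * self.chir_w * neg * (-np.cos(tau))
                    _scatter_quad_grads(g, quads, grads, dedtau)
        terms["chirality"] = e_chir

        # soft clash
        e_clash = 0.0
        tree = cKDTree(x)
        pairs = tree.query_pairs(self.clash_floor, output_type="ndarray")
        if len(pairs):
            keep = np.abs(self.atom_res[pairs[:, 0]]
                          - self.atom_res[pairs[:, 1]]) > 1
            pairs = pairs[keep]
        if len(pairs):
            diff = x[pairs[:, 0]] - x[pairs[:, 1]]
            d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
            gap = self.clash_floor - d
            e_clash = float(self.clash_w * (gap ** 2).sum())
            if with_grad:
                coef = -2.0 * self.clash_w * gap / d
                gv = coef[:, None] * diff
                np.add.at(g, pairs[:, 0], gv)
                np.add.at(g, pairs[:, 1], -gv)
        terms["clash"] = e_clash

        terms["total"] = sum(terms.values())
        return (terms, g) if with_grad else terms

    # -- model <-> flat vector ---------------------------------------------

    def pack(self, m: Model) -> np.ndarray:
        x = np.empty((self.n_atoms, 3))
        arrs = {"N": m.n, "CA": m.ca, "C": m.c, "O": m.o, "CB": m.cb}
        for k, (res, nm) in enumerate(self.atom_names):
            x[k] = arrs[nm][res]
        return x

    def unpack(self, x: np.ndarray) -> Model:
        L = self.L
        arrs = {nm: np.full((L, 3), np.nan) for nm in ("N", "CA", "C", "O", "CB")}
        for k, (res, nm) in enumerate(self.atom_names):
            arrs[nm][res] = x[k]
        return Model(self.sequence, arrs["N"], arrs["CA"], arrs["C"],
                     arrs["O"], arrs["CB"])

    def residue_violation_scores(self, x: np.ndarray) -> np.ndarray:
        """Per-residue sum of flat-bottom violation energies (B-factor
        column of written models)."""
        scores = np.zeros(self.L)
        if len(self.fb_i):
            diff = x[self.fb_i] - x[self.fb_j]
            d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
            viol = (np.maximum(self.fb_lo - d, 0.0)
                    + np.maximum(d - self.fb_hi, 0.0))
            e = self.fb_w * viol ** 2
            np.add.at(scores, self.atom_res[self.fb_i], e / 2)
            np.add.at(scores, self.atom_res[self.fb_j], e / 2)
        return scores


def _soft_well(viol: np.ndarray, switch: float):
    """Energy and d(energy)/d(violation) of a soft square well: quadratic up
    to ``switch``, linear beyond (continuous value and slope)."""
    inside = viol <= switch
    e = np.where(inside, viol ** 2, switch ** 2 + 2.0 * switch * (viol - switch))
    de = np.where(inside, 2.0 * viol, 2.0 * switch)
    return e, de


def _dihedral_and_grad(x: np.ndarray, quads: np.ndarray, with_grad: bool):
    """Torsion angles for atom quadruples plus (optionally) the four
    per-atom angle gradients (Blondel-Karplus form)."""
    p1, p2, p3, p4 = (x[quads[:, k]] for k in range(4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / b2n[:, None])
    phi = np.arctan2((m1 * n2).sum(axis=1), (n1 * n2).sum(axis=1))
    if not with_grad:
        return phi, None
    n1sq = np.maximum((n1 ** 2).sum(axis=1), 1e-12)
    n2sq = np.maximum((n2 ** 2).sum(axis=1), 1e-12)
    f = ((b2n / n1sq))[:, None] * n1       # dphi/dp1
    h = (-(b2n / n2sq))[:, None] * n2      # dphi/dp4
    p = ((b1 * b2).sum(axis=1) / b2n ** 2)[:, None]
    q = ((b3 * b2).sum(axis=1) / b2n ** 2)[:, None]
    g2 = -(1.0 + p) * f + q * h            # dphi/dp2
    g3 = p * f - (1.0 + q) * h             # dphi/dp3
    return phi, (f, g2, g3, h)


def _scatter_quad_grads(g, quads, grads, dedphi):
    for k, gk in enumerate(grads):
        np.add.at(g, quads[:, k], dedphi[:, None] * gk)


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def _annealed_minimize(fun, x0: np.ndarray, cfg: BuilderConfig,
                       rng: np.random.Generator, noise_scale: float,
                       n_stages: int | None = None, maxiter: int | None = None,
                       t_start: float | None = None):
    """Geometric-cooling annealing loop: per stage, inject temperature-scaled
    coordinate noise, then minimize in two L-BFGS chunks. Checkpoint energies
    within a stage are non-increasing (line-searched descent); stochastic
    uphill moves happen only at stage boundaries. Returns (x, checkpoints).
    """
    from scipy.optimize import minimize

    shape = x0.shape
    x = x0.ravel().copy()
    checkpoints = []
    n = n_stages if n_stages is not None else cfg.n_stages
    t0 = t_start if t_start is not None else cfg.t_start
    ratio = (cfg.t_end / t0) ** (1.0 / max(n - 1, 1))
    for stage in range(n):
        temp = t0 * ratio ** stage
        if stage > 0 and noise_scale > 0:
            x = x + rng.normal(0.0, noise_scale * math.sqrt(temp), x.shape)
        stage_cp = [float(fun(x)[0])]
        chunk = max((maxiter if maxiter is not None
                     else cfg.steps_per_stage) // 2, 1)
        for _ in range(2):
            res = minimize(fun, x, jac=True, method="L-BFGS-B",
                           options={"maxiter": chunk})
            if res.fun <= stage_cp[-1]:
                x = res.x
                stage_cp.append(float(res.fun))
        checkpoints.append(stage_cp)
    return x.reshape(shape), checkpoints


CB_STEP_UPPER = 6.9    # sequential reference-atom (CB) ladder, A
CB_STEP_LOWER = 3.8


def _trace_objective(bounds: list, L: int, repulsion: bool = True,
                     soft_switch: float = 1.0):
    """Two-point trace objective over reference atoms (CB, CA for glycine)
    and CA atoms: flat-bottom restraint wells on the reference atoms, a
    harmonic sequential CA ladder, a harmonic CA-CB tether, and (optionally)
    a hard-sphere floor. Every term depends only on pairwise distances, so
    the objective is exactly reflection-invariant.

    Layout: x[0:L] are reference atoms, x[L:2L] are CA.
    """
    bi = np.array([b.i - 1 for b in bounds], dtype=int)
    bj = np.array([b.j - 1 for b in bounds], dtype=int)
    blo = np.array([b.lower for b in bounds])
    bhi = np.array([b.upper for b in bounds])
    bw = np.array([getattr(b, "weight", 1.0) for b in bounds])
    res = np.concatenate([np.arange(L), np.arange(L)])
    ca = np.arange(L, 2 * L)

    def fun(xf):
        x = xf.reshape(2 * L, 3)
        g = np.zeros_like(x)
        e = 0.0
        if len(bi):
            diff = x[bi] - x[bj]
            d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
            below = np.maximum(blo - d, 0.0)
            above = np.maximum(d - bhi, 0.0)
            e_well, de_well = _soft_well(below + above, soft_switch)
            e += float((bw * e_well).sum())
            gv = (bw * de_well * np.sign(above - below) / d)[:, None] * diff
            np.add.at(g, bi, gv)
            np.add.at(g, bj, -gv)
        for ai, aj, d0, w in ((ca[:-1], ca[1:], CA_STEP, 10.0),
                              (np.arange(L), ca, sio.BOND_CA_CB, 10.0)):
            diff = x[ai] - x[aj]
            d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
            dev = d - d0
            e += float(w * (dev ** 2).sum())
            gv = (2.0 * w * dev / d)[:, None] * diff
            np.add.at(g, ai, gv)
            np.add.at(g, aj, -gv)
        if repulsion:
            pairs = cKDTree(x).query_pairs(NONBONDED_FLOOR,
                                           output_type="ndarray")
            if len(pairs):
                pairs = pairs[np.abs(res[pairs[:, 0]] - res[pairs[:, 1]]) > 1]
            if len(pairs):
                diff = x[pairs[:, 0]] - x[pairs[:, 1]]
                d = np.maximum(np.linalg.norm(diff, axis=1), 1e-9)
                gap = NONBONDED_FLOOR - d
                e += float((gap ** 2).sum())
                gv = (-2.0 * gap / d)[:, None] * diff
                np.add.at(g, pairs[:, 0], gv)
                np.add.at(g, pairs[:, 1], -gv)
        return e, g.ravel()

    return fun


def refine_trace(ref_points: np.ndarray, restraints: RestraintSet,
                 cfg: BuilderConfig, rng_seed: int | None = None) -> np.ndarray:
    """Pull an embedded reference-atom trace into the distance-bound network
    and derive a companion CA trace.

    Runs the annealed minimization in two phases: first without the
    hard-sphere floor (the chain may pass through itself while the topology
    sorts out), then with it. All terms are reflection-invariant, so
    mirrored starts stay fair mirror candidates. Returns the (L, 3) CA
    trace.
    """
    L = ref_points.shape[0]
    rng = np.random.default_rng(cfg.rng_seed if rng_seed is None else rng_seed)
    # companion CA start: nudge reference atoms toward the centroid
    cen = ref_points.mean(axis=0)
    off = cen - ref_points
    nrm = np.maximum(np.linalg.norm(off, axis=1, keepdims=True), 1e-9)
    ca0 = ref_points + sio.BOND_CA_CB * off / nrm
    x = np.concatenate([ref_points, ca0], axis=0)

    f_soft = _trace_objective(restraints.bounds, L, repulsion=False,
                              soft_switch=cfg.soft_switch)
    f_full = _trace_objective(restraints.bounds, L, repulsion=True,
                              soft_switch=cfg.soft_switch)
    x, _ = _annealed_minimize(f_soft, x, cfg, rng,
                              noise_scale=6.0 * cfg.noise_scale,
                              maxiter=3 * cfg.steps_per_stage)
    x, _ = _annealed_minimize(f_full, x, cfg, rng,
                              noise_scale=3.0 * cfg.noise_scale,
                              n_stages=max(cfg.n_stages // 2, 2),
                              t_start=cfg.t_start / 4.0,
                              maxiter=3 * cfg.steps_per_stage)
    return x[L:]


def refine(start, restraints: RestraintSet, cfg: BuilderConfig,
           sequence: str | None = None, rng_seed: int | None = None,
           return_checkpoints: bool = False):
    """Anneal a starting model (or bare CA trace) against the restraint
    potential. A bare trace is first pulled into the bound network at CA
    resolution, then dressed with a full ideal-geometry backbone and annealed
    against the complete potential. Deterministic per seed; a final energy
    above ``cfg.energy_ceiling`` flags the model unconverged rather than
    failing.
    """
    seed = cfg.rng_seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    if isinstance(start, Model):
        model = start
    else:
        if sequence is None:
            raise ValueError("a bare trace needs the sequence")
        ca = refine_trace(np.asarray(start), restraints, cfg,
                          rng_seed=int(rng.integers(2 ** 31)))
        model = backbone_on_trace(sequence, ca)
    em = _EnergyModel(model.sequence, restraints, cfg)

    def fun(xf):
        terms, g = em.energy_grad(xf.reshape(-1, 3))
        return terms["total"], g.ravel()

    x, checkpoints = _annealed_minimize(fun, em.pack(model), cfg, rng,
                                        noise_scale=cfg.noise_scale)
    # basin-hopping polish: small kicks, deep minimization, keep the best
    from scipy.optimize import minimize
    best_x = x.ravel()
    best_e = em.energy_grad(x, with_grad=False)["total"]
    for hop in range(3):
        x0 = best_x if hop == 0 else \
            best_x + rng.normal(0.0, 0.05, best_x.shape)
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": cfg.polish_iterations})
        if res.fun < best_e:
            best_x, best_e = res.x, float(res.fun)
            checkpoints[-1].append(best_e)
    x = best_x.reshape(-1, 3)
    terms = em.energy_grad(x, with_grad=False)

    out = em.unpack(x)
    out.energy = terms
    n_restraints = (len(restraints.bounds) + len(restraints.hbonds)
                    + len(restraints.torsions))
    ceiling = cfg.energy_ceiling + cfg.ceiling_per_restraint * n_restraints
    out.converged = terms["total"] <= ceiling
    out.bfactors = em.residue_violation_scores(x)
    if not out.converged:
        logger.warning("refine: final energy %.2f above ceiling %.2f",
                       terms["total"], ceiling)
    if return_checkpoints:
        return out, checkpoints
    return out


def energy_breakdown(model: Model, restraints: RestraintSet,
                     cfg: BuilderConfig | None = None) -> dict:
    """Evaluate the builder potential on an existing model."""
    cfg = cfg or BuilderConfig()
    em = _EnergyModel(model.sequence, restraints, cfg)
    return em.energy_grad(em.pack(model), with_grad=False)


def trace_handedness_penalty(ca: np.ndarray) -> float:
    """Left-handedness penalty of a CA trace: sum of sin^2(tau) over compact
    4-mer windows with negative torsion. Mirror images of a right-handed
    helical trace score strictly higher."""
    L = ca.shape[0]
    if L < 4:
        return 0.0
    tau = sio.dihedral(ca[:-3], ca[1:-2], ca[2:-1], ca[3:])
    dturn = np.linalg.norm(ca[:-3] - ca[3:], axis=1)
    sel = (dturn < HELIX_WINDOW_CUTOFF) & (np.sin(tau) < 0)
    return float((np.sin(tau[sel]) ** 2).sum())


@dataclass
class Ensemble:
    models: list            # sorted by total energy, ascending
    config: BuilderConfig

    def __len__(self):
        return len(self.models)

    def best(self) -> Model:
        return self.models[0]


def build_ensemble(restraints: RestraintSet, cfg: BuilderConfig,
                   sequence: str) -> Ensemble:
    """cfg.ensemble_size independent embed+refine runs.

    Each run embeds a sampled distance matrix, pulls the trace into the
    bound network, and — in ``both`` mirror mode — considers the reflected
    trace as well (the trace objective is reflection-invariant, so the
    mirror of an optimized trace is equally optimal): the hand with the
    lower left-handedness penalty is dressed with a full backbone and
    annealed against the complete potential. Models are sorted by total
    energy."""
    if cfg.ensemble_size < 1:
        raise ValueError("ensemble size must be >= 1")
    L = len(sequence)
    informative = [b for b in restraints.bounds
                   if getattr(b, "weight", 1.0) >= 0.2]
    lower, upper = smooth_bounds(informative, L,
                                 chain_upper=CB_STEP_UPPER,
                                 chain_lower=CB_STEP_LOWER)
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(cfg.ensemble_size)
    models = []
    for member, ss in enumerate(seeds):
        embed_seed, trace_seed, final_seed = [
            int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
        ref = embed_initial(lower, upper, rng_seed=embed_seed)
        ca = refine_trace(ref, restraints, cfg, rng_seed=trace_seed)
        if cfg.mirror_mode == "both":
            mirrored = ca * np.array([1.0, 1.0, -1.0])
            if trace_handedness_penalty(mirrored) < trace_handedness_penalty(ca):
                ca = mirrored
        elif cfg.mirror_mode == "mirror":
            ca = ca * np.array([1.0, 1.0, -1.0])
        model = refine(backbone_on_trace(sequence, ca), restraints, cfg,
                       rng_seed=final_seed)
        models.append(model)
    models.sort(key=lambda m: m.energy["total"])
    return Ensemble(models, cfg)
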