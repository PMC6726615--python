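"""Structure I/O and geometry: PDB reading/writing, Kabsch superposition,
TM-score, backbone construction from torsions, and geometric H-bond detection.

The in-memory structure type is :class:`Model`: a backbone-only protein model
holding N, CA, C, O and CB coordinates per residue (CB is absent, stored as
NaN, for glycine). All distances are in Angstroms, angles in radians.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("distfold")

# ---------------------------------------------------------------------------
# Ideal backbone geometry (standard stereochemical values)
# ---------------------------------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329  # peptide bond
BOND_C_O = 1.231
BOND_CA_CB = 1.521

ANGLE_N_CA_C = math.radians(111.2)
ANGLE_CA_C_N = math.radians(116.2)
ANGLE_C_N_CA = math.radians(121.7)
ANGLE_CA_C_O = math.radians(120.8)
ANGLE_N_CA_CB = math.radians(110.6)
# Improper torsion C-N-CA-CB fixing the L-configuration of the side chain.
TORSION_C_N_CA_CB = math.radians(-122.6)

BACKBONE_ATOMS = ("N", "CA", "C", "O", "CB")

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class Model:
    """Backbone-only protein model.

    Coordinate arrays are (L, 3) float64. ``cb`` rows are NaN for glycine.
    """

    sequence: str
    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    cb: np.ndarray
    bfactors: np.ndarray | None = None
    energy: dict | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        L = len(self.sequence)
        for name in ("n", "ca", "c", "o", "cb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} coordinates must have shape ({L}, 3)")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.sequence)

    def cb_or_ca(self) -> np.ndarray:
        """CB coordinates with CA substituted for glycine (the distance
        reference atoms of the distogram)."""
        out = self.cb.copy()
        gly = np.array([aa == "G" for aa in self.sequence])
        out[gly] = self.ca[gly]
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Model":
        def t(x):
            return x @ rotation.T + translation
        return Model(self.sequence, t(self.n), t(self.ca), t(self.c), t(self.o),
                     t(self.cb), bfactors=self.bfactors)

    def mirrored(self) -> "Model":
        """Reflection through the xy-plane (all pairwise distances preserved,
        chirality inverted)."""
        flip = np.diag([1.0, 1.0, -1.0])
        return Model(self.sequence, self.n @ flip, self.ca @ flip,
                     self.c @ flip, self.o @ flip, self.cb @ flip)

    def copy(self) -> "Model":
        return Model(self.sequence, self.n.copy(), self.ca.copy(), self.c.copy(),
                     self.o.copy(), self.cb.copy(),
                     bfactors=None if self.bfactors is None else self.bfactors.copy(),
                     energy=None if self.energy is None else dict(self.energy),
                     converged=self.converged)


def cb_distance_matrix(m: Model) -> np.ndarray:
    """Symmetric L x L matrix of CB-CB distances (CA for glycine)."""
    cb = m.cb_or_ca()
    diff = cb[:, None, :] - cb[None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

@dataclass
class ParseReport:
    residues: int = 0
    skipped_lines: int = 0
    rejected_residues: int = 0
    messages: list = field(default_factory=list)


def write_pdb(m: Model, bfactors: np.ndarray | None = None) -> str:
    """Serialize a model as fixed-column PDB ATOM records (chain A, 1-based).

    B-factor column carries ``bfactors`` (e.g. a per-residue restraint
    violation score) when given, else the model's own, else zeros.
    """
    b = bfactors if bfactors is not None else m.bfactors
    if b is None:
        b = np.zeros(len(m))
    lines = []
    serial = 1
    for i, aa in enumerate(m.sequence):
        res3 = _AA1TO3.get(aa, "UNK")
        atoms = [("N", m.n[i], "N"), ("CA", m.ca[i], "C"), ("C", m.c[i], "C"),
                 ("O", m.o[i], "O")]
        if aa != "G":
            atoms.append(("CB", m.cb[i], "C"))
        for name, xyz, elem in atoms:
            lines.append(
                f"ATOM  {serial:5d}  {name:<4s}{res3:>3s} A{i + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{b[i]:6.2f}"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_pdb(text: str, return_report: bool = False):
    """Parse backbone coordinates from PDB text.

    Residues missing CA are rejected with a warning; malformed ATOM lines are
    skipped and counted in the parse report. Missing CB (non-glycine) is
    synthesized from ideal geometry. Raises ``ValueError`` on an empty chain.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    report = ParseReport()
    # Pre-screen ATOM records: Bio.PDB's permissive parser can still choke on
    # badly truncated lines, so count and drop those ourselves.
    kept = []
    for line in text.splitlines():
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                report.skipped_lines += 1
                report.messages.append(f"skipped malformed record: {line[:26]!r}")
                continue
        kept.append(line)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(PERMISSIVE=True, QUIET=True)
        structure = parser.get_structure("model", io.StringIO("\n".join(kept)))

    models = list(structure.get_models())
    if not models:
        raise ValueError("empty chain: no residues with CA found")
    seq, rows = [], []
    for res in models[0].get_residues():
        if res.id[0].strip():
            continue  # het/water
        atoms = {a.get_name(): a.get_coord() for a in res}
        if "CA" not in atoms:
            report.rejected_residues += 1
            report.messages.append(f"residue {res.id[1]} has no CA; rejected")
            logger.warning("read_pdb: residue %s has no CA; rejected", res.id[1])
            continue
        aa = _AA3TO1.get(res.get_resname(), "X")
        seq.append(aa)
        rows.append([atoms.get(nm, np.full(3, np.nan)) for nm in BACKBONE_ATOMS])
    if not seq:
        raise ValueError("empty chain: no residues with CA found")

    coords = np.array(rows, dtype=float)
    m = Model("".join(seq), coords[:, 0], coords[:, 1], coords[:, 2],
              coords[:, 3], coords[:, 4])
    _fill_missing(m)
    report.residues = len(m)
    if return_report:
        return m, report
    return m


def _fill_missing(m: Model) -> None:
    """Synthesize missing N/C/O/CB from ideal geometry around available atoms."""
    L = len(m)
    for i in range(L):
        if np.isnan(m.n[i]).any() or np.isnan(m.c[i]).any():
            # fall back to placements along the CA trace
            prev_ca = m.ca[i - 1] if i > 0 else m.ca[i] + np.array([3.8, 0, 0])
            next_ca = m.ca[i + 1] if i < L - 1 else m.ca[i] - np.array([3.8, 0, 0])
            u = _unit(prev_ca - m.ca[i]); v = _unit(next_ca - m.ca[i])
            if np.isnan(m.n[i]).any():
                m.n[i] = m.ca[i] + BOND_N_CA * u
            if np.isnan(m.c[i]).any():
                m.c[i] = m.ca[i] + BOND_CA_C * v
        if np.isnan(m.o[i]).any():
            ref = m.n[i + 1] if i < L - 1 else m.n[i]
            d = _unit(m.c[i] - 0.5 * (m.ca[i] + ref))
            m.o[i] = m.c[i] + BOND_C_O * d
        if m.sequence[i] != "G" and np.isnan(m.cb[i]).any():
            m.cb[i] = place_atom(m.c[i], m.n[i], m.ca[i], BOND_CA_CB,
                                 ANGLE_N_CA_CB, TORSION_C_N_CA_CB)
        if m.sequence[i] == "G":
            m.cb[i] = np.nan


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 1e-12 else np.array([1.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# Internal-coordinate construction (NeRF)
# ---------------------------------------------------------------------------

def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D given A-B-C with |C-D| = bond, angle(B,C,D) = angle and
    torsion(A,B,C,D) = torsion (natural extension reference frame)."""
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m_ = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(torsion),
        -bond * math.sin(angle) * math.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m_ + d_local[2] * n


def backbone_from_torsions(sequence: str, phi: np.ndarray, psi: np.ndarray,
                           omega: np.ndarray | None = None) -> Model:
    """Build an ideal-geometry backbone from phi/psi (and optional omega)
    torsions. ``phi[0]`` and ``psi[-1]`` are not used to place any atom but
    must be present.
    """
    L = len(sequence)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (L,) or psi.shape != (L,):
        raise ValueError("phi/psi must have one value per residue")
    if omega is None:
        omega = np.full(L, math.pi)

    n = np.zeros((L, 3)); ca = np.zeros((L, 3)); c = np.zeros((L, 3))
    n[0] = [0.0, 0.0, 0.0]
    ca[0] = [BOND_N_CA, 0.0, 0.0]
    c[0] = ca[0] + BOND_CA_C * np.array(
        [-math.cos(ANGLE_N_CA_C), math.sin(ANGLE_N_CA_C), 0.0])
    for i in range(1, L):
        n[i] = place_atom(n[i - 1], ca[i - 1], c[i - 1], BOND_C_N,
                          ANGLE_CA_C_N, psi[i - 1])
        ca[i] = place_atom(ca[i - 1], c[i - 1], n[i], BOND_N_CA,
                           ANGLE_C_N_CA, omega[i])
        c[i] = place_atom(c[i - 1], n[i], ca[i], BOND_CA_C,
                          ANGLE_N_CA_C, phi[i])

    o = np.zeros((L, 3)); cb = np.full((L, 3), np.nan)
    for i in range(L):
        # carbonyl O trans to the next amide N about the CA-C axis
        psi_i = psi[i] if i < L - 1 else math.pi / 2
        o[i] = place_atom(n[i], ca[i], c[i], BOND_C_O, ANGLE_CA_C_O,
                          psi_i + math.pi)
        if sequence[i] != "G":
            cb[i] = place_atom(c[i], n[i], ca[i], BOND_CA_CB,
                               ANGLE_N_CA_CB, TORSION_C_N_CA_CB)
    return Model(sequence, n, ca, c, o, cb)


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
             p4: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) in (-pi, pi] for quadruples of points.

    Accepts (3,) vectors or (..., 3) stacks.
    """
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    return np.arctan2(y, x)


def phi_psi(m: Model) -> tuple[np.ndarray, np.ndarray]:
    """Backbone phi/psi per residue (NaN where undefined: phi[0], psi[-1])."""
    L = len(m)
    phi = np.full(L, np.nan)
    psi = np.full(L, np.nan)
    if L >= 2:
        phi[1:] = dihedral(m.c[:-1], m.n[1:], m.ca[1:], m.c[1:])
        psi[:-1] = dihedral(m.n[:-1], m.ca[:-1], m.c[:-1], m.n[1:])
    return phi, psi


# ---------------------------------------------------------------------------
# Superposition and TM-score
# ---------------------------------------------------------------------------

@dataclass
class Superposition:
    rotation: np.ndarray   # 3x3, proper (det = +1)
    translation: np.ndarray
    n_pairs: int

    def apply(self, x: np.ndarray) -> np.ndarray:
        return x @ self.rotation.T + self.translation


def kabsch(a: np.ndarray, b: np.ndarray) -> tuple[Superposition, float]:
    """Least-squares proper superposition of ``a`` onto ``b``.

    Returns the superposition (rotation restricted to det = +1; reflections
    are never used) and the resulting RMSD. Degenerate (e.g. collinear) input
    raises ``ValueError``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (N, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    h = (a - ac).T @ (b - bc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9:
        raise ValueError("degenerate (collinear) coordinates")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = bc - rot @ ac
    resid = (a @ rot.T + trans) - b
    rmsd = float(np.sqrt((resid ** 2).sum() / a.shape[0]))
    return Superposition(rot, trans, a.shape[0]), rmsd


def tm_d0(L: int) -> float:
    """TM-score distance scale d0, floored at 0.5 for short chains."""
    if L > 15:
        return max(1.24 * (L - 15) ** (1.0 / 3.0) - 1.8, 0.5)
    return 0.5


def tm_score(model: Model, reference: Model) -> float:
    """TM-score of ``model`` against ``reference`` on CA atoms, normalized by
    the reference length, with the fixed 1:1 residue correspondence.

    Maximized over superpositions by fragment-seeded Kabsch refinement: each
    seed fragment is superposed, then the aligned set is iteratively re-grown
    from residues within a distance cutoff until stable; the best score over
    all seeds is returned.
    """
    if len(model) != len(reference):
        raise ValueError("tm_score requires equal-length models")
    return _tm_coords(model.ca, reference.ca)


def _tm_coords(xa: np.ndarray, xb: np.ndarray) -> float:
    L = xb.shape[0]
    d0 = tm_d0(L)
    d0sq = d0 * d0

    def score_from(sup: Superposition) -> tuple[float, np.ndarray]:
        d2 = ((sup.apply(xa) - xb) ** 2).sum(axis=1)
        return float((1.0 / (1.0 + d2 / d0sq)).sum() / L), d2

    best = 0.0
    if L <= 8:
        from itertools import combinations
        seeds = [np.array(c) for size in range(3, L + 1)
                 for c in combinations(range(L), size)]
    else:
        seeds = []
        for fl in sorted({L, max(L // 2, 4), max(L // 4, 4), 4}):
            step = max(1, fl // 2)
            seeds.extend(np.arange(s, s + fl)
                         for s in range(0, L - fl + 1, step))
    for seed_idx in seeds:
        idx = seed_idx
        for _ in range(10):  # seed + refinement rounds until stable
            try:
                sup, _ = kabsch(xa[idx], xb[idx])
            except ValueError:
                break
            s, d2 = score_from(sup)
            best = max(best, s)
            # re-grow alignment set from close residues
            cut = max(d0sq * 4, np.sort(d2)[min(3, L - 1)])
            new = np.flatnonzero(d2 <= cut)
            if len(new) < 3 or np.array_equal(new, idx):
                break
            idx = new
    return best


# ---------------------------------------------------------------------------
# H-bond detection
# ---------------------------------------------------------------------------

def detect_hbonds(m: Model, cutoff: float = 3.5,
                  min_separation: int = 2) -> list[tuple[int, int]]:
    """Directional backbone H-bonds by the geometric criterion: donor amide N
    of residue i within ``cutoff`` Angstroms of acceptor carbonyl O of
    residue j, |i - j| >= min_separation. Returns 0-based (donor, acceptor)
    pairs.
    """
    diff = m.n[:, None, :] - m.o[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    ii, jj = np.meshgrid(np.arange(len(m)), np.arange(len(m)), indexing="ij")
    mask = (np.abs(ii - jj) >= min_separation) & (d <= cutoff)
    return [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]


def hbond_precision(predicted: list, m: Model, cutoff: float = 3.5,
                    min_separation: int = 2) -> float | None:
    """Fraction of predicted donor->acceptor pairs geometrically present in
    ``m``. ``predicted`` holds (donor, acceptor) 0-based pairs or objects with
    ``donor_res``/``acceptor_res`` 1-based fields. Returns None on an empty
    prediction list."""
    pairs = []
    for p in predicted:
        if hasattr(p, "donor_res"):
            pairs.append((p.donor_res - 1, p.acceptor_res - 1))
        else:
            pairs.append((int(p[0]), int(p[1])))
    if not pairs:
        logger.warning("hbond_precision: empty prediction list")
        return None
    detected = set(detect_hbonds(m, cutoff=cutoff, min_separation=min_separation))
    hits = sum(1 for p in pairs if p in detected)
    return hits / len(pairs)
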