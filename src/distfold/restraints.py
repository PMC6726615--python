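"""Restraint derivation: distograms, H-bond maps and torsion predictions are
converted into NOE-like distance bounds, directional H-bond restraints and
dihedral restraints, collected in a :class:`RestraintSet`.

Distance bounds are grown accretively around the maximum-likelihood bin until
the cumulative likelihood reaches a threshold (default 0.4), so less confident
predictions yield wider bounds. The unbounded last bin never contributes, so
every upper bound stays at or below the 19-A edge. H-bond restraints are
emitted for map cells at or above a likelihood threshold (default 0.85),
keeping donor/acceptor directionality. Torsion restraints cover phi and psi
only; omega predictions are not used as modelling constraints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .distogram import BinScheme, Distogram
from .structio import Model, cb_distance_matrix

ACCRETION_THRESHOLD = 0.4
HBOND_THRESHOLD = 0.85
HBOND_NO_TARGET = 2.95       # flat-bottom N-O well center, A
HBOND_NO_HALFWIDTH = 0.25    # well half-width: satisfied inside 2.7-3.2 A
HBOND_CONTACT_CUTOFF = 3.5   # satisfaction criterion for counting, A
TORSION_DEVIATION_FLOOR = math.radians(5.0)


@dataclass
class DistanceBound:
    """Flat-bottom bound between the CB atoms (CA for glycine) of residues
    i < j (1-based)."""
    i: int
    j: int
    lower: float
    upper: float
    cumulative_likelihood: float
    atom_i: str = "CB"
    atom_j: str = "CB"
    #: confidence weight used by the builder: the bound's excess cumulative
    #: likelihood over an uninformative (uniform) prediction of the same bin
    #: span, normalized to [0, 1]. Uniform-corrupted pairs score 0.
    weight: float = 1.0

    def __post_init__(self):
        if not self.i < self.j:
            raise ValueError("bounds require i < j")
        if not (3.5 <= self.lower < self.upper <= 19.0):
            raise ValueError(f"bound ({self.lower}, {self.upper}) outside the "
                             "binned range [3.5, 19]")


@dataclass
class HBondRestraint:
    donor_res: int      # 1-based; backbone amide N
    acceptor_res: int   # 1-based; backbone carbonyl O
    likelihood: float
    target: float = HBOND_NO_TARGET
    halfwidth: float = HBOND_NO_HALFWIDTH

    def __post_init__(self):
        if self.donor_res == self.acceptor_res:
            raise ValueError("donor and acceptor must differ")


@dataclass
class TorsionRestraint:
    residue: int        # 1-based
    angle: str          # "phi" | "psi"
    target: float       # radians, (-pi, pi]
    deviation: float    # radians, > 0

    def __post_init__(self):
        if self.angle not in ("phi", "psi"):
            raise ValueError("angle must be phi or psi")
        if not (-math.pi < self.target <= math.pi):
            raise ValueError("target must lie in (-pi, pi]")
        if self.deviation <= 0:
            raise ValueError("deviation must be positive")


@dataclass
class RestraintSet:
    bounds: list = field(default_factory=list)
    hbonds: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def max_residue(self) -> int:
        idx = [0]
        idx += [b.j for b in self.bounds]
        idx += [max(h.donor_res, h.acceptor_res) for h in self.hbonds]
        idx += [t.residue for t in self.torsions]
        return max(idx)


# ---------------------------------------------------------------------------
# Bound accretion
# ---------------------------------------------------------------------------

def accrete_bounds(p: np.ndarray, scheme: BinScheme,
                   threshold: float = ACCRETION_THRESHOLD):
    """Distance bounds for one pair by likelihood accretion.

    Starting from the maximum-likelihood bin, the contiguous bin interval is
    repeatedly extended by whichever adjacent bin has higher likelihood (ties
    extend left, toward shorter distances) until the cumulative likelihood
    reaches ``threshold``. The unbounded last bin is excluded throughout; if
    the maximum-likelihood bin is the last bin, or the threshold cannot be
    reached from the bounded bins, no bound is emitted (returns None).

    Returns (lower, upper, cumulative_likelihood) in Angstroms.
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (scheme.n_bins,):
        raise ValueError("p must hold one likelihood per bin")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-12):
        raise ValueError("p must be a normalized likelihood vector")

    last = scheme.n_bins - 1
    k = int(p.argmax())
    if k == last:
        return None
    lo = hi = k
    total = p[k]
    while total < threshold - 1e-12:
        left = p[lo - 1] if lo > 0 else -np.inf
        right = p[hi + 1] if hi + 1 < last else -np.inf  # last bin excluded
        if left == -np.inf and right == -np.inf:
            return None  # threshold unreachable without the unbounded bin
        if left >= right:
            lo -= 1
            total += p[lo]
        else:
            hi += 1
            total += p[hi]
    return float(scheme.edges[lo]), float(scheme.edges[hi + 1]), float(total)


def distogram_to_bounds(d: Distogram, sequence: str | None = None,
                        threshold: float = ACCRETION_THRESHOLD,
                        min_separation: int = 2) -> list[DistanceBound]:
    """One DistanceBound per unordered residue pair with |i - j| >=
    min_separation for which accretion emits. Atom roles are CB, or CA for
    glycine when ``sequence`` is given."""
    L = d.length
    out = []
    for i in range(L):
        for j in range(i + min_separation, L):
            res = accrete_bounds(d.likelihoods[i, j], d.scheme, threshold)
            if res is None:
                continue
            lower, upper, cum = res
            ai = "CA" if sequence and sequence[i] == "G" else "CB"
            aj = "CA" if sequence and sequence[j] == "G" else "CB"
            n_bins = int(np.searchsorted(d.scheme.edges, upper - 1e-9)
                         - np.searchsorted(d.scheme.edges, lower + 1e-9) + 1)
            chance = n_bins / d.scheme.n_bins
            weight = max(0.0, (cum - chance) / (1.0 - chance))
            out.append(DistanceBound(i + 1, j + 1, lower, upper, cum,
                                     atom_i=ai, atom_j=aj, weight=weight))
    return out


def hbond_map_to_restraints(hmap: np.ndarray,
                            threshold: float = HBOND_THRESHOLD,
                            min_separation: int = 2) -> list[HBondRestraint]:
    """One directional restraint per donor(row) -> acceptor(column) cell at or
    above ``threshold``."""
    hmap = np.asarray(hmap, dtype=float)
    if hmap.ndim != 2 or hmap.shape[0] != hmap.shape[1]:
        raise ValueError("H-bond map must be square")
    if np.any(hmap < 0) or np.any(hmap > 1):
        raise ValueError("H-bond likelihoods must lie in [0, 1]")
    out = []
    L = hmap.shape[0]
    for i in range(L):
        for j in range(L):
            if abs(i - j) < min_separation:
                continue
            if hmap[i, j] >= threshold:
                out.append(HBondRestraint(i + 1, j + 1, float(hmap[i, j])))
    return out


def torsions_to_restraints(angles: dict,
                           floor: float = TORSION_DEVIATION_FLOOR
                           ) -> list[TorsionRestraint]:
    """Phi/psi restraints from predicted torsions with error estimates.

    ``angles`` maps angle names ("phi", "psi", optionally "omega") to
    (values, errors) arrays in radians. Omega predictions are dropped;
    deviations are floored at ``floor`` radians. Terminal NaN angles
    (phi of residue 1, psi of residue L) are skipped.
    """
    out = []
    for name in ("phi", "psi"):
        if name not in angles:
            continue
        values, errors = angles[name]
        for idx, (v, e) in enumerate(zip(np.asarray(values, dtype=float),
                                         np.asarray(errors, dtype=float))):
            if not np.isfinite(v):
                continue
            target = _wrap_angle(float(v))
            out.append(TorsionRestraint(idx + 1, name, target,
                                        max(float(e), floor)))
    return out


def _wrap_angle(a: float) -> float:
    w = (a + math.pi) % (2.0 * math.pi) - math.pi
    return math.pi if w == -math.pi else w


def circular_difference(a, b):
    """Signed circular difference a - b wrapped into (-pi, pi]."""
    d = np.mod(np.asarray(a) - np.asarray(b) + np.pi, 2.0 * np.pi) - np.pi
    return d


# ---------------------------------------------------------------------------
# Satisfaction counting
# ---------------------------------------------------------------------------

def count_satisfied(rset: RestraintSet, model: Model,
                    hbond_cutoff: float = HBOND_CONTACT_CUTOFF) -> dict:
    """Per-category (satisfied, total) counts of a restraint set against a
    model: a bound is satisfied when lower <= CB-CB distance <= upper, an
    H-bond when donor N to acceptor O <= ``hbond_cutoff``, a torsion when the
    absolute circular difference <= its deviation."""
    L = len(model)
    if rset.max_residue() > L:
        raise ValueError("restraint indices exceed model length")
    from .structio import phi_psi

    dmat = cb_distance_matrix(model)
    b_ok = sum(1 for b in rset.bounds
               if b.lower - 1e-9 <= dmat[b.i - 1, b.j - 1] <= b.upper + 1e-9)

    h_ok = 0
    for h in rset.hbonds:
        d = np.linalg.norm(model.n[h.donor_res - 1] - model.o[h.acceptor_res - 1])
        if d <= hbond_cutoff + 1e-9:
            h_ok += 1

    phi, psi = phi_psi(model)
    t_ok = 0
    t_total = 0
    for t in rset.torsions:
        val = phi[t.residue - 1] if t.angle == "phi" else psi[t.residue - 1]
        if not np.isfinite(val):
            continue
        t_total += 1
        if abs(float(circular_difference(val, t.target))) <= t.deviation + 1e-9:
            t_ok += 1

    return {
        "bounds": (b_ok, len(rset.bounds)),
        "hbonds": (h_ok, len(rset.hbonds)),
        "torsions": (t_ok, t_total),
    }


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_restraints(rset: RestraintSet, dialect: str = "native-json") -> str:
    """Serialize a restraint set.

    ``cns-tbl``: NOE-style assign statements (midpoint d with dminus/dplus)
    plus a dihedral section; 1-based indices, glycine pairs select CA.
    ``native-json``: lossless round-trip format (see
    :func:`read_restraints`).
    """
    if dialect == "native-json":
        payload = {
            "format": "distfold-restraints-v1",
            "bounds": [asdict(b) for b in rset.bounds],
            "hbonds": [asdict(h) for h in rset.hbonds],
            "torsions": [asdict(t) for t in rset.torsions],
            "provenance": rset.provenance,
        }
        return json.dumps(payload, indent=1)
    if dialect == "cns-tbl":
        lines = ["! distfold restraints (NOE-style distance + dihedral)"]
        lines.append("! --- distance bounds ---")
        for b in rset.bounds:
            d = (b.lower + b.upper) / 2.0
            lines.append(
                f"assign (resid {b.i} and name {b.atom_i}) "
                f"(resid {b.j} and name {b.atom_j}) "
                f"{d:.2f} {d - b.lower:.2f} {b.upper - d:.2f}"
            )
        lines.append("! --- hydrogen bonds (N donor -> O acceptor) ---")
        for h in rset.hbonds:
            lines.append(
                f"assign (resid {h.donor_res} and name N) "
                f"(resid {h.acceptor_res} and name O) "
                f"{h.target:.2f} {h.halfwidth:.2f} {h.halfwidth:.2f}"
            )
        lines.append("! --- dihedral restraints ---")
        for t in rset.torsions:
            sel = _dihedral_selection(t)
            lines.append(
                f"assign {sel} 1.0 {math.degrees(t.target):.2f} "
                f"{math.degrees(t.deviation):.2f} 2"
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect: {dialect}")


def _dihedral_selection(t: TorsionRestraint) -> str:
    r = t.residue
    if t.angle == "phi":
        atoms = [(r - 1, "C"), (r, "N"), (r, "CA"), (r, "C")]
    else:
        atoms = [(r, "N"), (r, "CA"), (r, "C"), (r + 1, "N")]
    return " ".join(f"(resid {ri} and name {an})" for ri, an in atoms)


def read_restraints(text: str) -> RestraintSet:
    """Read the native-json dialect back."""
    payload = json.loads(text)
    if payload.get("format") != "distfold-restraints-v1":
        raise ValueError("not a distfold restraint file")
    return RestraintSet(
        bounds=[DistanceBound(**b) for b in payload["bounds"]],
        hbonds=[HBondRestraint(**h) for h in payload["hbonds"]],
        torsions=[TorsionRestraint(**t) for t in payload["torsions"]],
        provenance=payload.get("provenance", {}),
    )
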