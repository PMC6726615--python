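"""Distance-distribution (distogram) data model.

A distogram assigns each residue pair a probability distribution over 20
binned CB-CB distances (CA for glycine). This module defines the bin scheme,
the symmetrization of raw predictor scores, conversion to contact maps,
contact ranking, and distance-error statistics against a known structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structio import Model, cb_distance_matrix

N_BINS = 20

#: Center assigned to the unbounded last bin ([19, inf) Angstroms). Used only
#: for max-likelihood-bin bookkeeping (such pairs are excluded from distance
#: error statistics), never as a distance estimate.
LAST_BIN_SENTINEL_CENTER = 20.0


@dataclass(frozen=True)
class BinScheme:
    """20 half-open distance intervals [lo, hi), the last unbounded."""

    edges: np.ndarray    # 21 boundaries, edges[-1] == +inf
    centers: np.ndarray  # 20 representative values

    def __post_init__(self):
        edges = np.asarray(self.edges, dtype=float)
        centers = np.asarray(self.centers, dtype=float)
        if edges.shape != (N_BINS + 1,):
            raise ValueError("bin scheme needs 21 edges")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if not math.isinf(edges[-1]):
            raise ValueError("last edge must be +inf")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "centers", centers)

    @property
    def n_bins(self) -> int:
        return N_BINS

    def bin_of(self, distance) -> np.ndarray | int:
        """Index of the interval containing each distance. Distances below
        the first edge are clamped into the first bin."""
        d = np.asarray(distance, dtype=float)
        idx = np.searchsorted(self.edges, d, side="right") - 1
        idx = np.clip(idx, 0, N_BINS - 1)
        return idx if d.ndim else int(idx)


def default_bin_scheme() -> BinScheme:
    """The 20-channel scheme: [3.5, 4.5), then 0.5-A steps to 8 A, 1-A steps
    to 19 A, and a final unbounded bin for distances >= 19 A."""
    edges = np.concatenate([
        [3.5],
        np.arange(4.5, 8.0, 0.5),
        np.arange(8.0, 19.0 + 0.5, 1.0),
        [np.inf],
    ])
    centers = (edges[:-1] + edges[1:]) / 2.0
    centers[-1] = LAST_BIN_SENTINEL_CENTER
    return BinScheme(edges=edges, centers=centers)


@dataclass
class Distogram:
    """L x L x 20 per-pair distance-bin likelihoods with its bin scheme."""

    likelihoods: np.ndarray
    scheme: BinScheme = field(default_factory=default_bin_scheme)

    def __post_init__(self):
        p = np.asarray(self.likelihoods, dtype=float)
        if p.ndim != 3 or p.shape[0] != p.shape[1] or p.shape[2] != N_BINS:
            raise ValueError("likelihoods must be L x L x 20")
        self.likelihoods = p

    @property
    def length(self) -> int:
        return self.likelihoods.shape[0]

    def is_symmetric(self, tol: float = 1e-9) -> bool:
        p = self.likelihoods
        return bool(np.allclose(p, p.transpose(1, 0, 2), atol=tol))

    def validate(self, tol: float = 1e-6) -> None:
        p = self.likelihoods
        if np.any(p < -tol):
            raise ValueError("negative bin likelihoods")
        s = p.sum(axis=2)
        off = ~np.eye(self.length, dtype=bool)
        if not np.allclose(s[off], 1.0, atol=tol):
            raise ValueError("off-diagonal bin likelihoods must sum to 1")


@dataclass
class ContactMap:
    probabilities: np.ndarray  # L x L in [0, 1], symmetric, zero diagonal
    cutoff: float = 8.0

    @property
    def length(self) -> int:
        return self.probabilities.shape[0]


def symmetrize(logits: np.ndarray, scheme: BinScheme | None = None) -> Distogram:
    """Symmetrized distogram from raw (pre-softmax) scores: per-pair softmax
    over the 20 channels of logits + logits^T. This both enforces the
    symmetry of the underlying distance matrix and ensembles the independent
    upper/lower-triangle predictions.
    """
    z = np.asarray(logits, dtype=float)
    if z.ndim != 3 or z.shape[0] != z.shape[1] or z.shape[2] != N_BINS:
        raise ValueError("logits must be L x L x 20")
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite logits")
    s = z + z.transpose(1, 0, 2)
    s = s - s.max(axis=2, keepdims=True)  # stable softmax
    e = np.exp(s)
    p = e / e.sum(axis=2, keepdims=True)
    return Distogram(p, scheme or default_bin_scheme())


def distogram_to_contacts(d: Distogram, cutoff: float = 8.0) -> ContactMap:
    """Contact probabilities by summing likelihoods of all bins wholly below
    ``cutoff`` (which must coincide with a bin edge). Diagonal forced to 0."""
    edges = d.scheme.edges
    if not np.any(np.isclose(edges, cutoff)):
        raise ValueError(f"cutoff {cutoff} is not a bin edge")
    k = int(np.searchsorted(edges, cutoff - 1e-9))  # bins [0, k) lie below
    prob = d.likelihoods[:, :, :k].sum(axis=2)
    prob = (prob + prob.T) / 2.0
    np.fill_diagonal(prob, 0.0)
    return ContactMap(np.clip(prob, 0.0, 1.0), cutoff=cutoff)


def top_contacts(c: ContactMap, n: int,
                 min_separation: int = 5) -> list[tuple[int, int, float]]:
    """Top-``n`` residue pairs (0-based i < j, probability) ranked by contact
    probability, excluding pairs with |i - j| < min_separation. Ties break
    lexicographically by (i, j) for determinism."""
    if n < 1:
        raise ValueError("n must be >= 1")
    L = c.length
    iu, ju = np.triu_indices(L, k=max(min_separation, 1))
    p = c.probabilities[iu, ju]
    order = np.lexsort((ju, iu, -p))
    order = order[: min(n, len(order))]
    return [(int(iu[k]), int(ju[k]), float(p[k])) for k in order]


def contacts_to_rr(c: ContactMap, n: int | None = None,
                   min_separation: int = 5) -> str:
    """CASP RR dialect: lines ``i j 0 8 p`` (1-based), sorted by probability
    descending."""
    n = n if n is not None else c.length * (c.length - 1) // 2
    lines = [f"{i + 1} {j + 1} 0 {c.cutoff:g} {p:.6f}"
             for i, j, p in top_contacts(c, n, min_separation=min_separation)]
    return "\n".join(lines) + ("\n" if lines else "")


def distance_error_stats(d: Distogram, native: Model,
                         max_pred: float = 15.0,
                         min_separation: int = 2) -> dict:
    """Absolute errors between the center of each pair's maximum-likelihood
    bin and the native CB-CB distance, over pairs whose max-likelihood bin
    center is below ``max_pred`` Angstroms. Returns mean, median, count."""
    if len(native) != d.length:
        raise ValueError("native length does not match distogram")
    L = d.length
    centers = d.scheme.centers
    argmax = d.likelihoods.argmax(axis=2)
    pred = centers[argmax]
    true = cb_distance_matrix(native)
    iu, ju = np.triu_indices(L, k=max(min_separation, 1))
    keep = pred[iu, ju] < max_pred
    errs = np.abs(pred[iu, ju][keep] - true[iu, ju][keep])
    if errs.size == 0:
        return {"mean": None, "median": None, "count": 0}
    return {"mean": float(errs.mean()), "median": float(np.median(errs)),
            "count": int(errs.size)}


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_distogram_tsv(d: Distogram) -> str:
    """Text container: a header line ``# distogram L edge0 ... edge20`` then
    one row per (i, j) pair (1-based) with 20 likelihood columns."""
    edges = ["inf" if math.isinf(e) else f"{e:g}" for e in d.scheme.edges]
    lines = [f"# distogram {d.length} " + " ".join(edges)]
    L = d.length
    for i in range(L):
        for j in range(L):
            vals = " ".join(f"{v:.8g}" for v in d.likelihoods[i, j])
            lines.append(f"{i + 1}\t{j + 1}\t{vals}")
    return "\n".join(lines) + "\n"


def read_distogram_tsv(text: str) -> Distogram:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    head = lines[0].split()
    if head[:2] != ["#", "distogram"]:
        raise ValueError("not a distogram container (missing header)")
    L = int(head[2])
    edges = np.array([float(x) for x in head[3:]])
    centers = (edges[:-1] + edges[1:]) / 2.0
    centers[-1] = LAST_BIN_SENTINEL_CENTER
    scheme = BinScheme(edges=edges, centers=centers)
    p = np.zeros((L, L, N_BINS))
    for ln in lines[1:]:
        parts = ln.split()
        i, j = int(parts[0]) - 1, int(parts[1]) - 1
        p[i, j] = [float(x) for x in parts[2:]]
    return Distogram(p, scheme)


def write_distogram_npz(d: Distogram, path) -> None:
    """Binary variant of the container (NumPy .npz)."""
    np.savez_compressed(path, likelihoods=d.likelihoods,
                        edges=d.scheme.edges, centers=d.scheme.centers)


def read_distogram_npz(path) -> Distogram:
    data = np.load(path)
    scheme = BinScheme(edges=data["edges"], centers=data["centers"])
    return Distogram(data["likelihoods"], scheme)


def read_distogram(source) -> Distogram:
    """Read either container variant: a text path/string (TSV) or .npz path."""
    s = str(source)
    if s.endswith(".npz"):
        return read_distogram_npz(source)
    try:
        with open(source) as fh:
            text = fh.read()
    except (OSError, ValueError):
        text = s
    return read_distogram_tsv(text)
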