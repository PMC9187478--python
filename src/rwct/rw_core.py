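"""Seeded random-walker segmentation on an intensity-weighted lattice graph.

A 2D grayscale image is mapped to a weighted graph T = (W, F): one node per
pixel, one edge per pair of lattice-adjacent pixels, with Gaussian weights

    v_ij = exp(-beta * (t_i - t_j)^2)

where t_i is the (rescaled) pixel intensity and beta controls how strongly
intensity contrast blocks the walker.  The probability that a random walker
released at pixel i reaches the seeds of label L before any other seed is a
combinatorial harmonic function: it satisfies the discrete Laplace equation
at every unseeded node with the seed assignments as Dirichlet boundary
values.  Solving one sparse symmetric positive-definite system per label
yields a per-pixel probability field; the segmentation is the per-pixel
argmax over labels.

The graph Laplacian is

    P_ij = d_i          if i == j        (d_i = sum_j v_ij)
         = -v_ij        if i adjacent j
         = 0            otherwise

and factors as B^T C B with B the signed edge-node incidence matrix and
C = diag(v); both constructions are exposed for inspection and testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, splu

# --- configuration defaults ------------------------------------------------
DEFAULT_BETA = 90.0          # on intensities rescaled to [0, 1]
WEIGHT_FLOOR = 1e-10         # keeps the graph numerically connected
DEFAULT_TOL = 1e-8           # linear-system residual target
DIRECT_SOLVE_MAX = 100_000   # unknowns above which CG replaces factorization
PROB_SUM_TOL = 1e-6          # per-pixel probability normalization tolerance


class DisconnectedSeedError(ValueError):
    """Raised when unseeded pixels have no path to any seed."""


@dataclass(frozen=True)
class GridImage:
    """A 2D grayscale raster with physical pixel spacing.

    Parameters
    ----------
    pixels
        H x W array of finite real intensities (arbitrary units or HU).
    spacing
        Physical size of one row / column step, in mm.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"image must be a non-empty 2D array, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite intensities")
        sp_ = (float(self.spacing[0]), float(self.spacing[1]))
        if sp_[0] <= 0 or sp_[1] <= 0:
            raise ValueError(f"spacing must be positive, got {sp_}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "spacing", sp_)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class SeedMap:
    """User-placed Dirichlet boundary conditions: (row, col, label) triples.

    Labels are positive integers; 0 in a raster means unseeded.  A pixel may
    appear more than once only with a consistent label.
    """

    entries: np.ndarray  # (n, 3) int array of (row, col, label)

    def __post_init__(self):
        e = np.asarray(self.entries, dtype=np.int64).reshape(-1, 3)
        if len(e) and e[:, 2].min() < 1:
            raise ValueError("seed labels must be >= 1")
        # conflicting labels on one pixel are a user error, not a tie to break
        seen: dict[tuple[int, int], int] = {}
        for r, c, lab in e:
            key = (int(r), int(c))
            if seen.setdefault(key, int(lab)) != int(lab):
                raise ValueError(f"pixel {key} carries two different labels")
        object.__setattr__(self, "entries", e)

    @classmethod
    def from_points(cls, points: Iterable[tuple[int, int, int]]) -> "SeedMap":
        return cls(np.array(list(points), dtype=np.int64).reshape(-1, 3))

    @classmethod
    def from_raster(cls, raster: np.ndarray) -> "SeedMap":
        raster = np.asarray(raster)
        rows, cols = np.nonzero(raster)
        return cls(np.column_stack([rows, cols, raster[rows, cols]]).astype(np.int64))

    @classmethod
    def from_csv(cls, path) -> "SeedMap":
        df = pd.read_csv(path)
        expected = {"row", "col", "label"}
        if not expected.issubset(df.columns):
            raise ValueError(f"seed CSV needs columns {sorted(expected)}, got {list(df.columns)}")
        return cls(df[["row", "col", "label"]].to_numpy(dtype=np.int64))

    @property
    def labels(self) -> np.ndarray:
        """Sorted unique seed labels."""
        return np.unique(self.entries[:, 2])

    def validate_shape(self, shape: tuple[int, int]) -> None:
        e = self.entries
        if len(e) == 0:
            raise ValueError("seed map is empty")
        if (e[:, 0] < 0).any() or (e[:, 1] < 0).any() or \
           (e[:, 0] >= shape[0]).any() or (e[:, 1] >= shape[1]).any():
            raise ValueError("seed coordinates fall outside the image")

    def flat_indices(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Row-major pixel indices (i = row*W + col) and their labels."""
        self.validate_shape(shape)
        idx = self.entries[:, 0] * shape[1] + self.entries[:, 1]
        idx, keep = np.unique(idx, return_index=True)
        return idx, self.entries[keep, 2]

    def to_raster(self, shape: tuple[int, int]) -> np.ndarray:
        self.validate_shape(shape)
        out = np.zeros(shape, dtype=np.int64)
        out[self.entries[:, 0], self.entries[:, 1]] = self.entries[:, 2]
        return out


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected lattice graph with Gaussian edge weights in (0, 1]."""

    n_nodes: int
    edges: np.ndarray    # (E, 2), i < j, lattice-adjacent pixel indices
    weights: np.ndarray  # (E,) in (0, 1]
    beta: float
    shape: tuple[int, int]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if (w <= 0).any() or (w > 1).any():
            raise ValueError("edge weights must lie in (0, 1]")
        object.__setattr__(self, "weights", w)


def lattice_edges(shape: tuple[int, int], connectivity: int = 4) -> np.ndarray:
    """Edges of the pixel lattice in row-major indexing, each as (i, j), i < j."""
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pairs = [
        np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()]),   # horizontal
        np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()]),   # vertical
    ]
    if connectivity == 8:
        pairs.append(np.column_stack([idx[:-1, :-1].ravel(), idx[1:, 1:].ravel()]))
        pairs.append(np.column_stack([idx[:-1, 1:].ravel(), idx[1:, :-1].ravel()]))
    return np.vstack(pairs) if pairs else np.empty((0, 2), dtype=np.int64)


def rescale_intensities(pixels: np.ndarray) -> np.ndarray:
    """Affine map to [0, 1]; a constant image maps to all zeros."""
    lo, hi = float(pixels.min()), float(pixels.max())
    if hi == lo:
        return np.zeros_like(pixels)
    return (pixels - lo) / (hi - lo)


def compute_edge_weights(
    image: GridImage,
    beta: float = DEFAULT_BETA,
    connectivity: int = 4,
    rescale: bool = True,
    weight_floor: float = WEIGHT_FLOOR,
) -> WeightedGraph:
    """Gaussian edge weights v_ij = max(floor, exp(-beta (t_i - t_j)^2)).

    By default intensities are first rescaled to [0, 1] so that ``beta`` is
    image-scale-free; pass ``rescale=False`` to apply the weights to raw
    intensities.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    t = rescale_intensities(image.pixels) if rescale else image.pixels
    flat = t.ravel()
    edges = lattice_edges(image.shape, connectivity)
    diff = flat[edges[:, 0]] - flat[edges[:, 1]]
    weights = np.maximum(weight_floor, np.exp(-beta * diff * diff))
    return WeightedGraph(
        n_nodes=image.pixels.size, edges=edges, weights=weights,
        beta=float(beta), shape=image.shape,
    )


def build_laplacian(graph: WeightedGraph) -> sp.csr_matrix:
    """Sparse graph Laplacian: degree on the diagonal, -v_ij off-diagonal."""
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    w = graph.weights
    n = graph.n_nodes
    rows = np.concatenate([i, j])
    cols = np.concatenate([j, i])
    data = np.concatenate([-w, -w])
    lap = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    lap.setdiag(-np.asarray(lap.sum(axis=1)).ravel())
    return lap.tocsr()


def build_incidence(graph: WeightedGraph) -> sp.csr_matrix:
    """Signed edge-node incidence matrix B: +1 at the lower pixel index, -1 at
    the higher, so that B^T diag(v) B reproduces the Laplacian."""
    e = len(graph.edges)
    rows = np.repeat(np.arange(e), 2)
    cols = graph.edges.ravel()
    data = np.tile([1.0, -1.0], e)
    return sp.coo_matrix((data, (rows, cols)), shape=(e, graph.n_nodes)).tocsr()


@dataclass(frozen=True)
class ProbabilityField:
    """Per-pixel label probabilities from the harmonic (Dirichlet) solve."""

    probabilities: np.ndarray  # (n_nodes, K), rows sum to 1
    labels: np.ndarray         # (K,) the seeded labels, ascending
    shape: tuple[int, int]
    residual: float
    tol: float

    def image(self, label: int) -> np.ndarray:
        """H x W probability map for one label."""
        k = int(np.nonzero(self.labels == label)[0][0])
        return self.probabilities[:, k].reshape(self.shape)

    def argmax_mask(self) -> np.ndarray:
        """Per-pixel argmax labeling; ties go to the smallest label index."""
        # labels are ascending and np.argmax returns the first maximum
        return self.labels[np.argmax(self.probabilities, axis=1)].reshape(self.shape)


def _check_connectivity(lap: sp.csr_matrix, seed_idx: np.ndarray) -> None:
    adj = sp.triu(-lap, k=1)
    adj.data = np.abs(adj.data)
    n_comp, comp = connected_components(adj, directed=False)
    seeded_comps = set(comp[seed_idx].tolist())
    for c in range(n_comp):
        if c not in seeded_comps:
            members = np.nonzero(comp == c)[0]
            head = ", ".join(map(str, members[:10]))
            raise DisconnectedSeedError(
                f"component of {len(members)} unseeded pixel(s) unreachable from any "
                f"seed (pixel indices: {head}{'...' if len(members) > 10 else ''})"
            )


def solve_dirichlet(
    lap: sp.csr_matrix,
    seeds: SeedMap,
    shape: tuple[int, int],
    tol: float = DEFAULT_TOL,
) -> ProbabilityField:
    """Solve the seeded Dirichlet problem on the weighted graph.

    For each label L the potential is fixed at 1 on L's seeds and 0 on all
    other seeds, and harmonic (discrete Laplace equation) at unseeded nodes:
    with the Laplacian partitioned into seeded (s) and unseeded (u) blocks,

        L_uu x_u = -L_us b_s

    is solved per label.  K - 1 systems are solved explicitly and the last
    label takes the complement, so probabilities sum to exactly 1.
    """
    n = lap.shape[0]
    seed_idx, seed_labels = seeds.flat_indices(shape)
    labels = np.unique(seed_labels)
    if len(labels) < 2:
        raise ValueError(f"need seeds for at least two labels, got {len(labels)}")
    _check_connectivity(lap, seed_idx)

    unseeded = np.setdiff1d(np.arange(n), seed_idx, assume_unique=False)
    probs = np.zeros((n, len(labels)))
    residual = 0.0

    lap_csc = lap.tocsc()
    l_uu = lap_csc[unseeded][:, unseeded]
    l_us = lap_csc[unseeded][:, seed_idx]
    solver = None
    if len(unseeded):
        if len(unseeded) <= DIRECT_SOLVE_MAX:
            solver = splu(l_uu.tocsc())

    for k, lab in enumerate(labels[:-1]):
        b = (seed_labels == lab).astype(np.float64)
        probs[seed_idx, k] = b
        if len(unseeded):
            rhs = -l_us @ b
            if solver is not None:
                x = solver.solve(rhs)
                # one step of iterative refinement tightens the residual
                x += solver.solve(rhs - l_uu @ x)
            else:
                x, info = cg(l_uu, rhs, rtol=tol, atol=tol)
                if info != 0:
                    raise RuntimeError(f"conjugate gradient failed to converge (info={info})")
            residual = max(residual, float(np.max(np.abs(l_uu @ x - rhs), initial=0.0)))
            probs[unseeded, k] = x
    probs[:, -1] = 1.0 - probs[:, :-1].sum(axis=1)
    np.clip(probs, 0.0, 1.0, out=probs)  # shave numerical over/undershoot
    # seeds are exactly one-hot
    probs[seed_idx] = 0.0
    probs[seed_idx, np.searchsorted(labels, seed_labels)] = 1.0
    return ProbabilityField(
        probabilities=probs, labels=labels, shape=shape,
        residual=residual, tol=float(tol),
    )


def rw_segment(
    image: GridImage,
    seeds: SeedMap,
    beta: float = DEFAULT_BETA,
    connectivity: int = 4,
    rescale: bool = True,
    tol: float = DEFAULT_TOL,
) -> tuple[np.ndarray, ProbabilityField]:
    """Full random-walker segmentation: graph -> Laplacian -> harmonic solve
    -> per-pixel argmax.  Deterministic; seeded pixels keep their labels."""
    graph = compute_edge_weights(image, beta=beta, connectivity=connectivity, rescale=rescale)
    lap = build_laplacian(graph)
    prob = solve_dirichlet(lap, seeds, image.shape, tol=tol)
    return prob.argmax_mask(), prob
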