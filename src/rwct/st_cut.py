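"""Terminal-graph (s-t) minimum cut and the hybrid random-walker + cut segmenter.

The pixel graph is augmented with two terminals: a source Q (foreground) and
a sink I (background), W = P ∪ {Q, I}.  Edges split into n-links N (the
lattice edges, with capacity lambda_n * v_ij) and t-links joining every pixel
to both terminals.  T-link capacities are negative log-likelihoods: the link
to Q carries -log p(background) and the link to I carries -log p(foreground),
so that cutting a pixel away from its likely terminal is expensive.  Seed
pixels are hard-linked (capacity C_max to their terminal, 0 to the other).
The minimum-weight Q/I cut — equal, by duality, to the maximum flow — yields
the segmentation.

The hybrid segmenter feeds the random-walker posterior probabilities into
the t-links; a pure-cut mode uses seed-intensity histogram likelihoods
instead.  As lambda_n -> 0 the t-links dominate and the cut reduces to the
per-pixel argmax of the probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .rw_core import (
    DEFAULT_BETA,
    DEFAULT_TOL,
    GridImage,
    SeedMap,
    WeightedGraph,
    compute_edge_weights,
    rescale_intensities,
    rw_segment,
)

C_MAX = 1e9        # "hard" t-link capacity for seeds
PROB_CLIP = 1e-9   # probabilities clipped away from 0/1 before the log
DEFAULT_LAMBDA_N = 1.0


@dataclass(frozen=True)
class TerminalGraph:
    """Pixel s-t graph: n-links plus per-pixel source/sink t-links."""

    n_pixels: int
    edges: np.ndarray        # (E, 2) pixel-pixel n-links
    n_caps: np.ndarray       # (E,) capacities lambda_n * v_ij
    source_caps: np.ndarray  # (n,) pixel -> Q
    sink_caps: np.ndarray    # (n,) pixel -> I
    shape: tuple[int, int]

    def __post_init__(self):
        for caps in (self.n_caps, self.source_caps, self.sink_caps):
            if (np.asarray(caps) < 0).any():
                raise ValueError("capacities must be nonnegative")


@dataclass(frozen=True)
class CutResult:
    foreground: np.ndarray  # (n,) bool, True = source (Q) side
    cut_value: float        # sum of capacities crossing the partition
    flow_value: float       # maximum flow (equals cut_value by duality)


def histogram_prior(
    image: GridImage,
    seeds: SeedMap,
    fg_label: int,
    bins: int = 32,
) -> np.ndarray:
    """Foreground probability per pixel from seed-intensity histograms.

    Intensities are rescaled to [0, 1] and binned; seed pixels of the
    foreground label versus all other seeds define two Laplace-smoothed
    histograms whose normalized ratio is the per-pixel foreground prior.
    """
    t = rescale_intensities(image.pixels)
    seed_idx, seed_labels = seeds.flat_indices(image.shape)
    vals = t.ravel()[seed_idx]
    is_fg = seed_labels == fg_label
    if not is_fg.any() or is_fg.all():
        raise ValueError("histogram prior needs seeds both for and against the foreground label")
    edges = np.linspace(0.0, 1.0, bins + 1)
    h_fg, _ = np.histogram(vals[is_fg], bins=edges)
    h_bg, _ = np.histogram(vals[~is_fg], bins=edges)
    # likelihood ratio with add-one smoothing, normalized per bin
    lf = (h_fg + 1.0) / (h_fg.sum() + bins)
    lb = (h_bg + 1.0) / (h_bg.sum() + bins)
    post = lf / (lf + lb)
    which = np.clip(np.digitize(t.ravel(), edges) - 1, 0, bins - 1)
    return post[which].reshape(image.shape)


def build_terminal_graph(
    image: GridImage,
    fg_prob: np.ndarray,
    seeds: SeedMap,
    fg_label: int,
    lambda_n: float = DEFAULT_LAMBDA_N,
    beta: float = DEFAULT_BETA,
    connectivity: int = 4,
    graph: WeightedGraph | None = None,
    c_max: float = C_MAX,
    prob_clip: float = PROB_CLIP,
) -> TerminalGraph:
    """Assemble the s-t graph from a foreground probability map.

    T-link capacities are -log of the opposite-class probability, clipped to
    [0, c_max]; n-links scale the Gaussian lattice weights by lambda_n.
    """
    if lambda_n < 0:
        raise ValueError(f"lambda_n must be >= 0, got {lambda_n}")
    p = np.clip(np.asarray(fg_prob, dtype=np.float64).ravel(), prob_clip, 1.0 - prob_clip)
    if p.size != image.pixels.size:
        raise ValueError("probability map shape does not match the image")
    source_caps = np.clip(-np.log(1.0 - p), 0.0, c_max)  # cost of cutting away from Q
    sink_caps = np.clip(-np.log(p), 0.0, c_max)
    seed_idx, seed_labels = seeds.flat_indices(image.shape)
    is_fg = seed_labels == fg_label
    source_caps[seed_idx[is_fg]] = c_max
    sink_caps[seed_idx[is_fg]] = 0.0
    source_caps[seed_idx[~is_fg]] = 0.0
    sink_caps[seed_idx[~is_fg]] = c_max
    if graph is None:
        graph = compute_edge_weights(image, beta=beta, connectivity=connectivity)
    return TerminalGraph(
        n_pixels=image.pixels.size,
        edges=graph.edges,
        n_caps=lambda_n * graph.weights,
        source_caps=source_caps,
        sink_caps=sink_caps,
        shape=image.shape,
    )


def min_cut(tg: TerminalGraph) -> CutResult:
    """Exact minimum Q/I cut via maximum flow.

    Returns the source-side indicator, the cut value recomputed from the
    partition, and the max-flow value (which must agree by duality).
    """
    g = nx.DiGraph()
    g.add_nodes_from(range(tg.n_pixels))
    g.add_node("Q")
    g.add_node("I")

    def add_cap(u, v, cap):
        # parallel edges accumulate capacity
        if g.has_edge(u, v):
            g[u][v]["capacity"] += cap
        else:
            g.add_edge(u, v, capacity=cap)

    for px in range(tg.n_pixels):
        if tg.source_caps[px] > 0:
            add_cap("Q", px, float(tg.source_caps[px]))
        if tg.sink_caps[px] > 0:
            add_cap(px, "I", float(tg.sink_caps[px]))
    for (i, j), cap in zip(tg.edges, tg.n_caps):
        if cap > 0:
            add_cap(int(i), int(j), float(cap))
            add_cap(int(j), int(i), float(cap))
    flow_value, (q_side, _) = nx.minimum_cut(g, "Q", "I")
    fg = np.zeros(tg.n_pixels, dtype=bool)
    fg[[n for n in q_side if n != "Q"]] = True
    cut_value = cut_cost(tg, fg)
    return CutResult(foreground=fg, cut_value=cut_value, flow_value=float(flow_value))


def cut_cost(tg: TerminalGraph, foreground: np.ndarray) -> float:
    """Total capacity crossing a given Q/I partition (Q-side = foreground)."""
    fg = np.asarray(foreground, dtype=bool)
    cost = float(tg.source_caps[~fg].sum()) + float(tg.sink_caps[fg].sum())
    crossing = fg[tg.edges[:, 0]] != fg[tg.edges[:, 1]]
    return cost + float(tg.n_caps[crossing].sum())


def rwct_segment(
    image: GridImage,
    seeds: SeedMap,
    beta: float = DEFAULT_BETA,
    lambda_n: float = DEFAULT_LAMBDA_N,
    connectivity: int = 4,
    mode: str = "hybrid",
    tol: float = DEFAULT_TOL,
) -> np.ndarray:
    """Hybrid random-walker + minimum-cut segmentation.

    Modes
    -----
    ``"rw"``      random-walker argmax only (no cut stage).
    ``"hybrid"``  random-walker posteriors feed the t-links of a minimum cut.
    ``"cut"``     seed-histogram likelihoods feed the t-links (no walker).

    Multi-label inputs are handled one-vs-rest in ascending label order; a
    pixel claimed by several cuts takes the smallest label, and a pixel
    claimed by none falls back to the probability argmax.
    """
    if mode not in ("rw", "hybrid", "cut"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = seeds.labels
    if mode == "rw":
        mask, _ = rw_segment(image, seeds, beta=beta, connectivity=connectivity, tol=tol)
        return mask

    graph = compute_edge_weights(image, beta=beta, connectivity=connectivity)
    if mode == "hybrid":
        _, prob = rw_segment(image, seeds, beta=beta, connectivity=connectivity, tol=tol)

    def fg_probability(lab: int) -> np.ndarray:
        if mode == "hybrid":
            return prob.image(lab)
        return histogram_prior(image, seeds, lab)

    if len(labels) == 2:
        tg = build_terminal_graph(
            image, fg_probability(labels[0]), seeds, labels[0],
            lambda_n=lambda_n, graph=graph,
        )
        res = min_cut(tg)
        mask = np.where(res.foreground, labels[0], labels[1]).reshape(image.shape)
        return mask.astype(np.int64)

    claims = np.full(image.pixels.size, 0, dtype=np.int64)
    for lab in labels:  # ascending: first claim wins -> smallest label
        tg = build_terminal_graph(
            image, fg_probability(lab), seeds, lab, lambda_n=lambda_n, graph=graph,
        )
        res = min_cut(tg)
        take = res.foreground & (claims == 0)
        claims[take] = lab
    if (claims == 0).any():
        if mode == "hybrid":
            fallback = prob.argmax_mask().ravel()
        else:
            fallback = np.stack([fg_probability(l).ravel() for l in labels])
            fallback = labels[np.argmax(fallback, axis=0)]
        claims[claims == 0] = fallback[claims == 0]
    return claims.reshape(image.shape)
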