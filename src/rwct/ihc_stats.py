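"""Immunohistochemistry scoring and nonparametric group comparison.

Covers the quantitative readout of stained slides and the rank statistics
used to compare treatment groups:

* positive-cell fraction and the ordinal immunohistochemical score (IHS),
  the product of a staining-intensity category (0-3) and a positive-cell
  proportion category (0-4), giving scores in 0..12;
* exhaustive reconstruction of integer score vectors from published
  mean ± SD summaries (small n makes enumeration over all multisets exact);
* the tie-corrected Kruskal-Wallis H test on pooled average ranks,
  H = [12/(N(N+1)) Σ R_g²/n_g − 3(N+1)] / C with C = 1 − Σ(t³−t)/(N³−N);
* Dunn's post-hoc pairwise comparison: pooled mean-rank difference D with
  tie-adjusted standard error
  SE = sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)),
  z = D/SE, two-sided normal p, Bonferroni-adjusted over m = k(k−1)/2 pairs.

Note on published tables in this problem area: pairwise Dunn rank
differences are sometimes printed under the symbol "H", which they are not —
a two-group Kruskal-Wallis H for n = 5 + 5 cannot exceed ~6.8, while mean-
rank differences easily do.  This module labels the quantity D throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

IHS_MAX = 12  # 3 (intensity) x 4 (proportion)


# --- cell-level readout ----------------------------------------------------

def positive_fraction(cells: pd.DataFrame) -> float:
    """Fraction of cells flagged positive in a per-cell table."""
    if len(cells) == 0:
        raise ValueError("cell table is empty")
    return float(np.asarray(cells["positive"], dtype=bool).mean())


def proportion_category(fraction: float) -> int:
    """Positive-cell proportion category 0-4 (<5%, 5-25%, 25-50%, 50-75%, >75%)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {fraction}")
    if fraction < 0.05:
        return 0
    for cat, hi in enumerate((0.25, 0.50, 0.75), start=1):
        if fraction <= hi:
            return cat
    return 4


def ihs(intensity_cat: int, proportion_cat: int, convention: str = "product") -> int:
    """Combine intensity (0-3) and proportion (0-4) categories into the IHS.

    The default product convention spans 0-12; the additive convention
    (0-7) is selectable for labs that sum the two categories.
    """
    if not (0 <= intensity_cat <= 3 and 0 <= proportion_cat <= 4):
        raise ValueError(
            f"categories out of range: intensity {intensity_cat}, proportion {proportion_cat}"
        )
    if convention == "product":
        return intensity_cat * proportion_cat
    if convention == "sum":
        return intensity_cat + proportion_cat
    raise ValueError(f"unknown IHS convention {convention!r}")


# --- reconstruction of raw scores from printed summaries -------------------

@dataclass(frozen=True)
class ScoreSummary:
    """A published group summary: mean ± sample SD (divisor n−1) for n scores."""

    mean: float
    sd: float
    n: int
    mean_decimals: int = 2
    sd_decimals: int = 3

    def __post_init__(self):
        if self.sd < 0 or self.n < 1:
            raise ValueError("invalid summary")


def _rounds_to(value: float, printed: float, decimals: int) -> bool:
    return abs(value - printed) <= 0.5 * 10.0 ** (-decimals) + 1e-12


def reconstruct_scores(summary: ScoreSummary, lo: int = 0, hi: int = IHS_MAX) -> list[tuple[int, ...]]:
    """All multisets of n integers in [lo, hi] whose mean and sample SD round
    to the printed summary at its printed precision.  Exhaustive; returns an
    empty list (not an error) when nothing matches."""
    out = []
    for combo in itertools.combinations_with_replacement(range(lo, hi + 1), summary.n):
        arr = np.array(combo, dtype=float)
        m = arr.mean()
        if not _rounds_to(m, summary.mean, summary.mean_decimals):
            continue
        s = arr.std(ddof=1) if summary.n > 1 else 0.0
        if _rounds_to(s, summary.sd, summary.sd_decimals):
            out.append(combo)
    return out


# --- rank machinery --------------------------------------------------------

def _pooled_ranks(groups: Mapping[str, Sequence[float]]):
    names = list(groups)
    sizes = [len(groups[g]) for g in names]
    if any(s == 0 for s in sizes):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    ranks = rankdata(pooled, method="average")
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return names, dict(zip(names, split)), pooled, ranks


def _tie_term(pooled: np.ndarray) -> float:
    """Σ(t³ − t) over tie groups of the pooled sample."""
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


@dataclass(frozen=True)
class KwResult:
    h: float                 # tie-corrected statistic
    h_uncorrected: float
    tie_correction: float    # C = 1 − Σ(t³−t)/(N³−N)
    df: int
    p_value: float
    mean_ranks: dict
    n_total: int


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> KwResult:
    """Tie-corrected Kruskal-Wallis test over k ≥ 2 groups.

    If every pooled observation is tied the statistic is 0 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    names, rank_groups, pooled, _ = _pooled_ranks(groups)
    n = len(pooled)
    rank_sums = {g: float(r.sum()) for g, r in rank_groups.items()}
    mean_ranks = {g: rank_sums[g] / len(rank_groups[g]) for g in names}
    h_unc = 12.0 / (n * (n + 1)) * sum(
        rank_sums[g] ** 2 / len(rank_groups[g]) for g in names
    ) - 3.0 * (n + 1)
    c = 1.0 - _tie_term(pooled) / (n**3 - n)
    h = 0.0 if c <= 0.0 else h_unc / c
    h = max(h, 0.0)
    df = len(groups) - 1
    return KwResult(
        h=h, h_uncorrected=max(h_unc, 0.0), tie_correction=max(c, 0.0), df=df,
        p_value=float(chi2.sf(h, df)), mean_ranks=mean_ranks, n_total=n,
    )


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    d: float          # |mean rank difference|
    d_signed: float   # mean_rank(i) − mean_rank(j)
    se: float
    z: float
    p_value: float
    p_adjusted: float
    m: int


def dunn_pairwise(
    groups: Mapping[str, Sequence[float]],
    pair: tuple[str, str],
    m: int | None = None,
) -> PairwiseResult:
    """Dunn's post-hoc comparison of one pair, ranked jointly over all groups.

    Ranks are pooled over *all* k groups (no pairwise re-ranking); the
    Bonferroni factor m defaults to k(k−1)/2.
    """
    gi, gj = pair
    if gi not in groups or gj not in groups:
        raise ValueError(f"pair {pair} not among groups {list(groups)}")
    names, rank_groups, pooled, _ = _pooled_ranks(groups)
    n = len(pooled)
    if m is None:
        m = len(groups) * (len(groups) - 1) // 2
    mean_i = float(rank_groups[gi].mean())
    mean_j = float(rank_groups[gj].mean())
    d_signed = mean_i - mean_j
    se = np.sqrt(
        (n * (n + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n - 1)))
        * (1.0 / len(rank_groups[gi]) + 1.0 / len(rank_groups[gj]))
    )
    z = abs(d_signed) / se if se > 0 else np.inf
    p = float(2.0 * norm.sf(z))
    return PairwiseResult(
        pair=(gi, gj), d=abs(d_signed), d_signed=d_signed, se=float(se),
        z=float(z), p_value=p, p_adjusted=min(1.0, m * p), m=m,
    )


def all_pairwise(groups: Mapping[str, Sequence[float]]) -> list[PairwiseResult]:
    """Dunn comparisons for every unordered pair, Bonferroni over all of them."""
    names = list(groups)
    m = len(names) * (len(names) - 1) // 2
    return [
        dunn_pairwise(groups, (a, b), m=m)
        for a, b in itertools.combinations(names, 2)
    ]


def rank_order(groups: Mapping[str, Sequence[float]]) -> tuple[list[str], bool]:
    """Group names by mean score, descending; ties broken alphabetically.

    Returns (ordering, had_ties).
    """
    if not groups:
        raise ValueError("no groups")
    means = {g: float(np.mean(groups[g])) for g in groups}
    ordering = sorted(means, key=lambda g: (-means[g], g))
    vals = sorted(means.values())
    had_ties = len(set(vals)) < len(vals)
    return ordering, had_ties


# --- joint reconstruction selection ----------------------------------------

class ReconstructionError(ValueError):
    """Raised when printed statistics admit zero or several reconstructions."""


def _rank_signature(groups: Mapping[str, tuple]) -> tuple:
    """Canonical form of the pooled rank structure: per-group sorted ranks."""
    names, rank_groups, _, _ = _pooled_ranks(groups)
    return tuple((g, tuple(np.round(np.sort(rank_groups[g]), 9))) for g in sorted(names))


def select_joint_reconstruction(
    candidates: Mapping[str, Sequence[tuple[int, ...]]],
    printed_h: float,
    printed_d: Mapping[tuple[str, str], float],
    decimals: int = 3,
) -> dict[str, tuple[int, ...]]:
    """Pick the joint score assignment consistent with the published statistics.

    Over the Cartesian product of per-group candidate multisets, keep
    assignments whose tie-corrected H and every supplied pairwise mean-rank
    difference reproduce the printed values at the printed precision.  The
    surviving assignments must be unique up to rank-equivalence (identical
    pooled rank structure); otherwise an error lists them all.
    """
    names = list(candidates)
    for g in names:
        if not candidates[g]:
            raise ReconstructionError(f"group {g!r} has no candidate reconstructions")
    consistent = []
    for combo in itertools.product(*(candidates[g] for g in names)):
        groups = dict(zip(names, combo))
        kw = kruskal_wallis(groups)
        if not _rounds_to(kw.h, printed_h, decimals):
            continue
        ok = True
        for (gi, gj), target in printed_d.items():
            res = dunn_pairwise(groups, (gi, gj))
            if not _rounds_to(res.d, target, decimals):
                ok = False
                break
        if ok:
            consistent.append(groups)
    if not consistent:
        raise ReconstructionError(
            f"no joint assignment reproduces H={printed_h} and {printed_d}"
        )
    by_signature = {}
    for groups in consistent:
        by_signature.setdefault(_rank_signature(groups), groups)
    if len(by_signature) > 1:
        listing = "; ".join(str({g: v for g, v in grp.items()}) for grp in by_signature.values())
        raise ReconstructionError(
            f"{len(by_signature)} rank-inequivalent assignments are consistent: {listing}"
        )
    # deterministic representative: lexicographically smallest assignment
    consistent.sort(key=lambda grp: tuple(grp[g] for g in names))
    return consistent[0]
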