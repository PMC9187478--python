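"""Packaged published group summaries and their printed statistics.

Three immunohistochemistry markers (HIF-1α, VEGF, VEGFR-2) were each scored
in four treatment groups of n = 5 animals — M (model control), W (Symbicort),
C (Spiriva), C+W (combination) — and published only as mean ± SD per group
together with the overall tie-corrected Kruskal-Wallis H and a subset of
pairwise Dunn mean-rank differences (printed under the symbol "H").  These
summaries are the packaged input fixtures; the raw integer score vectors are
recovered at run time by exhaustive reconstruction
(:func:`rwct.ihc_stats.reconstruct_scores`) filtered against the printed
statistics (:func:`rwct.ihc_stats.select_joint_reconstruction`).
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

from .ihc_stats import ScoreSummary, reconstruct_scores, select_joint_reconstruction

GROUPS = ("M", "W", "C", "C+W")

# mean, sd, n per group, with the precision each value was printed at
PACKAGED_SUMMARIES: dict[str, dict[str, ScoreSummary]] = {
    "hif1a": {
        "M": ScoreSummary(6.00, 0.00, 5, sd_decimals=2),
        "W": ScoreSummary(4.00, 0.00, 5, sd_decimals=2),
        "C": ScoreSummary(5.60, 0.894, 5),
        "C+W": ScoreSummary(3.20, 1.095, 5),
    },
    "vegf": {
        "M": ScoreSummary(6.00, 0.00, 5, sd_decimals=2),
        "W": ScoreSummary(3.60, 0.894, 5),
        "C": ScoreSummary(4.40, 0.894, 5),
        "C+W": ScoreSummary(1.60, 0.548, 5),
    },
    "vegfr2": {
        "M": ScoreSummary(6.00, 0.00, 5, sd_decimals=2),
        "W": ScoreSummary(3.60, 0.894, 5),
        "C": ScoreSummary(4.80, 1.095, 5),
        "C+W": ScoreSummary(2.20, 1.095, 5),
    },
}

# published overall tie-corrected H per marker
PRINTED_H: dict[str, float] = {"hif1a": 15.472, "vegf": 16.505, "vegfr2": 14.617}

# published pairwise mean-rank differences (printed as "H" in the source tables)
PRINTED_D: dict[str, dict[tuple[str, str], float]] = {
    "hif1a": {
        ("C+W", "C"): 9.400,
        ("C+W", "M"): 11.200,
        ("W", "M"): 9.000,
        ("C+W", "W"): 2.200,
        ("W", "C"): 7.200,
        ("C", "M"): 1.800,
    },
    "vegf": {
        ("C+W", "M"): 14.200,
        ("C+W", "W"): 6.000,
        ("C+W", "C"): 8.600,
        ("W", "C"): 2.600,
        ("W", "M"): 8.200,
        ("C", "M"): 5.600,
    },
    "vegfr2": {
        ("C+W", "M"): 12.800,
    },
}

# published Bonferroni-adjusted p-values (3 dp) for the fully reported marker
PRINTED_ADJ_P: dict[str, dict[tuple[str, str], float]] = {
    "hif1a": {
        ("C+W", "C"): 0.033,
        ("C+W", "M"): 0.006,
        ("W", "M"): 0.047,
        ("C+W", "W"): 1.000,
        ("W", "C"): 0.201,
        ("C", "M"): 1.000,
    },
}

MARKERS = tuple(PACKAGED_SUMMARIES)


def candidate_scores(marker: str) -> dict[str, list[tuple[int, ...]]]:
    """Exhaustive per-group reconstruction candidates for one marker."""
    if marker not in PACKAGED_SUMMARIES:
        raise KeyError(f"unknown marker {marker!r}; choose from {MARKERS}")
    return {g: reconstruct_scores(s) for g, s in PACKAGED_SUMMARIES[marker].items()}


def packaged_group_scores(marker: str) -> dict[str, tuple[int, ...]]:
    """The unique joint score reconstruction for one marker, recomputed from
    the packaged summaries and printed statistics (nothing hard-coded)."""
    return select_joint_reconstruction(
        candidate_scores(marker), PRINTED_H[marker], PRINTED_D[marker]
    )


def summary_table(marker: str) -> pd.DataFrame:
    """The packaged summary as a tidy DataFrame (columns group/mean/sd/n)."""
    rows = [
        dict(group=g, mean=s.mean, sd=s.sd, n=s.n)
        for g, s in PACKAGED_SUMMARIES[marker].items()
    ]
    return pd.DataFrame(rows)


def summary_csv(marker: str) -> str:
    """The packaged summary in the CSV dialect the CLI accepts."""
    buf = StringIO()
    summary_table(marker).to_csv(buf, index=False)
    return buf.getvalue()
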