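"""Spot-level spatial colocalization of interacting gene pairs.

Spots pass QC on total counts, mitochondrial fraction and gene
complexity; a fixed-radius neighbor graph (self-inclusive, so same-spot
co-expression counts) supports a colocalization score per gene pair,
which is compared against a null built by randomly re-pairing the same
proteins, followed by ANOVA + Tukey HSD group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .screen import _pair_key
from .synthetic import SpotGrid

__all__ = [
    "QCReport",
    "qc_spots",
    "neighbor_graph",
    "colocalization_score",
    "permuted_pairs",
    "permuted_null",
    "compare_groups",
]


@dataclass
class QCReport:
    n_spots_in: int
    n_spots_kept: int
    n_genes_in: int
    n_genes_kept: int


def qc_spots(
    grid: SpotGrid,
    min_counts: int = 4000,
    max_counts: int = 36000,
    max_mito_fraction: float = 0.20,
    min_genes_per_spot: int = 2000,
    min_spots_per_gene: int = 5,
) -> tuple[SpotGrid, QCReport]:
    """Filter spots and genes by the standard QC bounds.

    Spots must have total counts within [min_counts, max_counts], a
    mitochondrial read fraction strictly below ``max_mito_fraction`` and
    at least ``min_genes_per_spot`` distinct genes detected; genes must be
    detected in at least ``min_spots_per_gene`` spots (applied after spot
    filtering).
    """
    counts = grid.counts
    totals = counts.sum(axis=1)
    mito_cols = [g for g in counts.columns if g in grid.mito_genes]
    mito_frac = counts[mito_cols].sum(axis=1) / totals.replace(0, np.nan)
    mito_frac = mito_frac.fillna(0.0)
    n_genes = (counts > 0).sum(axis=1)
    keep_spots = (
        (totals >= min_counts)
        & (totals <= max_counts)
        & (mito_frac < max_mito_fraction)
        & (n_genes >= min_genes_per_spot)
    )
    counts = counts.loc[keep_spots]
    spots = grid.spots.loc[keep_spots]
    gene_spots = (counts > 0).sum(axis=0)
    keep_genes = gene_spots >= min_spots_per_gene
    counts = counts.loc[:, keep_genes]
    if counts.empty or counts.shape[1] == 0:
        raise ValueError("QC removed all spots or all genes")
    report = QCReport(
        n_spots_in=len(grid.counts),
        n_spots_kept=len(counts),
        n_genes_in=grid.counts.shape[1],
        n_genes_kept=counts.shape[1],
    )
    filtered = SpotGrid(spots=spots, counts=counts, mito_genes=set(grid.mito_genes) & set(counts.columns))
    return filtered, report


def neighbor_graph(grid: SpotGrid, radius: float = 150.0) -> list[tuple[int, int]]:
    """Self-inclusive neighbor pairings within ``radius`` (ties included).

    Returns unordered spot-index pairings (i, j) with i <= j; every spot
    is paired with itself, so same-spot co-expression participates in the
    colocalization tabulation.
    """
    xy = grid.spots[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    out = [(int(i), int(i)) for i in range(len(xy))]
    out.extend((int(min(i, j)), int(max(i, j))) for i, j in pairs)
    return sorted(out)


def colocalization_score(
    grid: SpotGrid,
    graph: list[tuple[int, int]],
    pair: tuple[str, str],
    denominator: str = "expressing",
) -> float:
    """Fraction of neighbor pairings that are interaction-capable.

    A pairing (s, t) is interaction-capable when one member expresses
    (>= 1 count) gene p and the other gene q; a self-pairing requires the
    spot to express both.  ``denominator`` selects the normalization:
    "expressing" (default) counts pairings where both members express at
    least one of {p, q}; "all" counts every neighbor pairing.  Either
    gene absent from the grid gives 0.
    """
    p, q = pair
    cols = grid.counts.columns
    if p not in cols or q not in cols:
        return 0.0
    has_p = (grid.counts[p].to_numpy() >= 1)
    has_q = (grid.counts[q].to_numpy() >= 1)
    has_any = has_p | has_q
    num = 0
    den = 0
    for i, j in graph:
        capable = (has_p[i] and has_q[j]) or (has_q[i] and has_p[j])
        if denominator == "all":
            den += 1
        elif denominator == "expressing":
            if has_any[i] and has_any[j]:
                den += 1
        else:
            raise ValueError(f"unknown denominator mode: {denominator!r}")
        if capable:
            num += 1
    if den == 0:
        return 0.0
    return num / den


def permuted_pairs(
    pairs: list[tuple[str, str]],
    rng: np.random.Generator,
    max_tries: int = 1000,
) -> list[tuple[str, str]]:
    """Randomly re-pair the proteins of an edge list, avoiding original edges.

    The right-hand members are permuted against the left-hand members;
    draws are rejected while any re-paired edge reproduces an original
    edge or pairs a protein with itself (unless it was already
    homophilic).
    """
    if len(pairs) < 2:
        raise ValueError("need at least two edges to permute pairings")
    originals = {_pair_key(a, b) for a, b in pairs}
    left = [a for a, _ in pairs]
    right = [b for _, b in pairs]
    n = len(pairs)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        candidate = [_pair_key(left[i], right[perm[i]]) for i in range(n)]
        if any(c in originals for c in candidate):
            continue
        if any(a == b and (a, b) not in originals for a, b in candidate):
            continue
        return candidate
    raise RuntimeError("could not find a valid pairing permutation")


def permuted_null(
    pairs: list[tuple[str, str]],
    grid: SpotGrid,
    graph: list[tuple[int, int]],
    n_perm: int = 100,
    seed: int = 0,
    denominator: str = "expressing",
) -> np.ndarray:
    """Colocalization scores of randomly re-paired networks (flattened)."""
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(n_perm):
        for pair in permuted_pairs(pairs, rng):
            scores.append(colocalization_score(grid, graph, pair, denominator=denominator))
    return np.asarray(scores)


def compare_groups(
    known_scores: np.ndarray,
    novel_scores: np.ndarray,
    null_scores: np.ndarray,
) -> dict:
    """One-way ANOVA across the three score groups plus Tukey HSD post-hoc."""
    groups = {
        "known": np.asarray(known_scores, dtype=float),
        "novel": np.asarray(novel_scores, dtype=float),
        "null": np.asarray(null_scores, dtype=float),
    }
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs at least two values")
    arrays = list(groups.values())
    if np.ptp(np.concatenate(arrays)) == 0:
        return {"status": "degenerate", "f": 0.0, "p": 1.0, "tukey": None}
    f, p = stats.f_oneway(*arrays)
    if not np.isfinite(f):
        return {"status": "degenerate", "f": float(f), "p": float(p), "tukey": None}
    tukey = stats.tukey_hsd(*arrays)
    names = list(groups)
    pairwise = {}
    for i in range(3):
        for j in range(i + 1, 3):
            pairwise[f"{names[i]}_vs_{names[j]}"] = float(tukey.pvalue[i, j])
    return {"status": "ok", "f": float(f), "p": float(p), "tukey": pairwise}
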