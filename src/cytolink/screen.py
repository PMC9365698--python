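"""Screen-signal processing: plate normalization, pair scoring and benchmarking.

Raw bait x prey absorbance matrices are normalized by a two-way Tukey
median polish (per screening phase), collapsed to unordered protein-pair
scores by summing the two bait-prey orientations, thresholded, combined
across phases with a weighted sum, purged of promiscuous binders, and
benchmarked against positive/negative reference pair sets by ROC and
precision-recall analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as _skmetrics

__all__ = [
    "SignalMatrix",
    "PairScore",
    "ReferenceSets",
    "BenchmarkResult",
    "MedianPolishResult",
    "median_polish",
    "sum_orientations",
    "select_primary_hits",
    "combine_screens",
    "filter_promiscuous",
    "benchmark",
    "sample_random_negatives",
]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of a protein pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class SignalMatrix:
    """Bait x prey signal matrix for one screening phase.

    ``values`` is indexed by bait protein id (rows) and prey protein id
    (columns); missing measurements are NaN.  ``control_wells`` maps
    protein ids to control categories (``no-bait``, ``tag-only``,
    ``positive-control``) and is carried as metadata.
    """

    values: pd.DataFrame
    phase: str = "primary"
    control_wells: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("protein ids must be unique per axis")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise ValueError("signal matrix must contain only finite or missing values")

    @property
    def baits(self) -> list[str]:
        return list(self.values.index)

    @property
    def preys(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PairScore:
    pair: tuple[str, str]
    combined_score: float
    orientation_scores: tuple[float | None, float | None] = (None, None)
    homophilic: bool = False
    single_orientation: bool = False
    unconfirmed: bool = False
    phase_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ReferenceSets:
    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    negative_mode: str = "measured"
    stringent_positives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.positives = {_pair_key(*p) for p in self.positives}
        self.negatives = {_pair_key(*p) for p in self.negatives}
        self.stringent_positives = {_pair_key(*p) for p in self.stringent_positives}
        if self.positives & self.negatives:
            raise ValueError("positive and negative reference sets overlap")


@dataclass
class BenchmarkResult:
    roc_points: np.ndarray  # (n, 2) FPR, TPR
    pr_points: np.ndarray  # (n, 2) recall, precision
    auc: float
    average_precision: float
    n_positive: int
    n_negative: int


@dataclass
class MedianPolishResult:
    residuals: pd.DataFrame
    row_effects: pd.Series
    col_effects: pd.Series
    overall: float
    n_iter: int
    converged: bool


def median_polish(
    matrix: SignalMatrix | pd.DataFrame,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> MedianPolishResult:
    """Two-way Tukey median polish with NaN support.

    Alternates row and column median sweeps (rows first) until the largest
    absolute adjustment falls below ``tol`` or ``max_iter`` is reached.
    The additive decomposition ``overall + row + col + residual``
    reconstructs the input exactly for non-missing cells.
    """
    df = matrix.values if isinstance(matrix, SignalMatrix) else matrix
    x = df.to_numpy(dtype=float).copy()
    n_rows, n_cols = x.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("median polish requires at least a 2x2 matrix")
    row_ok = (~np.isnan(x)).sum(axis=1)
    col_ok = (~np.isnan(x)).sum(axis=0)
    if (row_ok == 0).any() or (col_ok == 0).any():
        raise ValueError("median polish: matrix has an all-missing row or column")

    overall = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # row sweep
        rmed = np.nanmedian(x, axis=1)
        x -= rmed[:, None]
        row_eff += rmed
        cmed_of_row = np.nanmedian(row_eff)
        row_eff -= cmed_of_row
        overall += cmed_of_row
        # column sweep
        cmed = np.nanmedian(x, axis=0)
        x -= cmed[None, :]
        col_eff += cmed
        rmed_of_col = np.nanmedian(col_eff)
        col_eff -= rmed_of_col
        overall += rmed_of_col
        delta = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
        if delta < tol:
            converged = True
            break

    residuals = pd.DataFrame(x, index=df.index, columns=df.columns)
    return MedianPolishResult(
        residuals=residuals,
        row_effects=pd.Series(row_eff, index=df.index),
        col_effects=pd.Series(col_eff, index=df.columns),
        overall=float(overall),
        n_iter=it,
        converged=converged,
    )


def sum_orientations(polished: SignalMatrix | pd.DataFrame) -> list[PairScore]:
    """Collapse a polished bait x prey matrix to unordered pair scores.

    score(a, b) = s(a->b) + s(b->a); a homophilic pair scores 2*s(a->a).
    When exactly one orientation was measured its value is used un-doubled
    and the pair is flagged ``single_orientation``.  Pairs missing both
    orientations are excluded.
    """
    df = polished.values if isinstance(polished, SignalMatrix) else polished
    baits = list(df.index)
    preys = list(df.columns)
    universe = sorted(set(baits) | set(preys))
    arr = df.to_numpy(dtype=float)
    bait_idx = {p: i for i, p in enumerate(baits)}
    prey_idx = {p: i for i, p in enumerate(preys)}

    def s(a: str, b: str) -> float:
        i = bait_idx.get(a)
        j = prey_idx.get(b)
        if i is None or j is None:
            return np.nan
        return arr[i, j]

    out: list[PairScore] = []
    for ia, a in enumerate(universe):
        for b in universe[ia:]:
            ab = s(a, b)
            ba = s(b, a)
            if a == b:
                if np.isnan(ab):
                    continue
                out.append(
                    PairScore(
                        pair=(a, b),
                        combined_score=2.0 * ab,
                        orientation_scores=(ab, ab),
                        homophilic=True,
                    )
                )
                continue
            have_ab = not np.isnan(ab)
            have_ba = not np.isnan(ba)
            if not have_ab and not have_ba:
                continue
            if have_ab and have_ba:
                out.append(
                    PairScore(
                        pair=(a, b),
                        combined_score=float(ab + ba),
                        orientation_scores=(float(ab), float(ba)),
                    )
                )
            else:
                val = float(ab) if have_ab else float(ba)
                out.append(
                    PairScore(
                        pair=(a, b),
                        combined_score=val,
                        orientation_scores=(
                            float(ab) if have_ab else None,
                            float(ba) if have_ba else None,
                        ),
                        single_orientation=True,
                    )
                )
    return out


def select_primary_hits(
    scores: Iterable[PairScore],
    threshold: float = 1.0,
    background_proteins: Iterable[str] = (),
) -> set[tuple[str, str]]:
    """Pairs whose combined score reaches ``threshold``, excluding pairs
    involving proteins flagged as high-variance background."""
    bg = set(background_proteins)
    return {
        ps.pair
        for ps in scores
        if ps.combined_score >= threshold and not (set(ps.pair) & bg)
    }


def combine_screens(
    primary_scores: Iterable[PairScore],
    secondary_scores: Iterable[PairScore],
    secondary_weight: float = 3.0,
) -> list[PairScore]:
    """Weighted combination of primary and secondary screen pair scores.

    combined = primary + secondary_weight * secondary for pairs measured
    in both phases; pairs absent from the secondary screen keep their
    primary score and are flagged ``unconfirmed``.
    """
    if secondary_weight < 0:
        raise ValueError("secondary_weight must be non-negative")
    sec = {ps.pair: ps for ps in secondary_scores}
    out: list[PairScore] = []
    for ps in primary_scores:
        s = sec.get(ps.pair)
        if s is None:
            out.append(
                PairScore(
                    pair=ps.pair,
                    combined_score=ps.combined_score,
                    orientation_scores=ps.orientation_scores,
                    homophilic=ps.homophilic,
                    single_orientation=ps.single_orientation,
                    unconfirmed=True,
                    phase_scores={"primary": ps.combined_score},
                )
            )
        else:
            out.append(
                PairScore(
                    pair=ps.pair,
                    combined_score=ps.combined_score
                    + secondary_weight * s.combined_score,
                    orientation_scores=ps.orientation_scores,
                    homophilic=ps.homophilic,
                    single_orientation=ps.single_orientation,
                    phase_scores={
                        "primary": ps.combined_score,
                        "secondary": s.combined_score,
                    },
                )
            )
    return out


def filter_promiscuous(
    scores: Sequence[PairScore],
    top_n: int = 1000,
    max_appearances: int = 20,
) -> tuple[list[PairScore], set[str]]:
    """Remove promiscuous binders.

    Proteins appearing strictly more than ``max_appearances`` times among
    the ``top_n`` highest-scoring pairs are excluded together with every
    pair they participate in.  Ties in score are broken by lexicographic
    pair id so the top-N cut is deterministic.
    """
    ranked = sorted(scores, key=lambda ps: (-ps.combined_score, ps.pair))
    top = ranked[: min(top_n, len(ranked))]
    counts: dict[str, int] = {}
    for ps in top:
        a, b = ps.pair
        counts[a] = counts.get(a, 0) + 1
        if b != a:
            counts[b] = counts.get(b, 0) + 1
    excluded = {p for p, c in counts.items() if c > max_appearances}
    kept = [ps for ps in scores if not (set(ps.pair) & excluded)]
    return kept, excluded


def sample_random_negatives(
    universe: Sequence[str],
    positives: set[tuple[str, str]],
    n_negatives: int,
    rng: np.random.Generator,
) -> set[tuple[str, str]]:
    """Seeded sample of non-positive protein pairs, without replacement."""
    universe = sorted(universe)
    all_pairs = [
        (a, b)
        for i, a in enumerate(universe)
        for b in universe[i:]
        if _pair_key(a, b) not in positives
    ]
    if n_negatives > len(all_pairs):
        raise ValueError("not enough non-positive pairs to sample negatives from")
    idx = rng.choice(len(all_pairs), size=n_negatives, replace=False)
    return {all_pairs[i] for i in idx}


def benchmark(
    scores: Iterable[PairScore],
    refs: ReferenceSets,
    expressed_proteins: set[str] | None = None,
) -> BenchmarkResult:
    """ROC / precision-recall benchmark of pair scores against reference sets.

    Every distinct score acts as a classification threshold; pairs in
    neither reference set are ignored.  Reference pairs never scored by
    the screen are treated as scoring below every measured pair.  When
    ``expressed_proteins`` is given, only pairs whose both members carry
    expression evidence enter the benchmark.
    """
    if not refs.positives or not refs.negatives:
        raise ValueError("both positive and negative reference sets must be nonempty")
    score_map = {ps.pair: ps.combined_score for ps in scores}
    floor = min(score_map.values()) - 1.0 if score_map else 0.0

    y_true: list[int] = []
    y_score: list[float] = []
    for pair_set, label in ((refs.positives, 1), (refs.negatives, 0)):
        for pair in sorted(pair_set):
            if expressed_proteins is not None and not set(pair) <= expressed_proteins:
                continue
            y_true.append(label)
            y_score.append(score_map.get(pair, floor))
    if not any(y_true) or all(y_true):
        raise ValueError("benchmark requires both labels after filtering")

    y_true_a = np.asarray(y_true)
    y_score_a = np.asarray(y_score)
    fpr, tpr, _ = _skmetrics.roc_curve(y_true_a, y_score_a)
    precision, recall, _ = _skmetrics.precision_recall_curve(y_true_a, y_score_a)
    return BenchmarkResult(
        roc_points=np.column_stack([fpr, tpr]),
        pr_points=np.column_stack([recall, precision]),
        auc=float(_skmetrics.roc_auc_score(y_true_a, y_score_a)),
        average_precision=float(_skmetrics.average_precision_score(y_true_a, y_score_a)),
        n_positive=int(y_true_a.sum()),
        n_negative=int((1 - y_true_a).sum()),
    )
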