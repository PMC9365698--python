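"""Synthetic input generators with planted ground truth.

Every downstream stage of the package can be exercised on data produced
here: arrayed binding-screen matrices with additive plate effects and
planted binder pairs, cell-type expression matrices with activation fold
changes, spatially zonated spot grids, and imaging-style cell tables with
planted pairwise association preferences.  All randomness flows through a
single ``numpy.random.Generator`` derived from the config seed; fixing the
seed fixes every generated artifact bit-for-bit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .screen import SignalMatrix, _pair_key

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ExpressionSet",
    "SpotGrid",
    "generate_screen",
    "generate_expression",
    "generate_spots",
    "generate_cell_table",
]


@dataclass
class SimConfig:
    """Parameters for all synthetic generators.

    The screen noise model is additive Gaussian on absorbance; the assay's
    real noise distribution is uncharacterized, so this is a stated
    modelling assumption (median polish targets additive structure).
    """

    n_proteins: int = 50
    n_true_pairs: int = 10
    pair_effect: float = 2.0
    noise_sd: float = 0.1
    row_effect_sd: float = 0.0
    col_effect_sd: float = 0.0
    baseline: float = 0.0
    promiscuity_rate: float = 0.0
    promiscuous_fraction_of_partners: float = 0.3
    promiscuous_effect: float = 1.5
    n_cell_types: int = 4
    n_replicates: int = 4
    activation_fold_range: tuple[float, float] = (2.0, 8.0)
    n_regulated: int = 6
    expression_scale: float = 10000.0
    kd_log10_range: tuple[float, float] = (-7.0, -4.0)
    grid_shape: tuple[int, int] = (20, 20)
    grid_pitch: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1 or self.n_cell_types < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        if self.n_true_pairs < 0:
            raise ValueError("n_true_pairs must be >= 0")
        for name in ("noise_sd", "row_effect_sd", "col_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.kd_log10_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
            raise ValueError("kd_log10_range must be a finite ordered interval")
        if not (0.0 <= self.promiscuity_rate <= 1.0):
            raise ValueError("promiscuity_rate must be in [0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    true_pairs: set[tuple[str, str]] = field(default_factory=set)
    promiscuous_proteins: set[str] = field(default_factory=set)
    planted_kd: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_cell_preferences: dict[tuple[str, str], float] = field(default_factory=dict)
    zonated_pairs: set[tuple[str, str]] = field(default_factory=set)
    regulated_proteins: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(kd <= 0 for kd in self.planted_kd.values()):
            raise ValueError("planted K_D values must be positive")
        if any(not np.isfinite(v) or v < 0 for v in self.planted_cell_preferences.values()):
            raise ValueError("cell preferences must be finite and >= 0")


@dataclass
class ExpressionSet:
    """Counts-per-cell expression with replicate structure.

    ``values`` has a (cell_type, replicate) MultiIndex over rows and
    protein ids as columns.
    """

    values: pd.DataFrame
    modality: str = "bulk-replicates"
    state: str | None = None

    def mean_by_cell_type(self) -> pd.DataFrame:
        return self.values.groupby(level="cell_type", sort=True).mean()


@dataclass
class SpotGrid:
    spots: pd.DataFrame  # index: spot id; columns: x, y
    counts: pd.DataFrame  # index: spot id; columns: gene ids
    mito_genes: set[str] = field(default_factory=set)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_screen(
    config: SimConfig,
) -> tuple[SignalMatrix, SignalMatrix, GroundTruth]:
    """Simulate primary and secondary arrayed binding screens.

    Signals decompose additively as baseline + bait(row) effect +
    prey(column) effect + pair effect + Gaussian noise.  The pair effect
    is positive in both orientations for planted true pairs; promiscuous
    proteins receive an elevated signal against a random subset of
    partners.  The secondary screen is an all-versus-all matrix restricted
    to the proteins selected for retest (true-pair members plus a random
    filler set).
    """
    rng = config.rng()
    ids = _protein_ids(config.n_proteins)
    n = config.n_proteins

    all_pairs = list(itertools.combinations(range(n), 2))
    if config.n_true_pairs > len(all_pairs):
        raise ValueError("n_true_pairs exceeds the number of distinct pairs")
    chosen = rng.choice(len(all_pairs), size=config.n_true_pairs, replace=False)
    true_pairs = {
        _pair_key(ids[all_pairs[k][0]], ids[all_pairs[k][1]]) for k in sorted(chosen)
    }

    n_prom = int(round(config.promiscuity_rate * n))
    prom_idx = rng.choice(n, size=n_prom, replace=False) if n_prom else np.array([], dtype=int)
    promiscuous = {ids[i] for i in prom_idx}

    lo, hi = config.kd_log10_range
    planted_kd = {
        pair: float(10.0 ** rng.uniform(lo, hi)) for pair in sorted(true_pairs)
    }

    def build_matrix(members: list[str]) -> pd.DataFrame:
        m = len(members)
        idx = {p: i for i, p in enumerate(members)}
        sig = np.full((m, m), config.baseline, dtype=float)
        sig += rng.normal(0.0, config.row_effect_sd, size=m)[:, None] if config.row_effect_sd else 0.0
        sig += rng.normal(0.0, config.col_effect_sd, size=m)[None, :] if config.col_effect_sd else 0.0
        for (a, b) in true_pairs:
            if a in idx and b in idx:
                sig[idx[a], idx[b]] += config.pair_effect
                if a != b:
                    sig[idx[b], idx[a]] += config.pair_effect
        for p in sorted(promiscuous & set(members)):
            partners = [q for q in members if q != p]
            n_hit = int(round(config.promiscuous_fraction_of_partners * len(partners)))
            if n_hit:
                hit = rng.choice(len(partners), size=n_hit, replace=False)
                for h in hit:
                    q = partners[h]
                    sig[idx[p], idx[q]] += config.promiscuous_effect
        if config.noise_sd:
            sig += rng.normal(0.0, config.noise_sd, size=(m, m))
        return pd.DataFrame(sig, index=members, columns=members)

    primary = SignalMatrix(values=build_matrix(ids), phase="primary")

    retest = sorted({p for pair in true_pairs for p in pair})
    others = [p for p in ids if p not in set(retest)]
    n_fill = min(len(others), max(0, min(n, 2 * len(retest) + 2) - len(retest)))
    if n_fill:
        fill = rng.choice(len(others), size=n_fill, replace=False)
        retest = sorted(set(retest) | {others[i] for i in fill})
    if len(retest) < 2:
        retest = ids[: min(4, n)]
    secondary = SignalMatrix(values=build_matrix(retest), phase="secondary")

    truth = GroundTruth(
        true_pairs=true_pairs,
        promiscuous_proteins=promiscuous,
        planted_kd=planted_kd,
    )
    return primary, secondary, truth


def generate_expression(
    config: SimConfig,
) -> tuple[ExpressionSet, ExpressionSet, pd.DataFrame, GroundTruth]:
    """Simulate resting/activated counts-per-cell expression with replicates.

    A designated subset of proteins is up- or down-regulated in the
    activated state by fold factors drawn from ``activation_fold_range``
    (direction alternating), applied on top of a cell-type-structured
    log-normal baseline.  Also returns a subtype proportion table whose
    proportions sum to 1 within each parent type.
    """
    rng = config.rng()
    ids = _protein_ids(config.n_proteins)
    cell_types = [f"CT{i}" for i in range(config.n_cell_types)]

    base = config.expression_scale * rng.lognormal(0.0, 1.0, size=(config.n_cell_types, config.n_proteins))

    n_reg = min(config.n_regulated, config.n_proteins)
    reg_idx = rng.choice(config.n_proteins, size=n_reg, replace=False)
    lo, hi = config.activation_fold_range
    folds = rng.uniform(lo, hi, size=n_reg)
    regulated: dict[str, float] = {}
    fold_vector = np.ones(config.n_proteins)
    for k, j in enumerate(reg_idx):
        f = folds[k] if k % 2 == 0 else 1.0 / folds[k]
        fold_vector[j] = f
        regulated[ids[j]] = float(f)

    def replicate_frame(mean: np.ndarray, state: str) -> ExpressionSet:
        rows = []
        index = []
        for i, ct in enumerate(cell_types):
            for r in range(config.n_replicates):
                noise = rng.lognormal(0.0, 0.1, size=config.n_proteins)
                rows.append(mean[i] * noise)
                index.append((ct, r))
        df = pd.DataFrame(
            np.vstack(rows),
            index=pd.MultiIndex.from_tuples(index, names=["cell_type", "replicate"]),
            columns=ids,
        )
        return ExpressionSet(values=df, modality="bulk-replicates", state=state)

    resting = replicate_frame(base, "resting")
    activated = replicate_frame(base * fold_vector[None, :], "activated")

    # two subtypes per parent with proportions summing to 1
    sub_rows = []
    for ct in cell_types:
        p = float(rng.uniform(0.2, 0.8))
        sub_rows.append({"subtype": f"{ct}_a", "parent": ct, "proportion": p})
        sub_rows.append({"subtype": f"{ct}_b", "parent": ct, "proportion": 1.0 - p})
    subtype_table = pd.DataFrame(sub_rows)

    truth = GroundTruth(regulated_proteins=regulated)
    return resting, activated, subtype_table, truth


def generate_spots(
    config: SimConfig,
    n_zonated_pairs: int = 2,
    n_control_pairs: int = 2,
    expression_rate: float = 5.0,
    mito_fraction: float = 0.05,
) -> tuple[SpotGrid, GroundTruth]:
    """Simulate a spot lattice with spatially zonated gene pairs.

    Zonated pairs are expressed in adjacent half-planes that meet at a
    border; control pairs occupy disjoint, non-adjacent bands.  Counts are
    Poisson, include housekeeping background and mitochondrial genes so QC
    filters are exercisable.
    """
    rows, cols = config.grid_shape
    if rows < 3 or cols < 3:
        raise ValueError("spot lattice must be at least 3x3")
    rng = config.rng()
    xs, ys = np.meshgrid(np.arange(cols), np.arange(rows))
    x = xs.ravel() * config.grid_pitch
    y = ys.ravel() * config.grid_pitch
    spot_ids = [f"S{i:05d}" for i in range(x.size)]
    spots = pd.DataFrame({"x": x, "y": y}, index=spot_ids)

    genes: list[str] = []
    counts: dict[str, np.ndarray] = {}
    zonated: set[tuple[str, str]] = set()

    mid = (cols - 1) / 2.0 * config.grid_pitch
    for k in range(n_zonated_pairs):
        ga, gb = f"ZA{k}", f"ZB{k}"
        left = x <= mid
        counts[ga] = rng.poisson(np.where(left, expression_rate, 0.0))
        counts[gb] = rng.poisson(np.where(~left, expression_rate, 0.0))
        genes += [ga, gb]
        zonated.add(_pair_key(ga, gb))

    third = (cols - 1) / 3.0 * config.grid_pitch
    for k in range(n_control_pairs):
        ga, gb = f"CA{k}", f"CB{k}"
        counts[ga] = rng.poisson(np.where(x < third, expression_rate, 0.0))
        counts[gb] = rng.poisson(np.where(x > 2 * third + config.grid_pitch, expression_rate, 0.0))
        genes += [ga, gb]

    n_housekeeping = 30
    for k in range(n_housekeeping):
        g = f"HK{k}"
        counts[g] = rng.poisson(expression_rate, size=x.size)
        genes.append(g)
    mito = set()
    for k in range(3):
        g = f"MT-G{k}"
        rate = expression_rate * mito_fraction * n_housekeeping / 3.0
        counts[g] = rng.poisson(rate, size=x.size)
        genes.append(g)
        mito.add(g)

    count_df = pd.DataFrame({g: counts[g] for g in genes}, index=spot_ids).astype(int)
    grid = SpotGrid(spots=spots, counts=count_df, mito_genes=mito)
    truth = GroundTruth(zonated_pairs=zonated)
    return grid, truth


def generate_cell_table(
    config: SimConfig,
    preferences: Mapping[tuple[str, str], float] | None = None,
    cell_types: list[str] | None = None,
    type_frequencies: np.ndarray | None = None,
    n_wells: int = 10,
    cells_per_well: int = 300,
    field_size: float = 2000.0,
    contact_radius: float = 40.0,
    coplacement_rate: float = 0.1,
    n_control_wells: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate imaging-style cell tables with planted association preferences.

    Cells are placed uniformly in each well; for every placed "seed" cell
    of type A, extra partner cells of type B are co-placed within the
    contact radius at Poisson rate ``coplacement_rate * (pref(A,B) - 1)``
    (clipped at zero).  A uniform preference of 1 therefore reproduces
    random mixing, and doubling a preference monotonically increases the
    expected co-occurrence of that type pair.  Control wells (uniform
    preferences) are appended when requested and flagged in the output.
    """
    rng = config.rng()
    if cell_types is None:
        cell_types = [f"CT{i}" for i in range(config.n_cell_types)]
    k = len(cell_types)
    if type_frequencies is None:
        type_frequencies = np.full(k, 1.0 / k)
    type_frequencies = np.asarray(type_frequencies, dtype=float)
    type_frequencies = type_frequencies / type_frequencies.sum()

    pref = np.ones((k, k))
    t_index = {t: i for i, t in enumerate(cell_types)}
    planted: dict[tuple[str, str], float] = {}
    if preferences:
        for (a, b), v in preferences.items():
            if v < 0 or not np.isfinite(v):
                raise ValueError("preferences must be finite and >= 0")
            pref[t_index[a], t_index[b]] = v
            pref[t_index[b], t_index[a]] = v
            planted[_pair_key(a, b)] = float(v)

    records = []
    for w in range(n_wells + n_control_wells):
        control = w >= n_wells
        well_pref = np.ones((k, k)) if control else pref
        well_id = f"{'ctrl' if control else 'well'}{w:03d}"
        seeds = rng.integers(0, k, size=cells_per_well)
        xy = rng.uniform(0.0, field_size, size=(cells_per_well, 2))
        for i in range(cells_per_well):
            ti = int(seeds[i])
            records.append(
                {
                    "well": well_id,
                    "site": 0,
                    "x": xy[i, 0],
                    "y": xy[i, 1],
                    "cell_type": cell_types[ti],
                    "control": control,
                }
            )
            for tj in range(k):
                # one partner at most per seed/type, placed with probability
                # proportional to the planted preference excess
                rate = min(coplacement_rate * max(well_pref[ti, tj] - 1.0, 0.0), 1.0)
                if rate <= 0:
                    continue
                n_extra = int(rng.uniform() < rate)
                for _ in range(n_extra):
                    r = contact_radius * np.sqrt(rng.uniform(0.05, 0.95))
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    records.append(
                        {
                            "well": well_id,
                            "site": 0,
                            "x": float(np.clip(xy[i, 0] + r * np.cos(theta), 0, field_size)),
                            "y": float(np.clip(xy[i, 1] + r * np.sin(theta), 0, field_size)),
                            "cell_type": cell_types[tj],
                            "control": control,
                        }
                    )
    table = pd.DataFrame.from_records(records)
    truth = GroundTruth(planted_cell_preferences=planted)
    return table, truth
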