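"""Cell-cell interaction scoring from segmented imaging cell tables.

Consumes (well, site, x, y, cell_type) tables; contacts are nuclear
centroids within a fixed pixel radius inside the same image site, pooled
per well.  Interaction scores normalize observed type-pair contacts by
the random-mixing expectation; condition effects are normalized to
matched controls into [-1, 1] and tested with Welch's t-test under
Benjamini-Hochberg control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "find_contacts",
    "contact_counts",
    "interaction_score_formula",
    "interaction_score",
    "well_scores",
    "normalize_to_control",
    "test_effects",
]

_REQUIRED_COLUMNS = ("well", "site", "x", "y", "cell_type")


def _check_table(cells: pd.DataFrame) -> None:
    for col in _REQUIRED_COLUMNS:
        if col not in cells.columns:
            raise ValueError(f"cell table lacks required column {col!r}")
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("cell coordinates must be finite")


def find_contacts(cells: pd.DataFrame, radius: float = 40.0) -> pd.DataFrame:
    """All unordered cell pairs with centroid distance <= radius.

    ``cells`` holds one well; contacts never span image sites.  Returns a
    frame with integer positional indices (i, j), the two cell types and
    the distance.
    """
    _check_table(cells)
    rows = []
    for _, site_cells in cells.groupby("site"):
        xy = site_cells[["x", "y"]].to_numpy(dtype=float)
        if len(xy) < 2:
            continue
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        pos = site_cells.index.to_numpy()
        types = site_cells["cell_type"].to_numpy()
        for i, j in pairs:
            rows.append(
                {
                    "i": pos[i],
                    "j": pos[j],
                    "type_i": types[i],
                    "type_j": types[j],
                    "distance": float(np.hypot(*(xy[i] - xy[j]))),
                }
            )
    return pd.DataFrame(rows, columns=["i", "j", "type_i", "type_j", "distance"])


def contact_counts(contacts: pd.DataFrame, cell_types: list[str]) -> pd.DataFrame:
    """Unordered contact counts per type pair (symmetric matrix).

    Entry (A, B) with A != B counts A-B contact pairs once; the diagonal
    counts homotypic contact pairs once.
    """
    mat = pd.DataFrame(0, index=cell_types, columns=cell_types, dtype=float)
    for t_i, t_j in zip(contacts["type_i"], contacts["type_j"]):
        mat.loc[t_i, t_j] += 1
        if t_i != t_j:
            mat.loc[t_j, t_i] += 1
    return mat


def interaction_score_formula(
    specific: float, frac_a: float, frac_b: float, total: float
) -> float:
    """score = specific / (frac_a * frac_b * total); NaN when undefined."""
    denom = frac_a * frac_b * total
    if denom <= 0:
        return np.nan
    return specific / denom


def interaction_score(
    well_cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius: float = 40.0,
) -> float:
    """Interaction score of one type pair in one well.

    Convention (documented, applied identically to model output):
    specific(A, B) is the unordered A-B contact count for A != B and
    twice the homotypic contact count for A == B; total is the summed
    per-cell contact count (2x the unordered contact count), so a
    randomly mixed well scores ~1 for every pair.  Undefined scores
    (absent type or no contacts) are returned as NaN rather than 0.
    """
    scores = well_scores(well_cells, radius=radius)
    return float(scores.loc[type_a, type_b])


def well_scores(well_cells: pd.DataFrame, radius: float = 40.0) -> pd.DataFrame:
    """Interaction-score matrix over all type pairs in one well."""
    _check_table(well_cells)
    cell_types = sorted(well_cells["cell_type"].unique())
    n_cells = len(well_cells)
    fractions = well_cells["cell_type"].value_counts(normalize=True)
    contacts = find_contacts(well_cells, radius=radius)
    counts = contact_counts(contacts, cell_types)
    total = 2.0 * len(contacts)
    out = pd.DataFrame(np.nan, index=cell_types, columns=cell_types)
    for a in cell_types:
        for b in cell_types:
            specific = 2.0 * counts.loc[a, a] if a == b else counts.loc[a, b]
            out.loc[a, b] = interaction_score_formula(
                specific, fractions.get(a, 0.0), fractions.get(b, 0.0), total
            )
    out.attrs["n_cells"] = n_cells
    out.attrs["n_contacts"] = len(contacts)
    return out


def normalize_to_control(observed: float, control_mean: float) -> float:
    """(obs - ctrl) / max(obs, ctrl), bounded in [-1, 1]; 0 when both are 0."""
    if observed < 0 or control_mean < 0:
        raise ValueError("normalization inputs must be nonnegative")
    m = max(observed, control_mean)
    if m == 0:
        return 0.0
    return (observed - control_mean) / m


def test_effects(
    condition_values: dict[str, np.ndarray],
    control_values: np.ndarray,
    fdr: float = 0.10,
    min_n: int = 2,
) -> pd.DataFrame:
    """Welch's t-test of each condition's raw replicate values vs control.

    Raw (not normalized) values enter the test; the reported effect size
    is the control-normalized mean, bounded in [-1, 1].  p-values are
    BH-adjusted across the tested family and flagged at the given FDR.
    Conditions with fewer than ``min_n`` replicates on either side are
    skipped with an explicit status.
    """
    control_values = np.asarray(control_values, dtype=float)
    control_values = control_values[np.isfinite(control_values)]
    rows = []
    for name in sorted(condition_values):
        vals = np.asarray(condition_values[name], dtype=float)
        vals = vals[np.isfinite(vals)]
        row = {"condition": name, "n": len(vals), "n_control": len(control_values)}
        if len(vals) < min_n or len(control_values) < min_n:
            row.update({"status": "skipped", "t": np.nan, "p": np.nan, "effect": np.nan})
        else:
            t, p = stats.ttest_ind(vals, control_values, equal_var=False)
            row.update(
                {
                    "status": "ok",
                    "t": float(t),
                    "p": float(p),
                    "effect": normalize_to_control(
                        float(np.mean(vals)), float(np.mean(control_values))
                    ),
                }
            )
        rows.append(row)
    result = pd.DataFrame(rows)
    ok = result["status"] == "ok"
    result["p_bh"] = np.nan
    result["significant"] = False
    if ok.any():
        rej, p_bh, _, _ = multipletests(result.loc[ok, "p"].to_numpy(), alpha=fdr, method="fdr_bh")
        result.loc[ok, "p_bh"] = p_bh
        result.loc[ok, "significant"] = rej
    return result
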