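"""Mass-action cell connectivity model.

Protein copies per cell are converted to surface densities on spherical
cells; per-interaction bound densities follow saturation
(Michaelis-Menten) binding with a 3D-to-2D dissociation-constant
conversion; summed bound densities give relative cell-pair affinities,
which parameterize a law-of-mass-action doublet ODE whose equilibrium is
scored with the same formula used for imaging data.  Protein knockouts
are simulated by zeroing expression and re-running the chain.

Only relative comparisons between cell pairs are meaningful: the
confinement length ``h``, collision rate ``k_c`` and dissociation scale
``kappa`` are order-of-magnitude constants, and equilibrium results
depend on ``kappa`` and ``k_c`` only through their ratio.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .imaging import interaction_score_formula
from .interactome import InteractionNetwork

__all__ = [
    "AVOGADRO",
    "CellGeometry",
    "ModelConfig",
    "ODEState",
    "EquilibrationError",
    "counts_to_density",
    "merge_subtypes",
    "kd_to_2d",
    "bound_density",
    "cell_pair_affinity",
    "integrate_doublets",
    "model_interaction_scores",
    "perturb_protein",
    "rank_and_compare",
]

AVOGADRO = 6.02214076e23
_LITRE_IN_UM3 = 1e15


@dataclass
class CellGeometry:
    """Physical/abundance parameters for the modelled cell types."""

    table: pd.DataFrame  # index: cell_type; columns: radius_um, blood_frequency

    def __post_init__(self) -> None:
        t = self.table
        if (t["radius_um"] <= 0).any():
            raise ValueError("cell radii must be positive")
        if (t["blood_frequency"] < 0).any():
            raise ValueError("blood frequencies must be nonnegative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.table.index)

    def radius(self, cell_type: str) -> float:
        return float(self.table.loc[cell_type, "radius_um"])

    def frequency(self, cell_type: str) -> float:
        return float(self.table.loc[cell_type, "blood_frequency"])


@dataclass
class ModelConfig:
    confinement_h_um: float = 0.01
    collision_rate: float = 1.0
    dissociation_scale: float = 1.0
    affinity_floor: float = 1e-12
    default_kd_molar: float = 1e-6
    equilibrium_tol: float = 1e-10
    max_time: float = 1e9

    def __post_init__(self) -> None:
        for name in ("confinement_h_um", "collision_rate", "dissociation_scale", "affinity_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class EquilibrationError(RuntimeError):
    """ODE failed to reach equilibrium; carries the last state reached."""

    def __init__(self, message: str, state: "ODEState"):
        super().__init__(message)
        self.state = state


@dataclass
class ODEState:
    cell_types: list[str]
    free: np.ndarray  # F_i
    doublets: np.ndarray  # symmetric matrix D_ij (unordered pair frequencies)
    initial: np.ndarray
    residual: float = np.nan

    def conservation_error(self) -> float:
        """Max relative violation of per-type conservation."""
        d = self.doublets
        bound = d.sum(axis=1) + np.diag(d)  # off-diag once + diag twice
        total = self.free + bound
        scale = np.maximum(np.abs(self.initial), 1e-300)
        return float(np.max(np.abs(total - self.initial) / scale))


def counts_to_density(copies_per_cell: float, radius_um: float) -> float:
    """Surface density (molecules / um^2) on a sphere of the given radius."""
    if radius_um <= 0:
        raise ValueError("radius must be positive")
    if copies_per_cell < 0:
        raise ValueError("copy number must be nonnegative")
    return copies_per_cell / (4.0 * np.pi * radius_um**2)


def merge_subtypes(
    expr: pd.DataFrame,
    subtype_table: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse subtype-level expression to parent-level weighted means.

    ``subtype_table`` has columns subtype, parent, proportion; proportions
    are renormalized (with a warning) if they do not sum to 1 per parent.
    Rows of ``expr`` not listed as subtypes pass through unchanged.
    """
    import warnings

    mapped = set(subtype_table["subtype"])
    out_rows = {}
    for parent, grp in subtype_table.groupby("parent"):
        subs = [s for s in grp["subtype"] if s in expr.index]
        if not subs:
            continue
        props = grp.set_index("subtype").loc[subs, "proportion"].to_numpy(dtype=float)
        total = props.sum()
        if not np.isclose(total, 1.0):
            warnings.warn(
                f"subtype proportions for {parent!r} sum to {total:.4g}; renormalizing"
            )
        props = props / total
        out_rows[parent] = expr.loc[subs].T @ props
    passthrough = expr.loc[[i for i in expr.index if i not in mapped]]
    merged = pd.DataFrame(out_rows).T
    merged.columns = expr.columns
    return pd.concat([merged, passthrough]).sort_index()


def kd_to_2d(kd_molar: float, config: ModelConfig) -> float:
    """Convert a solution-phase K_D (molar) to a 2D density (molecules/um^2).

    K2D = K_D * N_A * h with h the confinement length; at the default
    h = 0.01 um, 1 uM maps to ~6 molecules/um^2.
    """
    if kd_molar <= 0:
        raise ValueError("K_D must be positive")
    per_um3 = kd_molar * AVOGADRO / _LITRE_IN_UM3
    return per_um3 * config.confinement_h_um


def bound_density(
    rho_rec: float,
    rho_lig: float,
    kd_molar: float,
    config: ModelConfig | None = None,
) -> float:
    """Equilibrium bound density for one interaction (molecules / um^2).

    Saturation binding B = rho_rec * rho_lig / (K2D + rho_lig), averaged
    over both receptor/ligand role assignments since the network is
    undirected.
    """
    config = config or ModelConfig()
    if rho_rec < 0 or rho_lig < 0:
        raise ValueError("densities must be nonnegative")
    k2d = kd_to_2d(kd_molar, config)
    fwd = rho_rec * rho_lig / (k2d + rho_lig)
    rev = rho_lig * rho_rec / (k2d + rho_rec)
    return 0.5 * (fwd + rev)


def cell_pair_affinity(
    densities: pd.DataFrame,
    network: InteractionNetwork,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Symmetric cell-pair relative affinity A(X, Y).

    A(X, Y) sums the symmetrized bound density of every network edge over
    both placements of the edge's proteins on the two cells; homophilic
    edges contribute a single term.  Edges without a measured K_D fall
    back to ``config.default_kd_molar``.
    """
    config = config or ModelConfig()
    types = list(densities.index)
    a = pd.DataFrame(0.0, index=types, columns=types)
    for (p, q), kd in zip(network.pairs, network.edges["kd_molar"]):
        if p not in densities.columns or q not in densities.columns:
            continue
        kd_use = config.default_kd_molar if np.isnan(kd) else float(kd)
        for x, y in itertools.combinations_with_replacement(types, 2):
            rp_x, rq_y = densities.loc[x, p], densities.loc[y, q]
            contrib = bound_density(rp_x, rq_y, kd_use, config)
            if p != q:
                rq_x, rp_y = densities.loc[x, q], densities.loc[y, p]
                contrib += bound_density(rq_x, rp_y, kd_use, config)
            a.loc[x, y] += contrib
            if x != y:
                a.loc[y, x] += contrib
    return a


def _pack(d: np.ndarray, n: int) -> np.ndarray:
    iu = np.triu_indices(n)
    return d[iu]


def _unpack(v: np.ndarray, n: int) -> np.ndarray:
    d = np.zeros((n, n))
    iu = np.triu_indices(n)
    d[iu] = v
    d = d + d.T - np.diag(np.diag(d))
    return d


def integrate_doublets(
    affinity: pd.DataFrame,
    geometry: CellGeometry,
    config: ModelConfig | None = None,
) -> ODEState:
    """Integrate the doublet-formation ODE to equilibrium.

    Doublet dynamics: dD_ij/dt = k_c F_i F_j - k_off(i,j) D_ij for i != j
    and dD_ii/dt = (1/2) k_c F_i^2 - k_off(i,i) D_ii, with
    k_off(i,j) = kappa / max(A(i,j), floor).  Free-cell frequencies are
    recovered from per-type conservation, which the integration therefore
    satisfies exactly.  Integration proceeds in doubling time windows
    until the largest normalized time derivative drops below the
    equilibrium tolerance.
    """
    config = config or ModelConfig()
    types = [t for t in affinity.index if t in geometry.cell_types]
    n = len(types)
    if n == 0:
        raise ValueError("no cell types shared between affinity matrix and geometry")
    a = affinity.loc[types, types].to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("affinity matrix must be symmetric")
    init = np.array([geometry.frequency(t) for t in types])
    k_off = config.dissociation_scale / np.maximum(a, config.affinity_floor)
    k_c = config.collision_rate
    iu = np.triu_indices(n)
    half = np.where(iu[0] == iu[1], 0.5, 1.0)

    def free_of(dvec: np.ndarray) -> np.ndarray:
        d = _unpack(dvec, n)
        bound = d.sum(axis=1) + np.diag(d)
        return init - bound

    def rhs(_t: float, dvec: np.ndarray) -> np.ndarray:
        f = np.maximum(free_of(dvec), 0.0)
        form = half * k_c * f[iu[0]] * f[iu[1]]
        return form - k_off[iu] * dvec

    d0 = np.zeros(len(iu[0]))
    # characteristic time scale from the fastest dissociation / formation
    t_span = max(1.0 / max(k_off.max(), 1e-12), 1.0 / max(k_c, 1e-12))
    state = d0
    t_total = 0.0
    flux_scale = max(k_c * float(init.max()) ** 2, 1e-300)
    while t_total < config.max_time:
        sol = solve_ivp(
            rhs,
            (0.0, t_span),
            state,
            method="LSODA",
            rtol=1e-10,
            atol=1e-14,
        )
        state = sol.y[:, -1]
        t_total += t_span
        t_span *= 2.0
        deriv = rhs(0.0, state)
        scale = max(np.max(np.abs(state)), 1e-300)
        if np.max(np.abs(deriv)) / max(flux_scale, scale) < config.equilibrium_tol:
            d = _unpack(state, n)
            f = free_of(state)
            residual = float(np.max(np.abs(deriv)) / flux_scale)
            return ODEState(cell_types=types, free=f, doublets=d, initial=init, residual=residual)
    d = _unpack(state, n)
    raise EquilibrationError(
        "doublet ODE did not reach equilibrium within max_time",
        ODEState(cell_types=types, free=free_of(state), doublets=d, initial=init),
    )


def model_interaction_scores(state: ODEState) -> pd.DataFrame:
    """Interaction scores from an equilibrium state, imaging-style.

    specific(A, B) = D_AB for A != B and 2 * D_AA for homotypic pairs;
    total = sum over cells of their contact counts (= 2x total doublets);
    cell-type fractions come from the conserved initial frequencies.
    score = specific / (f_A * f_B * total) — the identical formula applied
    to the microscopy cell tables, so model and data are comparable.
    """
    types = state.cell_types
    d = state.doublets
    total_doublets = np.triu(d).sum()
    if total_doublets <= 0:
        out = pd.DataFrame(np.nan, index=types, columns=types)
        out.attrs["undefined"] = True
        return out
    total_contacts = 2.0 * total_doublets
    frac = state.initial / state.initial.sum()
    n = len(types)
    scores = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            specific = 2.0 * d[i, i] if i == j else d[i, j]
            scores[i, j] = interaction_score_formula(
                specific, frac[i], frac[j], total_contacts
            )
    out = pd.DataFrame(scores, index=types, columns=types)
    out.attrs["undefined"] = False
    return out


def _pipeline_scores(
    expression: pd.DataFrame,
    network: InteractionNetwork,
    geometry: CellGeometry,
    config: ModelConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    radii = np.array([geometry.radius(t) for t in expression.index])
    dens = expression.div(4.0 * np.pi * radii**2, axis=0)
    aff = cell_pair_affinity(dens, network, config)
    state = integrate_doublets(aff, geometry, config)
    return aff, model_interaction_scores(state)


def perturb_protein(
    expression: pd.DataFrame,
    network: InteractionNetwork,
    geometry: CellGeometry,
    protein_id: str,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Signed score change (perturbed - baseline) after zeroing one protein.

    ``expression`` is cell_type x protein copies per cell.  The knockout
    zeroes the protein's expression in every cell type, then the full
    density -> affinity -> equilibrium -> score chain is recomputed.
    """
    config = config or ModelConfig()
    if protein_id not in expression.columns:
        raise KeyError(f"unknown protein: {protein_id!r}")
    _, base = _pipeline_scores(expression, network, geometry, config)
    ko = expression.copy()
    ko[protein_id] = 0.0
    _, pert = _pipeline_scores(ko, network, geometry, config)
    return pert - base


def rank_and_compare(
    predicted: dict[str, pd.DataFrame],
    measured: dict[str, pd.DataFrame],
    top_fraction: float = 1.0 / 3.0,
    eligibility_fraction: float = 0.2,
) -> pd.DataFrame:
    """Test whether model-predicted top perturbations show larger measured changes.

    Per protein, cell pairs in the top ``top_fraction`` by |predicted
    change| are compared to the remaining pairs on |measured change| by a
    one-sided Welch's t-test (alternative: top > rest).  Proteins whose
    prediction maximum falls below ``eligibility_fraction`` times the
    median prediction maximum across proteins are excluded.  p-values are
    Benjamini-Hochberg adjusted across the tested proteins.
    """
    from scipy import stats
    from statsmodels.stats.multitest import multipletests

    proteins = sorted(set(predicted) & set(measured))
    maxima = {p: float(np.nanmax(np.abs(predicted[p].to_numpy()))) for p in proteins}
    med_max = float(np.median(list(maxima.values()))) if maxima else 0.0
    rows = []
    for p in proteins:
        if maxima[p] < eligibility_fraction * med_max:
            rows.append({"protein": p, "status": "ineligible", "t": np.nan, "p": np.nan})
            continue
        pred = predicted[p]
        meas = measured[p]
        pairs = [
            (a, b)
            for i, a in enumerate(pred.index)
            for b in list(pred.columns)[i:]
            if a in meas.index and b in meas.columns
        ]
        pvals = np.array([abs(pred.loc[a, b]) for a, b in pairs])
        mvals = np.array([abs(meas.loc[a, b]) for a, b in pairs])
        n_top = max(int(round(top_fraction * len(pairs))), 1)
        order = np.argsort(-pvals, kind="stable")
        top_mask = np.zeros(len(pairs), dtype=bool)
        top_mask[order[:n_top]] = True
        if top_mask.sum() < 2 or (~top_mask).sum() < 2:
            rows.append({"protein": p, "status": "skipped", "t": np.nan, "p": np.nan})
            continue
        t, pval = stats.ttest_ind(
            mvals[top_mask], mvals[~top_mask], equal_var=False, alternative="greater"
        )
        rows.append({"protein": p, "status": "ok", "t": float(t), "p": float(pval)})
    result = pd.DataFrame(rows, columns=["protein", "status", "t", "p"])
    ok = result["status"] == "ok"
    result["p_bh"] = np.nan
    if ok.any():
        result.loc[ok, "p_bh"] = multipletests(result.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    return result
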