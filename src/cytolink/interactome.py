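"""Interactome x expression integration.

Binarizes expression matrices, enumerates the per-cell-pair interaction
key, summarizes affinity distributions, tests for activation-driven
affinity switching, and computes eigenvector centralities of the
cell-type interaction graph.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .screen import _pair_key
from .synthetic import ExpressionSet

__all__ = [
    "InteractionNetwork",
    "CentralityResult",
    "binarize_expression",
    "build_interaction_key",
    "affinity_profile",
    "differential_proteins",
    "affinity_switch_test",
    "interaction_count_matrix",
    "eigenvector_centrality",
    "centrality_group_test",
]


@dataclass
class InteractionNetwork:
    """Undirected protein-pair network with optional per-edge affinity."""

    edges: pd.DataFrame  # columns: protein_a, protein_b, kd_molar (NaN ok), provenance

    def __post_init__(self) -> None:
        df = self.edges.copy()
        for col in ("protein_a", "protein_b"):
            if col not in df.columns:
                raise ValueError(f"network edge table lacks column {col!r}")
        if "kd_molar" not in df.columns:
            df["kd_molar"] = np.nan
        if "provenance" not in df.columns:
            df["provenance"] = "screen"
        keys = [
            _pair_key(a, b) for a, b in zip(df["protein_a"], df["protein_b"])
        ]
        df["protein_a"] = [k[0] for k in keys]
        df["protein_b"] = [k[1] for k in keys]
        if df.duplicated(subset=["protein_a", "protein_b"]).any():
            raise ValueError("duplicate edges in interaction network")
        kd = df["kd_molar"].to_numpy(dtype=float)
        if np.any(kd[~np.isnan(kd)] <= 0):
            raise ValueError("K_D values must be positive where present")
        self.edges = df.reset_index(drop=True)

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.edges["protein_a"], self.edges["protein_b"]))

    @property
    def proteins(self) -> set[str]:
        return set(self.edges["protein_a"]) | set(self.edges["protein_b"])

    def kd_of(self, pair: tuple[str, str]) -> float:
        a, b = _pair_key(*pair)
        m = (self.edges["protein_a"] == a) & (self.edges["protein_b"] == b)
        if not m.any():
            raise KeyError(pair)
        return float(self.edges.loc[m, "kd_molar"].iloc[0])


@dataclass
class CentralityResult:
    centrality: pd.Series  # cell_type -> max-normalized eigenvector centrality
    eigenvalue: float
    isolated: list[str] = field(default_factory=list)


def binarize_expression(
    expr: ExpressionSet | pd.DataFrame,
    modality: str | None = None,
    sc_threshold: float = 0.10,
) -> pd.DataFrame:
    """Convert expression to a boolean cell_type x protein detection matrix.

    Single-cell input (detection fractions): detected iff fraction >=
    ``sc_threshold``.  Bulk replicate input: detected iff strictly more
    than half of the replicates have a nonzero measurement.
    """
    if isinstance(expr, ExpressionSet):
        modality = modality or expr.modality
        values = expr.values
    else:
        values = expr
    if modality == "single-cell":
        frac = values
        if (frac.to_numpy() < 0).any() or (frac.to_numpy() > 1).any():
            raise ValueError("single-cell detection fractions must be in [0, 1]")
        return frac >= sc_threshold
    if modality == "bulk-replicates":
        if not isinstance(values.index, pd.MultiIndex):
            raise ValueError("bulk expression needs a (cell_type, replicate) index")
        nonzero = (values > 0).groupby(level="cell_type", sort=True).mean()
        return nonzero > 0.5
    raise ValueError(f"unknown expression modality: {modality!r}")


def build_interaction_key(
    binarized: pd.DataFrame,
    network: InteractionNetwork,
    id_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Enumerate detected molecular interactions for every cell-type pair.

    For each unordered cell pair (A, B) including A == A and each network
    edge (p, q), a row is emitted whenever p is detected on A and q on B
    or vice versa; both orientation flags are recorded so asymmetric
    detections remain distinguishable.  Unmapped network proteins are
    reported in the ``unmapped`` attribute of the result, never silently
    dropped.
    """
    if id_map:
        binarized = binarized.rename(columns=dict(id_map))
    cell_types = sorted(binarized.index)
    known = set(binarized.columns)
    unmapped = sorted(network.proteins - known)

    rows = []
    edge_iter = list(
        zip(
            network.edges["protein_a"],
            network.edges["protein_b"],
            network.edges["kd_molar"],
        )
    )
    if not edge_iter:
        warnings.warn("empty interaction network: emitting empty key")
    det = binarized.to_dict(orient="index")
    n_types = len(cell_types)
    for i in range(n_types):
        for j in range(i, n_types):
            a_type, b_type = cell_types[i], cell_types[j]
            for p, q, kd in edge_iter:
                if p not in known or q not in known:
                    continue
                fwd = bool(det[a_type][p]) and bool(det[b_type][q])
                rev = bool(det[a_type][q]) and bool(det[b_type][p])
                if fwd or rev:
                    ubiquitous = bool(
                        binarized[p].all() and binarized[q].all()
                    )
                    rows.append(
                        {
                            "cell_type_a": a_type,
                            "cell_type_b": b_type,
                            "protein_a": p,
                            "protein_b": q,
                            "detected_a_to_b": fwd,
                            "detected_b_to_a": rev,
                            "kd_molar": kd,
                            "ubiquitous": ubiquitous,
                        }
                    )
    key = pd.DataFrame(
        rows,
        columns=[
            "cell_type_a",
            "cell_type_b",
            "protein_a",
            "protein_b",
            "detected_a_to_b",
            "detected_b_to_a",
            "kd_molar",
            "ubiquitous",
        ],
    )
    key.attrs["unmapped"] = unmapped
    return key


def affinity_profile(
    key: pd.DataFrame,
    cell_pair: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per cell-pair affinity summary: K_D list, log-scale and arithmetic mean.

    Each detected interaction contributes one K_D entry; a protein that
    participates in several interactions contributes one entry per
    interaction.  Rows lacking a K_D annotation are ignored; an empty
    profile is flagged via ``n = 0``.
    """
    df = key.dropna(subset=["kd_molar"])
    if cell_pair is not None:
        a, b = sorted(cell_pair)
        df = df[(df["cell_type_a"] == a) & (df["cell_type_b"] == b)]
    out = []
    for (a, b), grp in df.groupby(["cell_type_a", "cell_type_b"], sort=True):
        kds = grp["kd_molar"].to_numpy(dtype=float)
        out.append(
            {
                "cell_type_a": a,
                "cell_type_b": b,
                "n": len(kds),
                "mean_kd_molar": float(np.mean(kds)),
                "log_mean_kd_molar": float(10.0 ** np.mean(np.log10(kds))),
                "kd_values": list(kds),
            }
        )
    cols = ["cell_type_a", "cell_type_b", "n", "mean_kd_molar", "log_mean_kd_molar", "kd_values"]
    return pd.DataFrame(out, columns=cols)


def differential_proteins(
    resting: ExpressionSet,
    activated: ExpressionSet,
    fold_threshold: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Classify proteins as up/down-regulated on activation per cell type.

    Fold change = (mean activated + pseudocount) / (mean resting +
    pseudocount) on counts; proteins with fold change > threshold are
    "up", those with fold change < 1/threshold are "down".
    """
    if fold_threshold <= 0:
        raise ValueError("fold_threshold must be positive")
    r = resting.mean_by_cell_type()
    a = activated.mean_by_cell_type()
    common_ct = r.index.intersection(a.index)
    common_p = r.columns.intersection(a.columns)
    if common_ct.empty:
        raise ValueError("no cell types shared between resting and activated data")
    fc = (a.loc[common_ct, common_p] + pseudocount) / (r.loc[common_ct, common_p] + pseudocount)
    rows = []
    for ct in common_ct:
        for p in common_p:
            f = fc.loc[ct, p]
            if f > fold_threshold:
                direction = "up"
            elif f < 1.0 / fold_threshold:
                direction = "down"
            else:
                continue
            rows.append({"cell_type": ct, "protein": p, "fold_change": float(f), "direction": direction})
    return pd.DataFrame(rows, columns=["cell_type", "protein", "fold_change", "direction"])


def affinity_switch_test(
    resting: ExpressionSet,
    activated: ExpressionSet,
    network: InteractionNetwork,
    fold_threshold: float = 2.0,
) -> pd.DataFrame:
    """Welch's t-test on log10 K_D of up- vs down-regulated interactions.

    Each differentially regulated protein contributes the K_D of every
    interaction it participates in.  Per cell type a two-sided Welch's
    t-test compares the up and down affinity pools on the log10 scale;
    p-values are Holm-adjusted across cell types.  Cell types with fewer
    than two values in either pool are reported with status "skipped".
    """
    diff = differential_proteins(resting, activated, fold_threshold=fold_threshold)
    kd_by_protein: dict[str, list[float]] = {}
    for (a, b), kd in zip(network.pairs, network.edges["kd_molar"]):
        if np.isnan(kd):
            continue
        kd_by_protein.setdefault(a, []).append(float(kd))
        if b != a:
            kd_by_protein.setdefault(b, []).append(float(kd))

    rows = []
    cell_types = sorted(resting.mean_by_cell_type().index.intersection(
        activated.mean_by_cell_type().index))
    for ct in cell_types:
        sub = diff[diff["cell_type"] == ct]
        up = [kd for p in sub.loc[sub["direction"] == "up", "protein"] for kd in kd_by_protein.get(p, [])]
        down = [kd for p in sub.loc[sub["direction"] == "down", "protein"] for kd in kd_by_protein.get(p, [])]
        row = {
            "cell_type": ct,
            "n_up": len(up),
            "n_down": len(down),
            "up_kd": up,
            "down_kd": down,
        }
        if len(up) < 2 or len(down) < 2:
            row.update({"status": "skipped", "t": np.nan, "p": np.nan})
        elif np.ptp(np.log10(up + down)) == 0:
            # identical constant pools: no shift, by convention t=0, p=1
            row.update({"status": "ok", "t": 0.0, "p": 1.0})
        else:
            t, p = stats.ttest_ind(np.log10(up), np.log10(down), equal_var=False)
            row.update({"status": "ok", "t": float(t), "p": float(p)})
        rows.append(row)
    result = pd.DataFrame(rows)
    tested = result["status"] == "ok"
    result["p_holm"] = np.nan
    if tested.any():
        result.loc[tested, "p_holm"] = multipletests(
            result.loc[tested, "p"].to_numpy(), method="holm"
        )[1]
    return result


def interaction_count_matrix(key: pd.DataFrame) -> pd.DataFrame:
    """Symmetric cell_type x cell_type matrix of detected interaction counts."""
    types = sorted(set(key["cell_type_a"]) | set(key["cell_type_b"]))
    mat = pd.DataFrame(0.0, index=types, columns=types)
    for (a, b), grp in key.groupby(["cell_type_a", "cell_type_b"]):
        mat.loc[a, b] += len(grp)
        if a != b:
            mat.loc[b, a] += len(grp)
    return mat


def eigenvector_centrality(
    weights: pd.DataFrame,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> CentralityResult:
    """Principal-eigenvector centrality of a weighted undirected graph.

    Power iteration on the symmetric weight matrix; the returned vector is
    normalized so its maximum entry is 1.  Nodes disconnected from the
    dominant component get centrality 0 and are listed as isolated.
    """
    w = weights.to_numpy(dtype=float)
    if not np.allclose(w, w.T):
        raise ValueError("weight matrix must be symmetric")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    n = w.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        nxt = w @ v
        norm = np.linalg.norm(nxt)
        if norm == 0:
            break
        nxt /= norm
        if np.linalg.norm(nxt - v) < tol:
            v = nxt
            lam = float(v @ w @ v)
            break
        v = nxt
    else:
        lam = float(v @ w @ v)
    lam = float(v @ w @ v)
    v = np.abs(v)
    vmax = v.max()
    if vmax > 0:
        v = v / vmax
    isolated = [weights.index[i] for i in range(n) if w[i].sum() == 0]
    if isolated:
        warnings.warn(f"isolated nodes with zero centrality: {isolated}")
        for node in isolated:
            v[weights.index.get_loc(node)] = 0.0
    return CentralityResult(
        centrality=pd.Series(v, index=weights.index),
        eigenvalue=lam,
        isolated=isolated,
    )


def centrality_group_test(
    per_tissue_centrality: Mapping[str, pd.Series],
    group_members: Iterable[str],
) -> pd.DataFrame:
    """Welch's t-test of one node group vs the rest, per tissue, BH-adjusted."""
    members = set(group_members)
    rows = []
    for tissue, cent in per_tissue_centrality.items():
        in_group = cent[cent.index.isin(members)].to_numpy()
        out_group = cent[~cent.index.isin(members)].to_numpy()
        if len(in_group) < 2 or len(out_group) < 2:
            rows.append({"tissue": tissue, "t": np.nan, "p": np.nan, "status": "skipped"})
            continue
        t, p = stats.ttest_ind(in_group, out_group, equal_var=False)
        rows.append({"tissue": tissue, "t": float(t), "p": float(p), "status": "ok"})
    result = pd.DataFrame(rows)
    ok = result["status"] == "ok"
    result["p_bh"] = np.nan
    if ok.any():
        result.loc[ok, "p_bh"] = multipletests(result.loc[ok, "p"].to_numpy(), method="fdr_bh")[1]
    return result
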