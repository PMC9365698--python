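"""Delimited-text readers and writers for the package's standard tables.

All on-disk formats are TSV (with "NA" for missing values) plus JSON
sidecars, so fixtures and outputs stay plain text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .interactome import InteractionNetwork
from .kinetics import CellGeometry
from .screen import SignalMatrix
from .synthetic import ExpressionSet, GroundTruth, SpotGrid

NA = "NA"


def read_signal_matrix(path: str | Path, phase: str = "primary") -> SignalMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[NA])
    return SignalMatrix(values=df.astype(float), phase=phase)


def write_signal_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", na_rep=NA)


def read_network(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return InteractionNetwork(edges=df)


def write_network(network: InteractionNetwork, path: str | Path) -> None:
    network.edges.to_csv(path, sep="\t", index=False, na_rep=NA)


def read_expression(path: str | Path, manifest_path: str | Path | None = None) -> ExpressionSet:
    """Expression TSV with cell_type and replicate columns; manifest JSON
    declares modality and state."""
    df = pd.read_csv(path, sep="\t")
    modality, state = "bulk-replicates", None
    if manifest_path is not None:
        manifest = json.loads(Path(manifest_path).read_text())
        modality = manifest.get("modality", modality)
        state = manifest.get("state")
    if "replicate" in df.columns:
        df = df.set_index(["cell_type", "replicate"])
    else:
        df = df.set_index("cell_type")
    return ExpressionSet(values=df, modality=modality, state=state)


def write_expression(expr: ExpressionSet, path: str | Path, manifest_path: str | Path | None = None) -> None:
    expr.values.reset_index().to_csv(path, sep="\t", index=False, na_rep=NA)
    if manifest_path is not None:
        Path(manifest_path).write_text(
            json.dumps({"modality": expr.modality, "state": expr.state}, indent=2)
        )


def read_geometry(path: str | Path) -> CellGeometry:
    df = pd.read_csv(path, sep="\t").set_index("cell_type")
    return CellGeometry(table=df)


def write_geometry(geometry: CellGeometry, path: str | Path) -> None:
    geometry.table.reset_index().to_csv(path, sep="\t", index=False)


def read_spot_grid(spots_path: str | Path, counts_path: str | Path) -> SpotGrid:
    spots = pd.read_csv(spots_path, sep="\t", index_col=0)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0).astype(int)
    mito = {g for g in counts.columns if g.startswith("MT-")}
    return SpotGrid(spots=spots, counts=counts, mito_genes=mito)


def write_spot_grid(grid: SpotGrid, spots_path: str | Path, counts_path: str | Path) -> None:
    grid.spots.to_csv(spots_path, sep="\t")
    grid.counts.to_csv(counts_path, sep="\t")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "true_pairs": sorted(map(list, truth.true_pairs)),
        "promiscuous_proteins": sorted(truth.promiscuous_proteins),
        "planted_kd": {f"{a}|{b}": kd for (a, b), kd in sorted(truth.planted_kd.items())},
        "planted_cell_preferences": {
            f"{a}|{b}": v for (a, b), v in sorted(truth.planted_cell_preferences.items())
        },
        "zonated_pairs": sorted(map(list, truth.zonated_pairs)),
        "regulated_proteins": dict(sorted(truth.regulated_proteins.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        true_pairs={tuple(p) for p in payload.get("true_pairs", [])},
        promiscuous_proteins=set(payload.get("promiscuous_proteins", [])),
        planted_kd={
            tuple(k.split("|")): float(v) for k, v in payload.get("planted_kd", {}).items()
        },
        planted_cell_preferences={
            tuple(k.split("|")): float(v)
            for k, v in payload.get("planted_cell_preferences", {}).items()
        },
        zonated_pairs={tuple(p) for p in payload.get("zonated_pairs", [])},
        regulated_proteins=payload.get("regulated_proteins", {}),
    )
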