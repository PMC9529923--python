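"""TSV readers and writers for networks, designs, expression, and predictions.

Dense matrices are written with a gene-id header row and a gene-id index
column; experiment columns are labelled with the perturbed gene and the
replicate index (``G17_r2``).  Edge lists carry (regulator, target, weight)
triples — note the regulator-first column order, while in-memory matrices
index ``[target, regulator]``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .networks import Network
from .pbased import ScoredGRN
from .simulate import ExpressionMatrix, PerturbationDesign

__all__ = [
    "write_network_tsv",
    "read_network_tsv",
    "write_edge_list_tsv",
    "read_edge_list_tsv",
    "write_design_tsv",
    "read_design_tsv",
    "write_expression_tsv",
    "read_expression_tsv",
    "write_scored_grn",
]


def write_network_tsv(network: Network, path: str | Path) -> None:
    df = pd.DataFrame(network.weights, index=network.gene_ids, columns=network.gene_ids)
    df.to_csv(path, sep="\t")


def read_network_tsv(path: str | Path) -> Network:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return Network(weights=df.to_numpy(dtype=float), gene_ids=[str(g) for g in df.index])


def write_edge_list_tsv(network: Network, path: str | Path) -> None:
    rows, cols = np.nonzero(network.weights)
    df = pd.DataFrame(
        {
            "source": [network.gene_ids[j] for j in cols],
            "target": [network.gene_ids[i] for i in rows],
            "weight": network.weights[rows, cols],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_edge_list_tsv(path: str | Path, gene_ids: list[str] | None = None) -> Network:
    """Rebuild a dense network from an edge list.

    Without an explicit ``gene_ids`` the gene set is the sorted union of the
    sources and targets seen, so isolated genes are only preserved when the
    caller supplies the full id list.
    """
    df = pd.read_csv(path, sep="\t")
    if gene_ids is None:
        gene_ids = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    index = {g: k for k, g in enumerate(gene_ids)}
    weights = np.zeros((len(gene_ids), len(gene_ids)))
    for source, target, weight in df.itertuples(index=False):
        weights[index[str(target)], index[str(source)]] = weight
    return Network(weights=weights, gene_ids=list(gene_ids))


def _experiment_columns(design: PerturbationDesign, gene_ids: list[str] | None) -> list[str]:
    return design.experiment_ids(gene_ids)


def write_design_tsv(
    design: PerturbationDesign, path: str | Path, gene_ids: list[str] | None = None
) -> None:
    names = gene_ids or [f"G{i + 1}" for i in range(design.n_genes)]
    df = pd.DataFrame(design.matrix, index=names, columns=_experiment_columns(design, names))
    df.to_csv(path, sep="\t")


def read_design_tsv(path: str | Path, replicate_count: int | None = None) -> PerturbationDesign:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if replicate_count is None:
        # infer from the experiment labels when they follow the G<g>_r<k> scheme
        reps = [int(c.rsplit("_r", 1)[1]) for c in df.columns if "_r" in c]
        replicate_count = max(reps) if reps else 1
    return PerturbationDesign(matrix=df.to_numpy(dtype=float), replicate_count=replicate_count)


def write_expression_tsv(
    expression: ExpressionMatrix,
    path: str | Path,
    design: PerturbationDesign | None = None,
    gene_ids: list[str] | None = None,
) -> None:
    names = gene_ids or [f"G{i + 1}" for i in range(expression.n_genes)]
    if design is not None:
        columns = _experiment_columns(design, names)
    else:
        columns = [f"E{j + 1}" for j in range(expression.n_experiments)]
    pd.DataFrame(expression.values, index=names, columns=columns).to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path, role: str = "noisy") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.to_numpy(dtype=float), role=role)


def write_scored_grn(
    grn: ScoredGRN, out_prefix: str | Path, gene_ids: list[str] | None = None
) -> list[Path]:
    """Write a prediction as dense matrix TSV + ranked edge list (or sweep TSVs).

    Returns the list of files written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    n = grn.n_genes
    names = gene_ids or [f"G{i + 1}" for i in range(n)]
    if grn.dense_weights is not None:
        dense_path = out_prefix.with_suffix(".matrix.tsv")
        pd.DataFrame(grn.dense_weights, index=names, columns=names).to_csv(dense_path, sep="\t")
        written.append(dense_path)
        rows, cols = np.nonzero(grn.dense_weights)
        scores = np.abs(grn.dense_weights[rows, cols])
        order = np.argsort(-scores, kind="stable")
        ranked = pd.DataFrame(
            {
                "source": [names[j] for j in cols[order]],
                "target": [names[i] for i in rows[order]],
                "score": scores[order],
            }
        )
        ranked_path = out_prefix.with_suffix(".edges.tsv")
        ranked.to_csv(ranked_path, sep="\t", index=False)
        written.append(ranked_path)
    else:
        for k, (pen, net) in enumerate(zip(grn.penalties, grn.sweep)):
            rows, cols = np.nonzero(net)
            df = pd.DataFrame(
                {
                    "source": [names[j] for j in cols],
                    "target": [names[i] for i in rows],
                    "penalty": pen,
                }
            )
            sweep_path = out_prefix.with_suffix(f".sweep{k:02d}.tsv")
            df.to_csv(sweep_path, sep="\t", index=False)
            written.append(sweep_path)
    return written
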