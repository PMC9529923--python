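"""Known-target perturbation extraction from DREAM5-style tables.

The DREAM5 expression compendia ship as a chips-by-genes expression table
plus a "chip features" table annotating each chip with its experiment group
and any perturbation (``DeletedGenes`` for knockouts, ``OverexpressedGenes``
for overexpression, free-text knockdown/treatment columns).  The extraction
keeps only chips whose perturbation names a single gene present in the
expression table, computes per-gene fold changes against the *within-group*
average of the unperturbed (control) chips, and assembles the matching
design matrix: ``-1`` for deletions, ``+1`` for overexpression.  Knockdown
chips are dropped — their targets are not specified — as are multi-gene
perturbations and chips whose group has no control.

A fixture generator emulates the format with analytically known outputs so
the logic is fully testable offline; the real DREAM5 download is an
optional, external input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ExpressionMatrix, PerturbationDesign

__all__ = [
    "ChipFeatureTable",
    "read_dream5_expression",
    "read_chip_features",
    "extract_known_target_subset",
    "make_dream5_fixture",
]

logger = logging.getLogger(__name__)

_DELETION = "DeletedGenes"
_OVEREXPRESSION = "OverexpressedGenes"
_KNOCKDOWN = "KnockdownGenes"
_GROUP = "Experiment"


@dataclass
class ChipFeatureTable:
    """Chip annotations keyed by chip id; wraps the DREAM5 'chip features' TSV."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if _GROUP not in self.table.columns:
            raise ValueError(f"chip feature table needs an '{_GROUP}' column")
        for col in (_DELETION, _OVEREXPRESSION):
            if col not in self.table.columns:
                self.table[col] = ""
        self.table = self.table.fillna("")

    @property
    def chip_ids(self) -> list[str]:
        return [str(c) for c in self.table.index]


def read_dream5_expression(path: str | Path) -> pd.DataFrame:
    """Read a chips-by-genes expression TSV into a genes-by-chips frame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def read_chip_features(path: str | Path) -> ChipFeatureTable:
    return ChipFeatureTable(table=pd.read_csv(path, sep="\t", index_col=0, dtype=str))


def _single_target(entry: str) -> str | None:
    """Gene name if the annotation names exactly one gene, else None."""
    entry = (entry or "").strip()
    if not entry:
        return None
    if "," in entry:
        return "MULTI"
    return entry


def extract_known_target_subset(
    expression: pd.DataFrame,
    features: ChipFeatureTable,
    genes: str = "all",
) -> tuple[ExpressionMatrix, PerturbationDesign, list[str]]:
    """Fold-change matrix and design for the known-target perturbation chips.

    Parameters
    ----------
    expression : DataFrame, genes x chips.
    features : ChipFeatureTable with one row per chip.
    genes : "all" keeps every measured gene as a row; "perturbed" restricts
        the rows to the union of perturbation targets.

    Returns the fold-change :class:`ExpressionMatrix` (perturbed chip minus
    the within-group control mean), the matching design (one ``-1`` or
    ``+1`` per column) and the retained gene ids.
    """
    if genes not in ("all", "perturbed"):
        raise ValueError("genes must be 'all' or 'perturbed'")
    feat = features.table
    measured = [str(g) for g in expression.index]
    gene_pos = {g: i for i, g in enumerate(measured)}

    aux_cols = [
        c for c in feat.columns if c not in (_GROUP, _DELETION, _OVEREXPRESSION)
    ]

    def _is_control(row: pd.Series) -> bool:
        if _single_target(row[_DELETION]) or _single_target(row[_OVEREXPRESSION]):
            return False
        return not any(str(row[c]).strip() for c in aux_cols)

    controls_by_group: dict[str, list[str]] = {}
    for chip, row in feat.iterrows():
        if _is_control(row):
            controls_by_group.setdefault(str(row[_GROUP]), []).append(str(chip))

    kept_chips: list[str] = []
    kept_targets: list[str] = []
    kept_signs: list[float] = []
    fold_columns: list[np.ndarray] = []
    for chip, row in feat.iterrows():
        chip = str(chip)
        deletion = _single_target(row[_DELETION])
        overexpr = _single_target(row[_OVEREXPRESSION])
        if deletion is None and overexpr is None:
            continue  # control or knockdown-only chip: not a known-target perturbation
        if deletion and overexpr:
            logger.warning("chip %s lists both deletion and overexpression; dropped", chip)
            continue
        target, sign = (deletion, -1.0) if deletion else (overexpr, +1.0)
        if target == "MULTI":
            logger.warning("chip %s has a multi-gene perturbation; dropped", chip)
            continue
        if target not in gene_pos:
            logger.warning("chip %s targets %s, absent from expression; dropped", chip, target)
            continue
        group_controls = controls_by_group.get(str(row[_GROUP]), [])
        if not group_controls:
            logger.warning("chip %s has no control in group %s; dropped", chip, row[_GROUP])
            continue
        baseline = expression[group_controls].mean(axis=1)
        fold_columns.append((expression[chip] - baseline).to_numpy(dtype=float))
        kept_chips.append(chip)
        kept_targets.append(target)
        kept_signs.append(sign)

    if genes == "perturbed":
        kept_genes = sorted(set(kept_targets), key=gene_pos.get)
    else:
        kept_genes = measured
    row_pos = {g: i for i, g in enumerate(kept_genes)}
    keep_rows = [gene_pos[g] for g in kept_genes]

    values = (
        np.column_stack(fold_columns)[keep_rows]
        if fold_columns
        else np.zeros((len(kept_genes), 0))
    )
    design = np.zeros((len(kept_genes), len(kept_chips)))
    for e, (target, sign) in enumerate(zip(kept_targets, kept_signs)):
        design[row_pos[target], e] = sign

    return (
        ExpressionMatrix(values=values, role="noisy"),
        PerturbationDesign(matrix=design, replicate_count=1),
        kept_genes,
    )


def make_dream5_fixture(
    n_genes: int = 8,
    n_groups: int = 3,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, ChipFeatureTable, dict]:
    """Synthetic DREAM5-layout fixture with analytically known extraction output.

    Each experiment group gets two control chips plus (cycling by group) a
    deletion chip, an overexpression chip, or a knockdown-only chip that the
    extraction must drop.  Returns the genes-by-chips expression frame, the
    feature table, and the expected fold changes / design / gene list
    computed directly from the construction.  With ``out_dir`` the two
    tables are also written in the on-disk dialect (chips as rows).
    """
    if n_genes < 2 or n_groups < 1:
        raise ValueError("need at least 2 genes and 1 group")
    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1}" for i in range(n_genes)]

    chips: list[str] = []
    rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    expected_cols: list[np.ndarray] = []
    expected_targets: list[tuple[str, float]] = []

    for g in range(n_groups):
        group = str(g + 1)
        control_vals = [rng.normal(size=n_genes), rng.normal(size=n_genes)]
        for c, vals in enumerate(control_vals):
            chip = f"chip_g{group}_ctrl{c + 1}"
            chips.append(chip)
            rows.append({"chip": chip, _GROUP: group, _DELETION: "", _OVEREXPRESSION: "",
                         _KNOCKDOWN: ""})
            columns[chip] = vals
        baseline = np.mean(control_vals, axis=0)
        kind = g % 3  # 0: deletion, 1: overexpression, 2: knockdown (dropped)
        target = gene_ids[int(rng.integers(n_genes))]
        shift = rng.normal(scale=2.0, size=n_genes)
        chip = f"chip_g{group}_pert"
        chips.append(chip)
        columns[chip] = baseline + shift
        if kind == 0:
            rows.append({"chip": chip, _GROUP: group, _DELETION: target,
                         _OVEREXPRESSION: "", _KNOCKDOWN: ""})
            expected_cols.append(shift)
            expected_targets.append((target, -1.0))
        elif kind == 1:
            rows.append({"chip": chip, _GROUP: group, _DELETION: "",
                         _OVEREXPRESSION: target, _KNOCKDOWN: ""})
            expected_cols.append(shift)
            expected_targets.append((target, +1.0))
        else:
            rows.append({"chip": chip, _GROUP: group, _DELETION: "",
                         _OVEREXPRESSION: "", _KNOCKDOWN: target})

    expression = pd.DataFrame(columns, index=gene_ids)
    feat = pd.DataFrame(rows).set_index("chip").astype(str)
    features = ChipFeatureTable(table=feat)

    expected_design = np.zeros((n_genes, len(expected_targets)))
    for e, (target, sign) in enumerate(expected_targets):
        expected_design[gene_ids.index(target), e] = sign
    expected = {
        "fold_change": (
            np.column_stack(expected_cols) if expected_cols else np.zeros((n_genes, 0))
        ),
        "design": expected_design,
        "gene_ids": gene_ids,
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        expression.T.to_csv(out_dir / "expression.tsv", sep="\t")
        feat.to_csv(out_dir / "chip_features.tsv", sep="\t")
    return expression, features, expected
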