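"""Orchestration of the full simulate–infer–evaluate study.

One benchmark run generates ``n_networks`` independent gold-standard
networks, builds the single-knockdown design, simulates noise-free steady
states, adds calibrated noise at each SNR level, runs every configured
estimator on every dataset, and evaluates each prediction with the
category-appropriate selfloop policy.  Optionally each design-based
estimator is additionally run against a deranged (scrambled) design — the
negative control showing that the design matrix, not the expression alone,
carries the causal signal.

All randomness derives from ``master_seed`` through fixed per-stage
``SeedSequence`` spawn keys, so a report is reproducible cell-by-cell and
independent of which other methods are configured.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .metrics import EvaluationResult, evaluate, jaccard, true_fraction
from .networks import Network, generate_scale_free_network
from .nonpbased import infer_clr, infer_tree_ensemble
from .pbased import (
    DEFAULT_PENALTIES,
    ScoredGRN,
    infer_least_squares,
    infer_penalized,
    infer_zscore,
)
from .simulate import (
    ExpressionMatrix,
    NoiseSpec,
    PerturbationDesign,
    add_noise,
    make_single_knockdown_design,
    scramble_design,
    simulate_steady_state,
)

__all__ = [
    "BenchmarkConfig",
    "BenchmarkReport",
    "CellResult",
    "METHOD_CATEGORIES",
    "run_benchmark",
    "similarity_analysis",
]

logger = logging.getLogger(__name__)

METHOD_CATEGORIES: dict[str, str] = {
    "least_squares": "p_based",
    "lasso": "p_based",
    "elastic_net": "p_based",
    "ridge": "p_based",
    "zscore": "p_based",
    "tree_ensemble": "non_p_based",
    "clr": "non_p_based",
}

#: L1/L2 mixing weights of the penalized design-based estimators.
PENALIZED_MIXING = {"lasso": 1.0, "elastic_net": 0.7, "ridge": 0.0}


@dataclass
class BenchmarkConfig:
    """Study conditions; the defaults are the benchmark's standard profile."""

    n_networks: int = 5
    n_genes: int = 100
    avg_links_per_node: float = 3.0
    replicates: int = 3
    snr_levels: tuple[float, ...] = (0.01, 0.1, 1.0)
    alpha: float = 0.01  # 1 - alpha = 99% confidence in the SNR calibration
    methods: tuple[str, ...] = tuple(METHOD_CATEGORIES)
    n_trees: int = 1000
    clr_bins: int = 10
    penalties: tuple[float, ...] | None = None
    master_seed: int = 0
    selfloop_mode: str = "policy"  # "policy" | "strip_all"
    scramble_control: bool = False
    transpose_nonp: bool = False
    noise_free: bool = False  # override: evaluate on X itself (sanity profile)

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be at least 1")
        if any(s <= 0 for s in self.snr_levels):
            raise ValueError("snr_levels must be positive")
        unknown = set(self.methods) - set(METHOD_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def penalty_vector(self) -> np.ndarray:
        if self.penalties is None:
            return DEFAULT_PENALTIES
        return np.asarray(self.penalties, dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BenchmarkConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        for key in ("snr_levels", "methods", "penalties"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["snr_levels"] = list(self.snr_levels)
        out["methods"] = list(self.methods)
        if out["penalties"] is not None:
            out["penalties"] = list(out["penalties"])
        return out


@dataclass
class CellResult:
    """Outcome of one (network, SNR, method, design-variant) grid cell."""

    network_index: int
    snr: float
    method: str
    variant: str  # "intact" | "scrambled"
    category: str
    result: EvaluationResult | None = None
    error: str | None = None
    walltime: float = 0.0

    @property
    def failed(self) -> bool:
        return self.result is None


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    cells: list[CellResult] = field(default_factory=list)
    networks: list[Network] = field(default_factory=list)

    def cell(
        self, network_index: int, snr: float, method: str, variant: str = "intact"
    ) -> CellResult:
        for c in self.cells:
            if (
                c.network_index == network_index
                and c.snr == snr
                and c.method == method
                and c.variant == variant
            ):
                return c
        raise KeyError((network_index, snr, method, variant))

    def auprs(self, method: str, snr: float, variant: str = "intact") -> list[float]:
        return [
            c.result.aupr
            for c in self.cells
            if c.method == method and c.snr == snr and c.variant == variant and not c.failed
        ]

    def mean_aupr(self, method: str, snr: float, variant: str = "intact") -> float:
        values = self.auprs(method, snr, variant)
        if not values:
            raise ValueError(f"no successful cells for {method} at snr={snr} ({variant})")
        return float(np.mean(values))

    @property
    def any_failed(self) -> bool:
        return any(c.failed for c in self.cells)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {
                "network": c.network_index,
                "snr": c.snr,
                "method": c.method,
                "variant": c.variant,
                "category": c.category,
                "failed": c.failed,
                "walltime_s": c.walltime,
            }
            if not c.failed:
                row.update(
                    aupr=c.result.aupr,
                    auroc=c.result.auroc,
                    max_f1=c.result.max_f1,
                    max_mcc=c.result.max_mcc,
                )
            else:
                row["error"] = c.error
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Deterministic JSON (wall times excluded so equal seeds give equal bytes)."""
        rows = []
        for c in sorted(
            self.cells, key=lambda c: (c.network_index, c.snr, c.method, c.variant)
        ):
            entry = {
                "network": c.network_index,
                "snr": c.snr,
                "method": c.method,
                "variant": c.variant,
                "category": c.category,
                "failed": c.failed,
            }
            if c.failed:
                entry["error"] = c.error
            else:
                entry.update(
                    aupr=c.result.aupr,
                    auroc=c.result.auroc,
                    max_f1=c.result.max_f1,
                    max_mcc=c.result.max_mcc,
                    n_max_f1_edges=len(c.result.max_f1_edges),
                )
            rows.append(entry)
        return json.dumps({"config": self.config.to_dict(), "cells": rows}, sort_keys=True)


def _stage_seed(master_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence((master_seed, *key)).generate_state(1)[0] % (2**31 - 1))


def _infer_one(
    name: str,
    y: ExpressionMatrix,
    design: PerturbationDesign,
    config: BenchmarkConfig,
    seed: int,
) -> ScoredGRN:
    if name == "least_squares":
        return infer_least_squares(y, design)
    if name in PENALIZED_MIXING:
        return infer_penalized(y, design, PENALIZED_MIXING[name], config.penalty_vector)
    if name == "zscore":
        return infer_zscore(y, design)
    if name == "tree_ensemble":
        return infer_tree_ensemble(y, config.n_trees, seed, config.transpose_nonp)
    if name == "clr":
        return infer_clr(y, config.clr_bins)
    raise ValueError(f"unknown method {name!r}")


def _run_cell(
    report: BenchmarkReport,
    gold: Network,
    y: ExpressionMatrix,
    design: PerturbationDesign,
    config: BenchmarkConfig,
    net_idx: int,
    snr: float,
    method: str,
    variant: str,
    seed: int,
) -> None:
    cell = CellResult(
        network_index=net_idx,
        snr=snr,
        method=method,
        variant=variant,
        category=METHOD_CATEGORIES[method],
    )
    start = time.perf_counter()
    try:
        grn = _infer_one(method, y, design, config, seed)
        cell.result = evaluate(gold, grn, config.selfloop_mode)
    except Exception as exc:  # noqa: BLE001 — one estimator must not abort the study
        cell.error = f"{type(exc).__name__}: {exc}"
        logger.exception("cell failed: net=%d snr=%s method=%s (%s)", net_idx, snr, method, variant)
    cell.walltime = time.perf_counter() - start
    logger.info(
        "net=%d snr=%s method=%s variant=%s: %s (%.2fs)",
        net_idx,
        snr,
        method,
        variant,
        "FAILED" if cell.failed else f"AUPR={cell.result.aupr:.3f}",
        cell.walltime,
    )
    report.cells.append(cell)


def run_benchmark(config: BenchmarkConfig) -> BenchmarkReport:
    """Run the configured grid; failures are isolated per cell (see ``any_failed``)."""
    report = BenchmarkReport(config=config)
    for k in range(config.n_networks):
        gold = generate_scale_free_network(
            config.n_genes,
            config.avg_links_per_node,
            seed=_stage_seed(config.master_seed, 0, k),
        )
        report.networks.append(gold)
        design = make_single_knockdown_design(config.n_genes, config.replicates)
        scrambled = (
            scramble_design(design, seed=_stage_seed(config.master_seed, 1, k))
            if config.scramble_control
            else None
        )
        x = simulate_steady_state(gold, design)
        for s, snr in enumerate(config.snr_levels):
            if config.noise_free:
                y = x
            else:
                spec = NoiseSpec.for_expression(x, snr, config.alpha)
                y = add_noise(x, spec, seed=_stage_seed(config.master_seed, 2, k, s))
            for m, method in enumerate(config.methods):
                seed = _stage_seed(config.master_seed, 3, k, s, m)
                _run_cell(report, gold, y, design, config, k, snr, method, "intact", seed)
                if scrambled is not None and METHOD_CATEGORIES[method] == "p_based":
                    _run_cell(
                        report, gold, y, scrambled, config, k, snr, method, "scrambled", seed
                    )
    return report


def similarity_analysis(report: BenchmarkReport) -> dict[float, dict]:
    """Between-method overlap of the max-F1 networks, averaged over networks.

    For each noise level: the methods x methods matrix of mean pairwise
    Jaccard indices of the max-F1 edge sets, the matching true-fraction
    matrix (overlap fraction found in the gold network, NaN where the
    overlap is empty), and within/between-category averages of the Jaccard
    values (diagonal excluded).
    """
    methods = [m for m in report.config.methods]
    out: dict[float, dict] = {}
    for snr in report.config.snr_levels:
        jac = pd.DataFrame(np.nan, index=methods, columns=methods, dtype=float)
        frac = pd.DataFrame(np.nan, index=methods, columns=methods, dtype=float)
        for a in methods:
            for b in methods:
                js, fs = [], []
                for k in range(report.config.n_networks):
                    try:
                        ca = report.cell(k, snr, a)
                        cb = report.cell(k, snr, b)
                    except KeyError:
                        continue
                    if ca.failed or cb.failed:
                        continue
                    js.append(jaccard(ca.result.max_f1_edges, cb.result.max_f1_edges))
                    gold_edges = report.networks[k].edges(include_diagonal=True)
                    tf = true_fraction(
                        ca.result.max_f1_edges, cb.result.max_f1_edges, gold_edges
                    )
                    if tf is not None:
                        fs.append(tf)
                if js:
                    jac.loc[a, b] = float(np.mean(js))
                if fs:
                    frac.loc[a, b] = float(np.mean(fs))

        def _mean_pairs(names_a: list[str], names_b: list[str]) -> float:
            vals = [
                jac.loc[a, b]
                for a in names_a
                for b in names_b
                if a != b and np.isfinite(jac.loc[a, b])
            ]
            return float(np.mean(vals)) if vals else float("nan")

        p_methods = [m for m in methods if METHOD_CATEGORIES[m] == "p_based"]
        np_methods = [m for m in methods if METHOD_CATEGORIES[m] == "non_p_based"]
        out[snr] = {
            "jaccard": jac,
            "true_fraction": frac,
            "within_p_based": _mean_pairs(p_methods, p_methods),
            "within_non_p_based": _mean_pairs(np_methods, np_methods),
            "between_categories": _mean_pairs(p_methods, np_methods),
        }
    return out
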