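"""Perturbation designs, steady-state expression, and SNR-calibrated noise.

The study design is a panel of single-gene knockdowns: each experiment pulls
one gene down (entry ``-1`` in the design matrix ``P``), with ``r``
replicates per gene, yielding an ``N x (N*r)`` design.  The expression
readout is the steady state of the linear network model

    A @ Y + P = 0        =>        X = -A^{-1} @ P

so the noise-free fold-change matrix ``X`` is the system's equilibrium
response to the perturbation panel (100 x 300 for the default 100 genes,
3 replicates).

Measurement noise is i.i.d. Gaussian with a variance calibrated to a target
signal-to-noise ratio

    SNR = sigma_min(X) / sqrt(q * lambda),    q = chi2_quantile(1 - alpha, N*M)

i.e. the *weakest* signal direction (smallest singular value of the
noise-free data) is compared against a 99%-confidence bound on the noise
magnitude.  Given a target SNR this is solved for the noise variance
``lambda``.  SNR levels 0.01 / 0.1 / 1 are the study's high / medium / low
noise conditions: at SNR = 1 the weakest signal just matches the noise, so
the system is comfortably reconstructible.

The scrambled-design control applies a uniform random derangement to the
gene labels of the perturbations, so no experiment keeps its true target and
the mapping between ``P`` and ``Y`` is broken everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateSignalError, NumericalError
from .networks import Network

__all__ = [
    "PerturbationDesign",
    "ExpressionMatrix",
    "NoiseSpec",
    "make_single_knockdown_design",
    "scramble_design",
    "simulate_steady_state",
    "required_variance",
    "snr_from_variance",
    "add_noise",
]


@dataclass
class PerturbationDesign:
    """Binary N x M perturbation design ``P``.

    ``matrix[g, e] = -1`` when experiment ``e`` knocks gene ``g`` down,
    ``+1`` for overexpression, ``0`` otherwise.  At most one nonzero per
    column (single-target design).
    """

    matrix: np.ndarray
    replicate_count: int = 1

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-D (genes x experiments)")
        if not np.isin(self.matrix, (-1.0, 0.0, 1.0)).all():
            raise ValueError("design entries must be in {-1, 0, +1}")
        if (np.count_nonzero(self.matrix, axis=0) > 1).any():
            raise ValueError("single-target design: at most one nonzero per column")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be positive")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.matrix.shape[1]

    @property
    def target_of_experiment(self) -> np.ndarray:
        """Per-column perturbed gene index, -1 where unperturbed."""
        nonzero = self.matrix != 0
        targets = np.where(nonzero.any(axis=0), nonzero.argmax(axis=0), -1)
        return targets.astype(int)

    def experiment_ids(self, gene_ids: list[str] | None = None) -> list[str]:
        """Labels encoding target gene and replicate index, e.g. ``G17_r2``."""
        names = gene_ids or [f"G{i + 1}" for i in range(self.n_genes)]
        seen: dict[int, int] = {}
        labels = []
        for e, t in enumerate(self.target_of_experiment):
            if t < 0:
                labels.append(f"ctrl_{e + 1}")
                continue
            seen[t] = seen.get(t, 0) + 1
            labels.append(f"{names[t]}_r{seen[t]}")
        return labels


@dataclass
class ExpressionMatrix:
    """N x M fold-change expression, either ``noise_free`` (X) or ``noisy`` (Y)."""

    values: np.ndarray
    role: str = "noise_free"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x experiments)")
        if not np.isfinite(self.values).all():
            raise ValueError("expression matrix must be finite")
        if self.role not in ("noise_free", "noisy"):
            raise ValueError("role must be 'noise_free' or 'noisy'")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_experiments(self) -> int:
        return self.values.shape[1]


def make_single_knockdown_design(n_genes: int, replicates: int = 3) -> PerturbationDesign:
    """Full single-target knockdown panel: every gene knocked down, ``replicates`` times.

    Columns are ordered gene-major, replicate-minor: columns
    ``g*replicates .. g*replicates + replicates - 1`` all target gene ``g``.
    """
    if n_genes < 1 or replicates < 1:
        raise ValueError("n_genes and replicates must be positive")
    matrix = np.zeros((n_genes, n_genes * replicates))
    for g in range(n_genes):
        matrix[g, g * replicates : (g + 1) * replicates] = -1.0
    return PerturbationDesign(matrix=matrix, replicate_count=replicates)


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of ``0..n-1`` with no fixed points (rejection)."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def scramble_design(design: PerturbationDesign, seed: int | None = None) -> PerturbationDesign:
    """Displace every perturbation to a wrong gene via a random derangement.

    The gene labels of the perturbation rows are permuted by a uniformly
    random derangement, so each experiment's ``-1``/``+1`` lands on a gene
    that is *not* its true target while the column structure, replicate
    grouping and entry multiset stay identical.
    """
    if design.n_genes < 2:
        raise ValueError("scrambling needs at least 2 genes (no derangement exists)")
    rng = np.random.default_rng(seed)
    perm = _random_derangement(design.n_genes, rng)
    scrambled = np.zeros_like(design.matrix)
    scrambled[perm, :] = design.matrix
    return PerturbationDesign(matrix=scrambled, replicate_count=design.replicate_count)


def simulate_steady_state(network: Network, design: PerturbationDesign) -> ExpressionMatrix:
    """Noise-free steady-state fold changes ``X = -A^{-1} P``.

    Replicate columns of the same perturbation are identical by construction;
    noise is applied downstream.
    """
    if network.n_genes != design.n_genes:
        raise ValueError("network and design disagree on the number of genes")
    a = network.weights
    try:
        x = np.linalg.solve(a, -design.matrix)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            f"network ({network.n_genes} genes) is singular; steady state undefined"
        ) from exc
    if not np.isfinite(x).all():
        raise NumericalError("steady-state solve produced non-finite values")
    return ExpressionMatrix(values=x, role="noise_free")


def _smallest_singular_value(values: np.ndarray) -> float:
    return float(np.linalg.svd(values, compute_uv=False).min())


def required_variance(x: ExpressionMatrix | np.ndarray, snr: float, alpha: float = 0.01) -> float:
    """Noise variance ``lambda`` that realizes a target SNR for the data ``x``.

    Inverts ``SNR = sigma_min(x) / sqrt(q * lambda)`` with
    ``q = chi2_quantile(1 - alpha, N*M)``, i.e.
    ``lambda = (sigma_min(x) / snr)**2 / q``.
    """
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if snr <= 0:
        raise ValueError("snr must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    smin = _smallest_singular_value(values)
    if smin <= 0 or not np.isfinite(smin):
        raise DegenerateSignalError("noise-free data is rank deficient (sigma_min = 0)")
    q = float(stats.chi2.ppf(1.0 - alpha, df=values.size))
    return (smin / snr) ** 2 / q


def snr_from_variance(
    x: ExpressionMatrix | np.ndarray, variance: float, alpha: float = 0.01
) -> float:
    """Forward evaluation of the SNR definition for a given noise variance."""
    values = x.values if isinstance(x, ExpressionMatrix) else np.asarray(x, dtype=float)
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    smin = _smallest_singular_value(values)
    q = float(stats.chi2.ppf(1.0 - alpha, df=values.size))
    return smin / np.sqrt(q * variance) if variance > 0 else np.inf


@dataclass
class NoiseSpec:
    """Target SNR, confidence parameter, and the derived noise variance."""

    snr: float
    alpha: float = 0.01
    variance_lambda: float = field(default=0.0)

    @classmethod
    def for_expression(
        cls, x: ExpressionMatrix | np.ndarray, snr: float, alpha: float = 0.01
    ) -> "NoiseSpec":
        return cls(snr=snr, alpha=alpha, variance_lambda=required_variance(x, snr, alpha))


def add_noise(
    x: ExpressionMatrix, spec: NoiseSpec, seed: int | None = None
) -> ExpressionMatrix:
    """Observed data ``Y = X + E``, ``E`` i.i.d. Gaussian with variance ``spec.variance_lambda``."""
    if spec.variance_lambda < 0:
        raise ValueError("noise variance must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(spec.variance_lambda), size=x.values.shape)
    return ExpressionMatrix(values=x.values + noise, role="noisy")
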