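"""Synthetic multi-subject resting-state time series from a planted network.

The planted adjacency matrix is conditioned into a valid correlation target
C (unit diagonal, off-diagonals in [0, 1), nearest positive-definite by
alternating projections), Cholesky-factored C = L L^T, and node time series
are built as Y = L X + baseline where X is standardized white noise — so the
population covariance of Y is exactly C. Rician noise (magnitude of a
complex Gaussian perturbation, the standard MR noise model) is then injected
at a prescribed SNR = mean signal magnitude / noise standard deviation.
Each simulated subject is an independent realization of the same target.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConvergenceError, ParameterError, ShapeError
from .network import WeightedNetwork

DEFAULT_N_TIMEPOINTS = 150
DEFAULT_BASELINE = 100.0
DEFAULT_EIG_FLOOR = 1e-8


@dataclass(frozen=True)
class CorrelationTarget:
    """Unit-diagonal positive-definite correlation matrix C."""

    matrix: np.ndarray
    eig_floor: float = DEFAULT_EIG_FLOOR

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class CovarianceTarget:
    """Positive-definite covariance target (diagonal not constrained to 1).

    Produced by projecting a planted adjacency onto the positive-definite
    cone; node variances emerge from the projection, and Pearson correlation
    of the generated series normalizes them per node.
    """

    matrix: np.ndarray
    eig_floor: float = DEFAULT_EIG_FLOOR

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class TimeSeriesPanel:
    """subjects x nodes x timepoints array of synthetic BOLD series."""

    data: np.ndarray
    baseline: float
    snr: float
    seed: int

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


def nearest_positive_definite(
    matrix: np.ndarray,
    eig_floor: float = DEFAULT_EIG_FLOOR,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> CorrelationTarget:
    """Nearest (Frobenius) unit-diagonal matrix with min eigenvalue >= floor.

    Alternating projections between the cone of matrices with eigenvalues
    >= ``eig_floor`` and the unit-diagonal affine set, with the Dykstra
    correction that makes the iteration converge to the nearest point.
    """
    a = np.asarray(matrix, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError("input must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ShapeError("input must be symmetric (within 1e-12)")
    a = 0.5 * (a + a.T)

    y = a.copy()
    ds = np.zeros_like(a)
    for _ in range(max_iter):
        r = y - ds
        vals, vecs = np.linalg.eigh(r)
        x = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
        x = 0.5 * (x + x.T)
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        if np.linalg.norm(y_new - y, "fro") < tol * max(1.0, np.linalg.norm(y, "fro")):
            y = y_new
            break
        y = y_new
    else:
        resid = float(np.linalg.norm(y - x, "fro"))
        raise ConvergenceError(
            f"nearest-PD projection did not converge (residual {resid:.3e})"
        )

    # final symmetric eigenvalue clip; restore exact unit diagonal by scaling
    vals, vecs = np.linalg.eigh(0.5 * (y + y.T))
    y = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    d = np.sqrt(np.diag(y))
    y = y / np.outer(d, d)
    y = 0.5 * (y + y.T)
    np.fill_diagonal(y, 1.0)
    min_eig = float(np.linalg.eigvalsh(y).min())
    if min_eig < 0.25 * eig_floor:
        raise ConvergenceError(
            f"conditioned matrix not positive definite (min eigenvalue {min_eig:.3e})"
        )
    return CorrelationTarget(y, eig_floor)


def nearest_positive_semidefinite(
    matrix: np.ndarray, eig_floor: float = DEFAULT_EIG_FLOOR
) -> CovarianceTarget:
    """Closest (Frobenius) matrix with all eigenvalues >= ``eig_floor``.

    For a symmetric matrix this is a single eigendecomposition with
    eigenvalue clipping; the diagonal is free, so the result is a covariance
    rather than a correlation target.
    """
    a = np.asarray(matrix, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ShapeError("input must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ShapeError("input must be symmetric (within 1e-12)")
    vals, vecs = np.linalg.eigh(0.5 * (a + a.T))
    c = (vecs * np.maximum(vals, eig_floor)) @ vecs.T
    return CovarianceTarget(0.5 * (c + c.T), eig_floor)


def cholesky_factor(target: CorrelationTarget | CovarianceTarget) -> np.ndarray:
    """Lower-triangular L with L L^T = C (relative Frobenius error < 1e-10)."""
    try:
        L = np.linalg.cholesky(target.matrix)
    except np.linalg.LinAlgError:
        # numerically at the PSD boundary: retry with a floor-sized jitter
        n = target.matrix.shape[0]
        jitter = max(target.eig_floor, 1e-12 * np.trace(target.matrix) / n)
        L = np.linalg.cholesky(target.matrix + jitter * np.eye(n))
    err = np.linalg.norm(L @ L.T - target.matrix, "fro") / np.linalg.norm(
        target.matrix, "fro"
    )
    if err > 1e-10:
        raise ConvergenceError(f"Cholesky identity violated (relative error {err:.3e})")
    return L


def correlated_timeseries(
    target: CorrelationTarget | CovarianceTarget,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    baseline: float = DEFAULT_BASELINE,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Noiseless node x time series with population covariance exactly C.

    X is i.i.d. standard Gaussian white noise per node and timepoint
    (temporal autocorrelation is not modeled); Y = L X + baseline.
    """
    if n_timepoints < 3:
        raise ParameterError("need at least 3 timepoints for correlations")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    L = cholesky_factor(target)
    x = rng.standard_normal((target.n_nodes, n_timepoints))
    return L @ x + baseline


def add_rician_noise(
    series: np.ndarray,
    snr: float,
    seed: int | np.random.Generator = 0,
    sigma: float | None = None,
) -> np.ndarray:
    """Rician noise at the given SNR: each sample y becomes
    sqrt((y + g1)^2 + g2^2) with g1, g2 ~ N(0, sigma^2) independent, where
    sigma = mean(|series|) / snr unless given explicitly.
    """
    if snr <= 0:
        raise ParameterError("snr must be positive")
    y = np.asarray(series, dtype=np.float64)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if sigma is None:
        sigma = float(np.mean(np.abs(y))) / snr
    g1 = rng.normal(0.0, sigma, size=y.shape)
    g2 = rng.normal(0.0, sigma, size=y.shape)
    return np.sqrt((y + g1) ** 2 + g2**2)


def adjacency_to_target(
    network: WeightedNetwork,
    eig_floor: float = DEFAULT_EIG_FLOOR,
    mode: str = "covariance",
) -> CorrelationTarget | CovarianceTarget:
    """Condition a planted adjacency into a generative target.

    ``mode="covariance"`` (default): project the raw zero-diagonal adjacency
    onto the positive-definite cone (eigenvalue clipping). Node variances
    emerge from the projection — high-strength hubs get larger variance —
    and the subject-level Pearson step renormalizes per node, preserving
    weight contrast regardless of the adjacency's scale.

    ``mode="correlation"``: force a unit-diagonal correlation target — if any
    weight >= 1, rescale all off-diagonals by 1/(max_weight + 0.05) so they
    lie in [0, 1), set the diagonal to 1, then the nearest-correlation
    projection. This compresses all weights by the largest hub weight and is
    kept for targets that are already on a correlation scale.
    """
    a = network.to_adjacency()
    if mode == "covariance":
        return nearest_positive_semidefinite(a, eig_floor=eig_floor)
    if mode == "correlation":
        wmax = a.max(initial=0.0)
        if wmax >= 1.0:
            a = a / (wmax + 0.05)
        np.fill_diagonal(a, 1.0)
        return nearest_positive_definite(a, eig_floor=eig_floor)
    raise ParameterError(f"unknown conditioning mode {mode!r}")


def generate_cohort(
    network: WeightedNetwork,
    n_subjects: int,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    snr: float = 35.0,
    baseline: float = DEFAULT_BASELINE,
    seed: int = 0,
    eig_floor: float = DEFAULT_EIG_FLOOR,
) -> TimeSeriesPanel:
    """Multi-subject panel: the adjacency is conditioned once, then every
    subject draws fresh standardized series and fresh Rician noise from a
    deterministic per-subject sub-seed (SeedSequence(seed, spawn_key=(k,))).
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    target = adjacency_to_target(network, eig_floor=eig_floor)
    panel = np.empty((n_subjects, target.n_nodes, n_timepoints))
    for k in range(n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        clean = correlated_timeseries(target, n_timepoints, baseline, rng)
        panel[k] = add_rician_noise(clean, snr, rng)
    return TimeSeriesPanel(panel, baseline, snr, seed)


# -- plain-text I/O -------------------------------------------------------


def write_cohort(panel: TimeSeriesPanel, out_dir: str | Path) -> Path:
    """Write one CSV per subject (rows = timepoints, columns = node ids) and
    a YAML manifest listing the files, snr, baseline and seed. Returns the
    manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for k in range(panel.n_subjects):
        name = f"subject_{k:03d}.csv"
        pd.DataFrame(
            panel.data[k].T, columns=[str(i) for i in range(panel.n_nodes)]
        ).to_csv(out / name, index=False, float_format="%.10g")
        files.append(name)
    manifest = {
        "subjects": files,
        "snr": float(panel.snr),
        "baseline": float(panel.baseline),
        "seed": int(panel.seed),
    }
    path = out / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path


def read_cohort(manifest_path: str | Path) -> TimeSeriesPanel:
    path = Path(manifest_path)
    manifest = yaml.safe_load(path.read_text())
    data = np.stack(
        [
            pd.read_csv(path.parent / name).to_numpy(dtype=float).T
            for name in manifest["subjects"]
        ]
    )
    return TimeSeriesPanel(
        data, manifest["baseline"], manifest["snr"], manifest["seed"]
    )
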