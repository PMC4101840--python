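"""Elastic network models: spring networks, Hessian, covariance, MSF.

Two coarse-grained harmonic potentials over a CA trace are supported:

* **pfANM** (parameter-free anisotropic network model): every pair of
  sites is connected by a spring with force constant ``k_ij = 1/d_ij^2``,
  where ``d_ij`` is the equilibrium CA-CA distance.
* **ANM**: unit force constants for all pairs within a cutoff ``R_cut``
  (13 A by default, boundary inclusive), zero beyond.

Both are relaxed at the input conformation (the potential minimum sits at
the trace coordinates).  The Hessian of the quadratic expansion is
pseudo-inverted to obtain the 3N x 3N covariance of thermal fluctuations,
whose 3x3 diagonal blocks give each site's mean-square fluctuation (MSF),
the dynamical-flexibility measure used throughout.

Energies are expressed in units of k_B*T; the inverse temperature ``beta``
enters only as an explicit scale factor.  All headline analyses use
per-protein z-scores, which removes this scale entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structure_io import CaTrace

__all__ = [
    "EnsembleParams",
    "SpringNetwork",
    "CovarianceResult",
    "build_pfanm",
    "build_anm",
    "site_stiffness",
    "potential_energy",
    "build_hessian",
    "covariance_from_hessian",
    "msf_from_covariance",
    "msf_approx",
]

DEFAULT_RCUT = 13.0


@dataclass(frozen=True)
class EnsembleParams:
    """Thermodynamic and mutational scale parameters.

    beta : inverse temperature 1/(k_B T); beta > 0.
    alpha2 : variance of spring rest-length perturbations (A^2); alpha2 > 0.
    """

    beta: float = 1.0
    alpha2: float = 1.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not self.alpha2 > 0:
            raise ValueError("alpha2 must be > 0")


@dataclass(frozen=True)
class SiteVector:
    """A per-site scalar aligned to a CaTrace's site order."""

    protein_id: str
    values: np.ndarray
    quantity: str = "other"
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be 1-D")
        object.__setattr__(self, "values", v)
        if self.normalized:
            n = v.size
            sd = np.sqrt(np.mean(v**2) - np.mean(v) ** 2)
            if abs(np.mean(v)) > 1e-10 or abs(sd - 1.0) > 1e-10:
                raise ValueError("normalized SiteVector must have mean 0, SD 1")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SpringNetwork:
    """Pairwise springs over a CA trace, relaxed at its coordinates.

    kij : symmetric (N, N) non-negative force constants, zero diagonal
        (units: k_B*T / A^2).
    d0 : symmetric (N, N) rest lengths, equal to the trace's pairwise
        distances ("all springs relaxed" at equilibrium).
    rcut : cutoff distance (A) for ANM; None for pfANM.
    """

    trace: CaTrace
    model: str
    kij: np.ndarray
    d0: np.ndarray
    rcut: float | None = None

    def __post_init__(self) -> None:
        n = self.trace.n_sites
        if self.kij.shape != (n, n) or self.d0.shape != (n, n):
            raise ValueError("kij and d0 must be (N, N)")
        if np.any(self.kij < 0) or np.any(np.diag(self.kij) != 0):
            raise ValueError("kij must be non-negative with zero diagonal")
        if not np.allclose(self.kij, self.kij.T):
            raise ValueError("kij must be symmetric")

    @property
    def n_sites(self) -> int:
        return self.trace.n_sites

    def incident_springs(self, site: int) -> np.ndarray:
        """Indices j of sites connected to `site` by a spring (k_ij > 0)."""
        return np.flatnonzero(self.kij[site] > 0)

    def to_edge_tsv(self, path) -> None:
        """Export as a TSV edge list (i, j, kij, d0) for debugging."""
        import pandas as pd

        iu, ju = np.triu_indices(self.n_sites, k=1)
        keep = self.kij[iu, ju] > 0
        pd.DataFrame(
            {"i": iu[keep], "j": ju[keep], "kij": self.kij[iu, ju][keep],
             "d0": self.d0[iu, ju][keep]}
        ).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CovarianceResult:
    """Pseudo-inverse covariance of a network's quadratic Hessian."""

    covariance: np.ndarray
    n_zero_modes: int
    eigenvalues: np.ndarray


def build_pfanm(trace: CaTrace) -> SpringNetwork:
    """Parameter-free ANM: k_ij = 1 / d_ij^2 for every pair of sites."""
    d0 = trace.distance_matrix()
    if np.min(d0 + np.eye(trace.n_sites)) <= 0:
        raise ValueError("zero pairwise distance gives an infinite force constant")
    with np.errstate(divide="ignore"):
        kij = 1.0 / d0**2
    np.fill_diagonal(kij, 0.0)
    return SpringNetwork(trace=trace, model="pfANM", kij=kij, d0=d0)


def build_anm(trace: CaTrace, rcut: float = DEFAULT_RCUT) -> SpringNetwork:
    """ANM: unit springs for all pairs with d_ij <= rcut (boundary inclusive)."""
    if not rcut > 0:
        raise ValueError("rcut must be > 0")
    d0 = trace.distance_matrix()
    kij = (d0 <= rcut).astype(float)
    np.fill_diagonal(kij, 0.0)
    return SpringNetwork(trace=trace, model="ANM", kij=kij, d0=d0, rcut=rcut)


def site_stiffness(network: SpringNetwork) -> SiteVector:
    """Site stiffness k_i = sum_{j != i} k_ij (raw, un-normalized).

    For pfANM this equals the weighted contact number; for ANM, the
    contact number.
    """
    return SiteVector(
        protein_id=network.trace.protein_id,
        values=network.kij.sum(axis=1),
        quantity="k_i",
    )


def potential_energy(network: SpringNetwork, conformation: np.ndarray) -> float:
    """Harmonic network energy V = 1/2 sum_{i<j} k_ij (d_ij - d0_ij)^2.

    Zero at the network's equilibrium (trace) coordinates, non-negative
    everywhere.  Units: k_B*T.
    """
    conformation = np.asarray(conformation, dtype=float)
    if conformation.shape != (network.n_sites, 3):
        raise ValueError(
            f"conformation must be ({network.n_sites}, 3), got {conformation.shape}"
        )
    d = squareform(pdist(conformation))
    # sum over ordered pairs double counts: 1/2 * 1/2 = 1/4
    return 0.25 * float(np.sum(network.kij * (d - network.d0) ** 2))


def build_hessian(network: SpringNetwork) -> np.ndarray:
    """Analytic 3N x 3N Hessian of the network potential at equilibrium.

    Off-diagonal 3x3 blocks are ``H_ij = -(k_ij / d0_ij^2) r_ij r_ij^T``
    with ``r_ij`` the equilibrium inter-site vector; diagonal blocks are
    minus the sum of the off-diagonal blocks in their row.  Symmetric and
    positive semi-definite, with translations and rotations in its null
    space.
    """
    coords = network.trace.coords
    n = network.n_sites
    rij = coords[None, :, :] - coords[:, None, :]  # (N, N, 3), r_j - r_i
    with np.errstate(divide="ignore", invalid="ignore"):
        coeff = network.kij / network.d0**2
    np.fill_diagonal(coeff, 0.0)
    blocks = -coeff[:, :, None, None] * np.einsum("ija,ijb->ijab", rij, rij)
    diag = -blocks.sum(axis=1)
    blocks[np.arange(n), np.arange(n)] = diag
    h = blocks.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)
    return 0.5 * (h + h.T)  # enforce exact symmetry against rounding


def covariance_from_hessian(
    hessian: np.ndarray,
    zero_mode_rtol: float = 1e-8,
    expected_zero_modes: int = 6,
) -> CovarianceResult:
    """Moore-Penrose pseudo-inverse of the Hessian via eigendecomposition.

    Eigenvalues below ``zero_mode_rtol`` times the largest are treated as
    rigid-body zero modes and dropped.  A connected, non-collinear 3-D
    network has exactly 6 (3 translations, 3 rotations); any other count
    signals a disconnected or degenerate network and raises.

    ``expected_zero_modes`` exists for analytically degenerate fixtures
    (e.g. a two-site dumbbell has only 5 rigid modes).
    """
    hessian = np.asarray(hessian, dtype=float)
    evals, evecs = np.linalg.eigh(hessian)
    lam_max = evals[-1]
    if lam_max <= 0:
        raise ValueError("Hessian has no positive eigenvalues")
    zero = evals <= zero_mode_rtol * lam_max
    n_zero = int(zero.sum())
    if n_zero > expected_zero_modes:
        raise ValueError(
            f"network is disconnected or degenerate (found {n_zero} zero modes, "
            f"expected {expected_zero_modes})"
        )
    if n_zero < expected_zero_modes:
        raise ValueError(
            f"numerically broken rigid-body invariance (found {n_zero} zero "
            f"modes, expected {expected_zero_modes})"
        )
    inv = np.where(zero, 0.0, 1.0 / np.where(zero, 1.0, evals))
    cov = (evecs * inv) @ evecs.T
    return CovarianceResult(
        covariance=0.5 * (cov + cov.T),
        n_zero_modes=n_zero,
        eigenvalues=np.sort(evals),
    )


def msf_from_covariance(
    cov: CovarianceResult, params: EnsembleParams, protein_id: str = ""
) -> SiteVector:
    """Per-site mean-square fluctuation MSF_i = Tr(C_ii) / beta (A^2)."""
    c = cov.covariance
    n3 = c.shape[0]
    if n3 % 3:
        raise ValueError("covariance must be 3N x 3N")
    diag = np.diag(c).reshape(n3 // 3, 3)
    msf = diag.sum(axis=1) / params.beta
    return SiteVector(protein_id=protein_id, values=msf, quantity="MSF")


def msf_approx(k_i: SiteVector, params: EnsembleParams) -> SiteVector:
    """Stiffness-based MSF approximation: MSF_i ~ 3 / (2 beta k_i).

    Valid for compact networks where a site's fluctuation is dominated by
    its local spring environment; z-scored, it equals z(1/k_i) exactly.
    """
    if np.any(k_i.values <= 0):
        raise ValueError("msf_approx requires all k_i > 0")
    return SiteVector(
        protein_id=k_i.protein_id,
        values=1.5 / (params.beta * k_i.values),
        quantity="MSF_approx",
    )
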