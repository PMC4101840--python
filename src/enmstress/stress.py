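"""Mutational stress: random rest-length perturbations and acceptance rates.

A point mutation at site *i* is modelled as a random perturbation of the
rest lengths of every spring incident to *i*: ``d0_ij -> d0_ij + delta_ij``
with the deltas drawn independently from a zero-mean distribution of
variance ``alpha2``.  Because the wild type is relaxed at its equilibrium
conformation, holding the mutant at that same conformation stores energy
``1/2 k_ij delta_ij^2`` in each perturbed spring.  The Mean Local
mutational Stress is the average of this excess energy over mutations:

    MLmS_i = <V_mut(r0) - V_wt(r0)> = 1/2 alpha2 k_i        (an identity)

where ``k_i = sum_j k_ij`` is the site stiffness.  Selection enters
through the Boltzmann acceptance factor ``exp(-beta dV)``, whose
mutational average linearizes to ``1 - beta MLmS_i`` under weak
selection.  Monte-Carlo estimators and a Gaussian closed form of the
exact average are provided as mutually checking routes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .enm import EnsembleParams, SiteVector, SpringNetwork, potential_energy

__all__ = [
    "MutationSample",
    "mlms_analytic",
    "sample_mutation",
    "mlms_monte_carlo",
    "acceptance_rate_linearized",
    "acceptance_rate_mc",
    "acceptance_rate_closed_form",
]


@dataclass(frozen=True)
class MutationSample:
    """One random mutation at a site: its spring perturbations and energy cost."""

    site: int
    partners: np.ndarray  # indices j of perturbed springs (k_ij > 0)
    deltas: np.ndarray  # rest-length perturbations delta_ij (A)
    delta_v: float  # V_mut(r0_wt) - V_wt(r0_wt), >= 0 (k_B*T)


def mlms_analytic(k_i: SiteVector, params: EnsembleParams) -> SiteVector:
    """Exact mean local mutational stress MLmS_i = alpha2 * k_i / 2 (raw)."""
    return SiteVector(
        protein_id=k_i.protein_id,
        values=0.5 * params.alpha2 * k_i.values,
        quantity="MLmS",
    )


def _draw_deltas(
    rng: np.random.Generator, n: int, alpha2: float, distribution: str
) -> np.ndarray:
    if distribution == "gaussian":
        return rng.normal(0.0, np.sqrt(alpha2), size=n)
    if distribution == "uniform":
        half = np.sqrt(3.0 * alpha2)  # uniform(-h, h) has variance h^2/3
        return rng.uniform(-half, half, size=n)
    raise ValueError(f"unknown perturbation distribution {distribution!r}")


def sample_mutation(
    network: SpringNetwork,
    site: int,
    params: EnsembleParams,
    rng: np.random.Generator,
    distribution: str = "gaussian",
) -> MutationSample:
    """Draw one random mutation at `site` and compute its energy cost.

    The cost is computed by two independent routes that must agree: (a)
    directly as ``1/2 sum_j k_ij delta_ij^2`` and (b) by re-evaluating the
    full network potential with perturbed rest lengths at the wild-type
    equilibrium coordinates.  Disagreement beyond 1e-10 relative raises,
    guarding the energy bookkeeping.
    """
    if not 0 <= site < network.n_sites:
        raise IndexError(f"site {site} out of range for N={network.n_sites}")
    partners = network.incident_springs(site)
    deltas = _draw_deltas(rng, partners.size, params.alpha2, distribution)
    k = network.kij[site, partners]
    dv_direct = 0.5 * float(np.sum(k * deltas**2))

    d0_mut = network.d0.copy()
    d0_mut[site, partners] += deltas
    d0_mut[partners, site] += deltas
    mutant = SpringNetwork(
        trace=network.trace, model=network.model, kij=network.kij,
        d0=d0_mut, rcut=network.rcut,
    )
    dv_network = potential_energy(mutant, network.trace.coords)
    scale = max(dv_direct, 1e-30)
    if abs(dv_direct - dv_network) > 1e-10 * scale:
        raise AssertionError(
            "energy bookkeeping mismatch between direct and network routes: "
            f"{dv_direct!r} vs {dv_network!r}"
        )
    return MutationSample(site=site, partners=partners, deltas=deltas, delta_v=dv_direct)


def _delta_v_samples(
    network: SpringNetwork,
    site: int,
    params: EnsembleParams,
    n_samples: int,
    seed: int,
    distribution: str,
) -> np.ndarray:
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100 for a meaningful standard error")
    partners = network.incident_springs(site)
    rng = np.random.default_rng(seed)
    deltas = _draw_deltas(rng, n_samples * partners.size, params.alpha2, distribution)
    deltas = deltas.reshape(n_samples, partners.size)
    return 0.5 * deltas**2 @ network.kij[site, partners]


def mlms_monte_carlo(
    network: SpringNetwork,
    site: int,
    params: EnsembleParams,
    n_samples: int = 10_000,
    seed: int = 0,
    distribution: str = "gaussian",
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, SE) of the mutational stress at one site.

    Converges on ``mlms_analytic`` for any zero-mean perturbation
    distribution of variance alpha2 — the identity depends only on the
    variance, which the uniform option demonstrates.
    """
    dv = _delta_v_samples(network, site, params, n_samples, seed, distribution)
    return float(dv.mean()), float(dv.std(ddof=1) / np.sqrt(n_samples))


def acceptance_rate_linearized(mlms: SiteVector, params: EnsembleParams) -> SiteVector:
    """Weak-selection acceptance rate omega_i ~ 1 - beta * MLmS_i.

    No clipping: values go negative where beta*MLmS > 1, the documented
    breakdown of the linearization.  Downstream analyses use z-scores,
    where the affine map makes the issue moot.
    """
    if mlms.normalized:
        raise ValueError("acceptance rates are defined on raw MLmS values")
    return SiteVector(
        protein_id=mlms.protein_id,
        values=1.0 - params.beta * mlms.values,
        quantity="acceptance_rate",
    )


def acceptance_rate_mc(
    network: SpringNetwork,
    site: int,
    params: EnsembleParams,
    n_samples: int = 10_000,
    seed: int = 0,
    distribution: str = "gaussian",
) -> tuple[float, float]:
    """Monte-Carlo estimate (mean, SE) of <exp(-beta dV)> at one site."""
    dv = _delta_v_samples(network, site, params, n_samples, seed, distribution)
    w = np.exp(-params.beta * dv)
    return float(w.mean()), float(w.std(ddof=1) / np.sqrt(n_samples))


def acceptance_rate_closed_form(
    network: SpringNetwork, site: int, params: EnsembleParams
) -> float:
    """Exact <exp(-beta dV)> for Gaussian perturbations.

    The Gaussian integral over each independent spring gives
    ``prod_j (1 + beta alpha2 k_ij)^(-1/2)`` over springs incident to the
    site.  Serves as the oracle for the Monte-Carlo route.
    """
    partners = network.incident_springs(site)
    k = network.kij[site, partners]
    return float(np.exp(-0.5 * np.sum(np.log1p(params.beta * params.alpha2 * k))))
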