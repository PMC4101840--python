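import numpy as np
import pytest

from enmstress import EnsembleParams, make_compact_globule_trace, make_helix_trace

GLOBULE_N = 120
GLOBULE_SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def helix50():
    return make_helix_trace(50)


@pytest.fixture(scope="session")
def globules():
    """Five compact globule traces (N=120, seeds 1-5), shared across tests."""
    return [make_compact_globule_trace(GLOBULE_N, seed=s) for s in GLOBULE_SEEDS]


@pytest.fixture(scope="session")
def globule(globules):
    return globules[0]


@pytest.fixture
def params():
    return EnsembleParams()


def pdb_atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resseq: int,
    xyz,
    occ: float = 1.0,
    b: float = 0.0,
    altloc: str = " ",
    icode: str = " ",
    element: str = "C",
) -> str:
    """One fixed-column PDB ATOM record."""
    x, y, z = xyz
    return (
        f"ATOM  {serial:5d} {name:^4s}{altloc}{resname:>3s} {chain}{resseq:4d}"
        f"{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}"
    )


@pytest.fixture
def simple_pdb_text():
    """Three-residue chain A with CA B-factors 10/20/30, plus an N atom."""
    lines = [
        pdb_atom_line(1, "N", "ALA", "A", 1, (0.0, 1.2, 0.0), element="N"),
        pdb_atom_line(2, "CA", "ALA", "A", 1, (0.0, 0.0, 0.0), b=10.0),
        pdb_atom_line(3, "CA", "GLY", "A", 2, (3.8, 0.0, 0.0), b=20.0),
        pdb_atom_line(4, "CA", "SER", "A", 3, (7.6, 0.0, 0.0), b=30.0),
        "END",
    ]
    return "\n".join(lines) + "\n"


def collinear_trace():
    """Three collinear sites at 0 / 3.8 / 7.6 Angstrom along x."""
    from enmstress import CaTrace

    coords = np.array([[0.0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]])
    return CaTrace("collinear", "A", ("1", "2", "3"), coords)


def triangle_trace(side: float):
    """Equilateral triangle in the xy plane."""
    from enmstress import CaTrace

    coords = side * np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, np.sqrt(3) / 2, 0.0]]
    )
    return CaTrace("triangle", "A", ("1", "2", "3"), coords)


def two_site_trace(distance: float):
    from enmstress import CaTrace

    coords = np.array([[0.0, 0, 0], [distance, 0, 0]])
    return CaTrace("pair", "A", ("1", "2"), coords)


def finite_difference_hessian(network, step: float = 1e-4) -> np.ndarray:
    """Central-difference second derivatives of the network potential.

    Independent numerical oracle for the analytic Hessian: evaluates the
    potential energy at four displaced conformations per matrix entry.
    """
    from enmstress import potential_energy

    coords = network.trace.coords
    n3 = 3 * network.n_sites

    def v_at(disp):
        return potential_energy(network, coords + disp.reshape(-1, 3))

    h = np.zeros((n3, n3))
    basis = np.eye(n3) * step
    for a in range(n3):
        ea = basis[a]
        for b in range(a, n3):
            eb = basis[b]
            h[a, b] = h[b, a] = (
                v_at(ea + eb) - v_at(ea - eb) - v_at(-ea + eb) + v_at(-ea - eb)
            ) / (4 * step**2)
    return h
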