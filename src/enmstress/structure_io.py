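"""Read C-alpha traces from PDB files and generate synthetic traces.

A :class:`CaTrace` is the geometric input to every elastic-network
computation in this package: one chain's ordered C-alpha sites with 3D
coordinates and (optionally) the B-factors of those CA atoms.  Synthetic
generators (an ideal alpha helix and a self-avoiding compact globule)
make the whole pipeline testable without any structure downloads.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "CaTrace",
    "read_ca_trace",
    "make_helix_trace",
    "make_compact_globule_trace",
]


@dataclass(frozen=True)
class CaTrace:
    """One protein chain reduced to its ordered C-alpha sites.

    Parameters
    ----------
    protein_id : str
        Identifier of the protein (e.g. PDB id or a synthetic tag).
    chain_id : str
        Chain identifier within the structure.
    site_labels : tuple of str
        Author residue numbers, with insertion code appended when present
        (e.g. ``"52"``, ``"52A"``).  Positional site indices (0..N-1) are
        used internally; these labels are the join key to rate tables.
    coords : (N, 3) ndarray
        CA coordinates in Angstrom.
    bfactors : (N,) ndarray, optional
        Crystallographic B-factor of each CA atom; ``None`` when absent.
    """

    protein_id: str
    chain_id: str
    site_labels: tuple[str, ...]
    coords: np.ndarray
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        n = coords.shape[0]
        if n < 2:
            raise ValueError("a CaTrace needs at least 2 sites")
        if len(self.site_labels) != n:
            raise ValueError("site_labels length must match coords")
        if np.min(pdist(coords)) <= 0.0:
            raise ValueError("duplicated coordinates: zero pairwise distance")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "site_labels", tuple(str(s) for s in self.site_labels))
        if self.bfactors is not None:
            b = np.asarray(self.bfactors, dtype=float)
            if b.shape != (n,):
                raise ValueError("bfactors length must match coords")
            object.__setattr__(self, "bfactors", b)

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def distance_matrix(self) -> np.ndarray:
        """Symmetric N x N matrix of pairwise CA-CA distances (Angstrom)."""
        return squareform(pdist(self.coords))

    def to_tsv(self, path: str | Path) -> None:
        """Serialize as TSV (protein_id, chain, site_label, x, y, z, bfactor)."""
        df = pd.DataFrame(
            {
                "protein_id": self.protein_id,
                "chain": self.chain_id,
                "site_label": self.site_labels,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
                "bfactor": self.bfactors if self.bfactors is not None else np.nan,
            }
        )
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CaTrace":
        df = pd.read_csv(path, sep="\t", dtype={"site_label": str})
        bf = df["bfactor"].to_numpy()
        return cls(
            protein_id=str(df["protein_id"].iloc[0]),
            chain_id=str(df["chain"].iloc[0]),
            site_labels=tuple(df["site_label"]),
            coords=df[["x", "y", "z"]].to_numpy(),
            bfactors=None if np.all(np.isnan(bf)) else bf,
        )


def read_ca_trace(pdb_source: str | Path | io.TextIOBase, chain: str) -> CaTrace:
    """Extract the CA trace of one chain from a PDB file.

    Every non-hetero residue with a CA atom contributes one site, in file
    order; residues lacking a CA are skipped with a logged warning.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties: first in file).  Only the first model of multi-model files is
    used.

    Raises
    ------
    ValueError
        If the chain is absent (the message lists available chains), if the
        chain has fewer than 2 CA sites, or if two sites share the same
        (residue number, insertion code) after altloc resolution.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(pdb_source, io.TextIOBase):
        pdb_file = PDBFile.read(pdb_source)
    else:
        pdb_file = PDBFile.read(str(pdb_source))
        pdb_source = Path(pdb_source)
    atoms = pdb_file.get_structure(
        model=1, altloc="occupancy", extra_fields=["b_factor", "occupancy"]
    )
    atoms = atoms[~atoms.hetero]
    available = sorted(set(atoms.chain_id))
    mask = atoms.chain_id == chain
    if not mask.any():
        raise ValueError(
            f"chain {chain!r} not found; available chains: {{{', '.join(available)}}}"
        )
    chain_atoms = atoms[mask]
    ca = chain_atoms[chain_atoms.atom_name == "CA"]
    if ca.array_length() == 0:
        raise ValueError(f"chain {chain!r} contains no CA atoms")
    if ca.array_length() < 2:
        raise ValueError(f"chain {chain!r} has fewer than 2 CA sites")

    labels = [
        f"{res_id}{ins.strip()}" for res_id, ins in zip(ca.res_id, ca.ins_code)
    ]
    dupes = pd.Series(labels)[pd.Series(labels).duplicated()].unique()
    if len(dupes):
        raise ValueError(
            f"duplicate residue identifiers after altloc resolution: {list(dupes)}"
        )

    n_res_total = struc.get_residue_count(chain_atoms)
    n_skipped = n_res_total - ca.array_length()
    if n_skipped > 0:
        logger.warning(
            "chain %s: skipped %d residue(s) lacking a CA atom", chain, n_skipped
        )

    protein_id = "structure"
    if isinstance(pdb_source, Path):
        protein_id = pdb_source.stem
    return CaTrace(
        protein_id=protein_id,
        chain_id=chain,
        site_labels=tuple(labels),
        coords=ca.coord,
        bfactors=ca.b_factor,
    )


def make_helix_trace(n_sites: int, protein_id: str = "helix") -> CaTrace:
    """Ideal alpha-helical CA trace (deterministic, no randomness).

    Textbook helix geometry: cylinder radius 2.3 A, rise 1.5 A per residue,
    100 degrees of rotation per residue, giving consecutive CA-CA virtual
    bonds of ~3.8 A.
    """
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2")
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    i = np.arange(n_sites)
    coords = np.column_stack(
        [radius * np.cos(twist * i), radius * np.sin(twist * i), rise * i]
    )
    labels = tuple(str(k + 1) for k in range(n_sites))
    return CaTrace(protein_id=protein_id, chain_id="A", site_labels=labels, coords=coords)


def make_compact_globule_trace(
    n_sites: int,
    seed: int,
    protein_id: str | None = None,
    bond_length: float = 3.8,
    min_separation: float = 3.5,
    radius_coeff: float = 3.0,
    max_restarts: int = 500,
) -> CaTrace:
    """Self-avoiding CA chain confined to a sphere, mimicking a folded globule.

    Consecutive sites are exactly ``bond_length`` (3.8 A) apart; all other
    pairs are at least ``min_separation`` (3.5 A) apart; the chain lives in
    a sphere of radius ``radius_coeff * n_sites**(1/3)`` so the mean density
    is comparable to single-domain globular proteins.  Reproducible for a
    given seed.  The resulting ANM contact graph at a 13 A cutoff is
    connected by construction (consecutive bonds are well inside the
    cutoff); this is verified post hoc and the chain regrown otherwise.
    """
    if n_sites < 10:
        raise ValueError("n_sites must be >= 10")
    radius = radius_coeff * n_sites ** (1.0 / 3.0)
    rng = np.random.default_rng(seed)

    def _grow() -> np.ndarray | None:
        pts = np.empty((n_sites, 3))
        # Start near the centre so the chain has room in every direction.
        start = rng.uniform(-1.0, 1.0, size=3)
        pts[0] = start / max(np.linalg.norm(start), 1e-9) * rng.uniform(0, radius / 3)
        for k in range(1, n_sites):
            placed = False
            for _ in range(300):
                v = rng.normal(size=3)
                cand = pts[k - 1] + bond_length * v / np.linalg.norm(v)
                if np.linalg.norm(cand) > radius:
                    continue
                if k >= 2:
                    d2 = np.sum((pts[: k - 1] - cand) ** 2, axis=1)
                    if d2.min() < min_separation**2:
                        continue
                pts[k] = cand
                placed = True
                break
            if not placed:
                return None
        return pts

    for _ in range(max_restarts):
        pts = _grow()
        if pts is None:
            continue
        if _anm_connected(pts, rcut=13.0):
            if protein_id is None:
                protein_id = f"globule{seed}"
            labels = tuple(str(k + 1) for k in range(n_sites))
            return CaTrace(
                protein_id=protein_id, chain_id="A", site_labels=labels, coords=pts
            )
    raise RuntimeError(
        "failed to grow a compact globule within the attempt budget; "
        "try a larger radius_coeff"
    )


def _anm_connected(coords: np.ndarray, rcut: float) -> bool:
    from scipy.sparse.csgraph import connected_components

    d = squareform(pdist(coords))
    adj = (d <= rcut) & ~np.eye(len(coords), dtype=bool)
    n_comp, _ = connected_components(adj, directed=False)
    return n_comp == 1
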