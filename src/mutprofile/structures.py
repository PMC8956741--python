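"""3D mutation clustering on protein structures.

Residue-residue contacts (any atom pair within 5 angstroms) are required to
be reproducible across independent crystal structures and across the chains
within each structure before entering the contact graph: with S structures a
contact must hold in at least ceil(2S/3) of them, and a structure counts as
supporting only when at least ceil(2C/3) of its C chains show the contact.
A candidate 3D cluster is the closed neighborhood of any residue with at
least one contact neighbor; its summed missense-mutation count is tested
against a permutation null in which each individual mutation is reassigned
uniformly at random among the resolved residues (multinomial placement),
with the add-one p-value estimator p = (1 + #{null >= observed}) / (1 + B).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from mutprofile.datamodel import ThresholdConfig


def _structure_contacts(
    path,
    cutoff: float,
    include_hydrogens: bool = False,
) -> tuple[set[int], set[tuple[int, int]], int]:
    """Per-structure analysis.

    Returns (resolved residues, contact pairs supported by >= ceil(2C/3) of
    the C chains, number of chains).  Contacts are intra-chain, all-atom.
    """
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    atoms = atoms[atoms.hetero == False]  # noqa: E712 - biotite boolean mask
    if not include_hydrogens:
        atoms = atoms[atoms.element != "H"]
    chains = sorted(set(atoms.chain_id.tolist()))
    n_chains = len(chains)
    if n_chains == 0:
        raise ValueError(f"no polymer chains in {path}")
    need_chains = math.ceil(2 * n_chains / 3)

    resolved: set[int] = set()
    support: dict[tuple[int, int], int] = {}
    for chain in chains:
        sub = atoms[atoms.chain_id == chain]
        res_ids = sub.res_id
        resolved.update(int(r) for r in set(res_ids.tolist()))
        tree = cKDTree(sub.coord)
        pairs = tree.query_pairs(cutoff)
        chain_pairs: set[tuple[int, int]] = set()
        for i, j in pairs:
            a, b = int(res_ids[i]), int(res_ids[j])
            if a == b:
                continue
            chain_pairs.add((min(a, b), max(a, b)))
        for p in chain_pairs:
            support[p] = support.get(p, 0) + 1
    kept = {p for p, c in support.items() if c >= need_chains}
    return resolved, kept, n_chains


@dataclass
class ContactGraph:
    """Undirected residue contact graph with multi-structure support counts."""

    residues: frozenset           # residues eligible as cluster members
    edges: frozenset              # frozenset of (a, b) tuples, a < b
    n_structures: int

    def neighbors(self, residue: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == residue:
                out.add(b)
            elif b == residue:
                out.add(a)
        return out


def build_contact_graph(
    structure_paths: list,
    thr: ThresholdConfig | None = None,
    include_hydrogens: bool = False,
) -> ContactGraph:
    """Reproducible contact graph over one or more PDB structures.

    The graph is invariant to the file order of the structures.  Residues
    are eligible when resolved in at least the same minimum number of
    structures a contact needs for support.
    """
    thr = thr or ThresholdConfig()
    if not structure_paths:
        raise ValueError("at least one structure is required")
    per_structure = [
        _structure_contacts(p, thr.contact_dist, include_hydrogens)
        for p in structure_paths
    ]
    n_struct = len(per_structure)
    need_struct = math.ceil(2 * n_struct / 3)

    res_support: dict[int, int] = {}
    edge_support: dict[tuple[int, int], int] = {}
    for resolved, kept, _ in per_structure:
        for r in resolved:
            res_support[r] = res_support.get(r, 0) + 1
        for e in kept:
            edge_support[e] = edge_support.get(e, 0) + 1

    residues = frozenset(r for r, c in res_support.items() if c >= need_struct)
    if not residues:
        raise ValueError("no residue is resolved in enough structures")
    edges = frozenset(
        e for e, c in edge_support.items()
        if c >= need_struct and e[0] in residues and e[1] in residues
    )
    return ContactGraph(residues=residues, edges=edges, n_structures=n_struct)


@dataclass
class Cluster3D:
    center: int
    members: frozenset            # center + its contact neighbors
    count: int = 0
    p_value: float | None = None
    significant: bool = False


def enumerate_clusters(graph: ContactGraph) -> list[Cluster3D]:
    """One candidate cluster per residue with at least one neighbor."""
    clusters = []
    for r in sorted(graph.residues):
        nb = graph.neighbors(r)
        if nb:
            clusters.append(Cluster3D(center=r, members=frozenset({r} | nb)))
    return clusters


def permutation_test_clusters(
    clusters: list[Cluster3D],
    counts: dict[int, int],
    graph: ContactGraph,
    n_perm: int | None = None,
    seed: int | None = None,
    thr: ThresholdConfig | None = None,
    scheme: str = "multinomial",
) -> list[Cluster3D]:
    """Permutation significance of cluster mutation sums.

    ``scheme='multinomial'`` (default) reassigns every individual mutation
    uniformly among resolved residues; ``scheme='residue-shuffle'`` permutes
    the observed per-residue count vector over residues.  Deterministic for
    a fixed seed; p-values are never 0 by construction.
    """
    thr = thr or ThresholdConfig()
    n_perm = n_perm if n_perm is not None else thr.n_perm
    seed = seed if seed is not None else thr.rng_seed
    residues = sorted(graph.residues)
    index = {r: i for i, r in enumerate(residues)}
    vec = np.zeros(len(residues), dtype=np.int64)
    for r, k in counts.items():
        if r in index:
            vec[index[r]] += k
    n_mut = int(vec.sum())
    if n_mut == 0:
        return []

    member_mat = np.zeros((len(clusters), len(residues)), dtype=np.int64)
    for ci, cl in enumerate(clusters):
        for r in cl.members:
            if r in index:
                member_mat[ci, index[r]] = 1
    observed = member_mat @ vec

    rng = np.random.default_rng(seed)
    if scheme == "multinomial":
        p_uniform = np.full(len(residues), 1.0 / len(residues))
        null = rng.multinomial(n_mut, p_uniform, size=n_perm)
    elif scheme == "residue-shuffle":
        null = np.empty((n_perm, len(residues)), dtype=np.int64)
        for b in range(n_perm):
            null[b] = rng.permutation(vec)
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")
    null_sums = null @ member_mat.T          # (n_perm, n_clusters)

    out = []
    for ci, cl in enumerate(clusters):
        obs = int(observed[ci])
        p = (1 + int((null_sums[:, ci] >= obs).sum())) / (1 + n_perm)
        out.append(
            Cluster3D(
                center=cl.center, members=cl.members, count=obs,
                p_value=p, significant=p < thr.alpha,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Toy structure generation (text-only PDB fixtures)
# ---------------------------------------------------------------------------

def write_toy_structure(
    path,
    coords: dict[int, tuple[float, float, float]],
    chains: tuple[str, ...] = ("A", "B", "C"),
    chain_offset: float = 100.0,
    perturb: dict[str, dict[int, tuple[float, float, float]]] | None = None,
) -> Path:
    """Write a minimal valid PDB with one CA atom per residue per chain.

    Chains are copies of ``coords`` translated far apart (``chain_offset``
    along x per chain) so no inter-chain contact arises.  ``perturb``
    optionally overrides coordinates for specific residues of specific
    chains, to break a contact in a subset of chains.
    """
    n_res = len(coords)
    atoms = struc.AtomArray(n_res * len(chains))
    i = 0
    for c_idx, chain in enumerate(chains):
        shift = np.array([chain_offset * c_idx, 0.0, 0.0])
        for res_id in sorted(coords):
            xyz = np.array(coords[res_id], dtype=float)
            if perturb and chain in perturb and res_id in perturb[chain]:
                xyz = np.array(perturb[chain][res_id], dtype=float)
            atoms.coord[i] = xyz + shift
            atoms.chain_id[i] = chain
            atoms.res_id[i] = res_id
            atoms.res_name[i] = "ALA"
            atoms.atom_name[i] = "CA"
            atoms.element[i] = "C"
            atoms.hetero[i] = False
            i += 1
    pdb = PDBFile()
    pdb.set_structure(atoms)
    path = Path(path)
    pdb.write(str(path))
    return path
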