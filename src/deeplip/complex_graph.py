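"""Spatial interaction graph of a protein-ligand complex.

Nodes are the heavy atoms of the ligand and the pocket (hydrogens are
excluded by default since PDBbind-style pockets usually lack them).
Covalent edges come from the ligand's bond block and, inside the pocket,
from a covalent-radius criterion (pocket PDB files carry no CONECT
records); non-covalent edges connect every remaining atom pair within a
distance threshold.  Every edge is stored in both directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GraphConstructionError
from .structure_io import ComplexSample, Ligand, Pocket

GRAPH_RECIPE_ID = "atom19-v1"

ELEMENT_VOCAB = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "H", "other")
MAX_DEGREE = 5
FEATURE_DIM = len(ELEMENT_VOCAB) + (MAX_DEGREE + 1) + 1 + 1  # 19

COVALENT_EDGE_TYPES = ("covalent:single", "covalent:double",
                       "covalent:triple", "covalent:aromatic")
NONCOVALENT_EDGE_TYPE = "noncovalent"
EDGE_TYPES = COVALENT_EDGE_TYPES + (NONCOVALENT_EDGE_TYPE,)

_ORDER_TO_TYPE = {"single": "covalent:single", "double": "covalent:double",
                  "triple": "covalent:triple", "aromatic": "covalent:aromatic"}

#: Single-bond covalent radii (Angstrom); used with a +0.4 A tolerance.
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
}
_DEFAULT_RADIUS = 0.77
_RADIUS_TOL = 0.4


@dataclass
class GraphConfig:
    distance_threshold: float = 4.5  # A, the PotentialNet convention
    include_pocket_covalent: bool = True
    include_hydrogens: bool = False
    recipe_id: str = GRAPH_RECIPE_ID

    def __post_init__(self):
        if self.distance_threshold <= 0:
            raise ValueError("distance_threshold must be positive")


@dataclass
class SpatialGraph:
    """Typed-edge graph over complex atoms.

    ``edges`` holds directed entries ``(i, j, edge_type, distance)``; every
    undirected edge appears in both directions with equal type/distance.
    """
    node_features: np.ndarray            # (n_nodes, FEATURE_DIM)
    edges: List[Tuple[int, int, str, float]]
    ligand_mask: np.ndarray              # bool, (n_nodes,)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def typed_index(self) -> Dict[str, np.ndarray]:
        """Per edge type, an int array of shape (2, m): rows (dst, src)."""
        out: Dict[str, List[Tuple[int, int]]] = {t: [] for t in EDGE_TYPES}
        for i, j, t, _ in self.edges:
            out[t].append((i, j))
        return {t: (np.array(pairs, dtype=np.intp).T if pairs
                    else np.zeros((2, 0), dtype=np.intp))
                for t, pairs in out.items()}

    def to_edge_table(self) -> str:
        """Plain-text node/edge dump for debugging."""
        lines = [f"# nodes {self.n_nodes}  ligand {int(self.ligand_mask.sum())}"]
        lines.append("# i j type distance")
        for i, j, t, d in self.edges:
            lines.append(f"{i} {j} {t} {d:.3f}")
        return "\n".join(lines) + "\n"


def atom_features(element: str, formal_charge: int, degree: int,
                  is_ligand: bool) -> np.ndarray:
    """19-dim node feature: one-hot element (11) + one-hot degree 0-5 (6)
    + formal charge (1) + ligand flag (1).  Unknown elements map to
    'other'; degrees above 5 clamp to 5."""
    vec = np.zeros(FEATURE_DIM)
    try:
        vec[ELEMENT_VOCAB.index(element)] = 1.0
    except ValueError:
        vec[ELEMENT_VOCAB.index("other")] = 1.0
    vec[len(ELEMENT_VOCAB) + min(max(int(degree), 0), MAX_DEGREE)] = 1.0
    vec[-2] = float(formal_charge)
    vec[-1] = 1.0 if is_ligand else 0.0
    return vec


def _complex_atoms(ligand: Ligand, pocket: Pocket, include_hydrogens: bool):
    """Combined node list (ligand first), with ligand bond remapping."""
    lig_keep = [k for k, a in enumerate(ligand.atoms)
                if include_hydrogens or a.element != "H"]
    poc_keep = [k for k, a in enumerate(pocket.atoms)
                if include_hydrogens or a.element != "H"]
    remap = {old: new for new, old in enumerate(lig_keep)}
    elements = ([ligand.atoms[k].element for k in lig_keep]
                + [pocket.atoms[k].element for k in poc_keep])
    coords = np.array([ligand.atoms[k].coords for k in lig_keep]
                      + [pocket.atoms[k].coords for k in poc_keep])
    charges = ([ligand.atoms[k].formal_charge for k in lig_keep]
               + [0] * len(poc_keep))
    n_lig = len(lig_keep)
    bonds = [(remap[b.i], remap[b.j], b.order) for b in ligand.bonds
             if b.i in remap and b.j in remap]
    return elements, coords, charges, n_lig, bonds


def _pocket_covalent_pairs(elements: List[str], coords: np.ndarray,
                           n_lig: int) -> List[Tuple[int, int, float]]:
    """Covalent-radius rule d <= r_i + r_j + 0.4 A among pocket atoms."""
    idx = np.arange(n_lig, coords.shape[0])
    if idx.size < 2:
        return []
    sub = coords[idx]
    radii = np.array([COVALENT_RADII.get(elements[k], _DEFAULT_RADIUS)
                      for k in idx])
    dmat = cdist(sub, sub)
    cutoff = radii[:, None] + radii[None, :] + _RADIUS_TOL
    out = []
    ii, jj = np.nonzero((dmat <= cutoff) & (dmat > 1e-8))
    for a, b in zip(ii, jj):
        if a < b:
            out.append((int(idx[a]), int(idx[b]), float(dmat[a, b])))
    return out


def noncovalent_edges(ligand: Ligand, pocket: Pocket, threshold: float,
                      include_hydrogens: bool = False,
                      include_pocket_covalent: bool = True,
                      ) -> List[Tuple[int, int, float]]:
    """All atom pairs (within and across molecules) at Euclidean distance
    <= threshold that are not covalently bonded; directed, both ways.

    Indices refer to the combined node ordering (ligand atoms first).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    elements, coords, _, n_lig, bonds = _complex_atoms(
        ligand, pocket, include_hydrogens)
    excluded: Set[Tuple[int, int]] = set()
    for i, j, _ in bonds:
        excluded.add((min(i, j), max(i, j)))
    if include_pocket_covalent:
        for i, j, _ in _pocket_covalent_pairs(elements, coords, n_lig):
            excluded.add((i, j))
    dmat = cdist(coords, coords)
    ii, jj = np.nonzero(dmat <= threshold)
    out = []
    for a, b in zip(ii, jj):
        a, b = int(a), int(b)
        if a == b or (min(a, b), max(a, b)) in excluded:
            continue
        out.append((a, b, float(dmat[a, b])))
    return out


def build_complex_graph(sample: ComplexSample,
                        config: Optional[GraphConfig] = None) -> SpatialGraph:
    """Assemble the full spatial graph for one complex."""
    config = config or GraphConfig()
    elements, coords, charges, n_lig, bonds = _complex_atoms(
        sample.ligand, sample.pocket, config.include_hydrogens)
    n = len(elements)
    if n_lig == 0:
        raise GraphConstructionError(
            f"sample {sample.id!r}: no ligand heavy atoms")
    if n == n_lig:
        raise GraphConstructionError(
            f"sample {sample.id!r}: no pocket heavy atoms")

    edges: List[Tuple[int, int, str, float]] = []
    degree = np.zeros(n, dtype=int)

    def add_undirected(i, j, etype, dist):
        edges.append((i, j, etype, dist))
        edges.append((j, i, etype, dist))

    for i, j, order in bonds:
        d = float(np.linalg.norm(coords[i] - coords[j]))
        add_undirected(i, j, _ORDER_TO_TYPE[order], d)
        degree[i] += 1
        degree[j] += 1
    if config.include_pocket_covalent:
        for i, j, d in _pocket_covalent_pairs(elements, coords, n_lig):
            add_undirected(i, j, "covalent:single", d)
            degree[i] += 1
            degree[j] += 1

    nc = noncovalent_edges(sample.ligand, sample.pocket,
                           config.distance_threshold,
                           include_hydrogens=config.include_hydrogens,
                           include_pocket_covalent=config.include_pocket_covalent)
    for i, j, d in nc:
        edges.append((i, j, NONCOVALENT_EDGE_TYPE, d))

    feats = np.stack([
        atom_features(elements[k], charges[k], int(degree[k]), k < n_lig)
        for k in range(n)])
    mask = np.zeros(n, dtype=bool)
    mask[:n_lig] = True
    return SpatialGraph(feats, edges, mask)
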