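"""Residue interaction network construction from alternate conformations.

A residue interaction network (RIN) is built for one multiconformer
structure from two classes of coupling evidence:

* **spatial** — heavy atoms that carry a non-blank altloc label on two
  residues lie within a distance cutoff (default 4 Å), with at least one of
  the two residues having multiple conformers.  The edge weight is the count
  of distinct in-contact altloc atom pairs, normalized by residue size (sum
  of the two residues' unique atom counts), so large residues do not
  dominate simply by having more atoms.
* **sequential** — alternate backbone conformations of sequence-adjacent
  residues are mechanically coupled through the peptide bond.  Maximal runs
  of consecutive residues whose backbones are split into altlocs are
  detected, and each adjacent pair inside a run receives an edge weighted by
  its backbone altloc contact count, normalized the same way.

Sequence-adjacent pairs are handled exclusively by the sequential rule;
the spatial rule skips them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structure_io import MulticonformerStructure, ResidueModel

#: Edge provenance labels.
SPATIAL, SEQUENTIAL, BOTH = "spatial", "sequential", "both"

NodeKey = tuple[str, str]  # (chain_id, residue label)


@dataclass(frozen=True)
class RINParams:
    """Knobs for network construction.

    contact_cutoff
        Heavy-atom distance threshold in Å (default 4.0).
    min_conformers
        Minimum conformer count required on at least one residue of a pair
        (``require_both=True`` demands it on both) for spatial contacts.
    size_normalization
        ``sum_atoms``: divide contact counts by U_A + U_B (unique atom names
        per residue); ``geometric_mean``: divide by sqrt(U_A * U_B).
    """

    contact_cutoff: float = 4.0
    min_conformers: int = 2
    require_both: bool = False
    size_normalization: str = "sum_atoms"

    def __post_init__(self):
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")
        if self.size_normalization not in {"sum_atoms", "geometric_mean"}:
            raise ValueError(
                f"unknown size_normalization {self.size_normalization!r}"
            )


@dataclass
class ResidueRIN:
    """Weighted undirected residue graph for one structure.

    Edges are stored with the lower residue key first; weights are
    non-negative; provenance marks each edge spatial, sequential or both.
    """

    structure_id: str
    nodes: set[NodeKey] = field(default_factory=set)
    edges: dict[tuple[NodeKey, NodeKey], float] = field(default_factory=dict)
    provenance: dict[tuple[NodeKey, NodeKey], str] = field(default_factory=dict)

    def add_edge(self, a: NodeKey, b: NodeKey, weight: float, kind: str) -> None:
        if a == b:
            raise ValueError("self-edges are not allowed")
        if weight <= 0:
            return
        key = (a, b) if a <= b else (b, a)
        if key in self.edges:
            self.edges[key] += weight
            if self.provenance[key] != kind:
                self.provenance[key] = BOTH
        else:
            self.edges[key] = weight
            self.provenance[key] = kind
        self.nodes.update(key)

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(structure_id=self.structure_id)
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w, provenance=self.provenance[(a, b)])
        return g


def _size_norm(res_a: ResidueModel, res_b: ResidueModel, params: RINParams) -> float:
    ua = len(res_a.unique_atom_names())
    ub = len(res_b.unique_atom_names())
    if params.size_normalization == "geometric_mean":
        return float(np.sqrt(ua * ub))
    return float(ua + ub)


def _contact_pair_count(
    atoms_a, atoms_b, cutoff: float
) -> int:
    """Distinct (name_A, altloc_A, name_B, altloc_B) pairs within cutoff."""
    if not atoms_a or not atoms_b:
        return 0
    xa = np.array([a.xyz for a in atoms_a], dtype=float)
    xb = np.array([b.xyz for b in atoms_b], dtype=float)
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
    return int(np.count_nonzero(d2 <= cutoff * cutoff))


def spatial_contact_weight(
    res_a: ResidueModel, res_b: ResidueModel, params: RINParams | None = None
) -> float:
    """Spatial coupling weight between two (non sequence-adjacent) residues.

    Counts distinct altloc atom pairs within the cutoff over all conformer
    combinations, then divides by the residue-size normalizer.  Returns 0
    unless at least one residue (both, with ``require_both``) has at least
    ``min_conformers`` conformers.
    """
    params = params or RINParams()
    if params.require_both:
        eligible = (res_a.n_conformers >= params.min_conformers
                    and res_b.n_conformers >= params.min_conformers)
    else:
        eligible = (res_a.n_conformers >= params.min_conformers
                    or res_b.n_conformers >= params.min_conformers)
    if not eligible:
        return 0.0
    p = _contact_pair_count(
        res_a.altloc_atoms(), res_b.altloc_atoms(), params.contact_cutoff
    )
    if p == 0:
        return 0.0
    return p / _size_norm(res_a, res_b, params)


def _adjacent(res_i: ResidueModel, res_j: ResidueModel) -> bool:
    """Sequence adjacency: same chain, consecutive author numbering (an
    insertion-coded residue is adjacent to its same-numbered neighbour)."""
    if res_i.chain_id != res_j.chain_id:
        return False
    return abs(res_j.seq_num - res_i.seq_num) <= 1 and res_i.key != res_j.key


def sequential_backbone_edges(
    chain: list[ResidueModel], params: RINParams | None = None
) -> list[tuple[NodeKey, NodeKey, float]]:
    """Edges from coupled backbone altlocs of sequence-adjacent residues.

    Scans the ordered chain for maximal runs of consecutive residues in
    which every residue has >= 2 backbone conformers; the run extends
    recursively while that condition holds.  Each adjacent pair (i, i+1)
    inside a run gets an edge weighted by the number of backbone altloc
    atom pairs (N/CA/C/O against N/CA/C/O, across altloc combinations)
    within the cutoff, size-normalized.  Runs of length 1 produce no edges.
    """
    params = params or RINParams()
    edges: list[tuple[NodeKey, NodeKey, float]] = []

    def flush(run: list[ResidueModel]) -> None:
        for r_i, r_j in zip(run, run[1:]):
            bb_i = [a for a in r_i.altloc_atoms() if a.is_backbone]
            bb_j = [a for a in r_j.altloc_atoms() if a.is_backbone]
            b = _contact_pair_count(bb_i, bb_j, params.contact_cutoff)
            if b > 0:
                w = b / _size_norm(r_i, r_j, params)
                a_key: NodeKey = (r_i.chain_id, r_i.label)
                b_key: NodeKey = (r_j.chain_id, r_j.label)
                edges.append((a_key, b_key, w))

    run: list[ResidueModel] = []
    for res in chain:
        if res.has_backbone_altlocs() and (
            not run or _adjacent(run[-1], res)
        ):
            run.append(res)
        else:
            flush(run)
            run = [res] if res.has_backbone_altlocs() else []
    flush(run)
    return edges


def build_network(
    structure: MulticonformerStructure, params: RINParams | None = None
) -> ResidueRIN:
    """Build the full RIN: spatial edges over all non-adjacent residue pairs
    plus sequential backbone edges, zero-weight edges omitted.

    A coarse bounding-sphere pre-filter skips residue pairs that cannot have
    atoms within the cutoff; results are identical to the all-pairs scan.
    """
    params = params or RINParams()
    rin = ResidueRIN(structure_id=structure.structure_id)
    residues = structure.residues()

    # bounding spheres over altloc atoms only (the atoms that can interact)
    centers = np.full((len(residues), 3), np.nan)
    radii = np.zeros(len(residues))
    flagged = np.zeros(len(residues), dtype=bool)
    for i, res in enumerate(residues):
        alt = res.altloc_atoms()
        if alt:
            xyz = np.array([a.xyz for a in alt], dtype=float)
            centers[i] = xyz.mean(axis=0)
            radii[i] = float(np.linalg.norm(xyz - centers[i], axis=1).max())
            flagged[i] = True

    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if not (flagged[i] and flagged[j]):
                continue  # spatial contacts need altloc atoms on both sides
            if _adjacent(residues[i], residues[j]):
                continue
            gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
            if gap > params.contact_cutoff:
                continue
            w = spatial_contact_weight(residues[i], residues[j], params)
            if w > 0:
                rin.add_edge(
                    (residues[i].chain_id, residues[i].label),
                    (residues[j].chain_id, residues[j].label),
                    w, SPATIAL,
                )

    for cid in sorted(structure.chains):
        for a, b, w in sequential_backbone_edges(structure.chains[cid], params):
            rin.add_edge(a, b, w, SEQUENTIAL)
    return rin


def brute_force_network(
    structure: MulticonformerStructure, params: RINParams | None = None
) -> ResidueRIN:
    """Reference O(n² · atoms²) construction with no pre-filtering.

    Kept deliberately naive (explicit double loop, no bounding spheres) as
    the oracle for equivalence testing against :func:`build_network`.
    """
    params = params or RINParams()
    rin = ResidueRIN(structure_id=structure.structure_id)
    residues = structure.residues()
    for i in range(len(residues)):
        for j in range(i + 1, len(residues)):
            if _adjacent(residues[i], residues[j]):
                continue
            w = 0.0
            ri, rj = residues[i], residues[j]
            if params.require_both:
                ok = (ri.n_conformers >= params.min_conformers
                      and rj.n_conformers >= params.min_conformers)
            else:
                ok = (ri.n_conformers >= params.min_conformers
                      or rj.n_conformers >= params.min_conformers)
            if ok:
                count = 0
                for a in ri.altloc_atoms():
                    for b in rj.altloc_atoms():
                        d = np.linalg.norm(
                            np.array(a.xyz) - np.array(b.xyz))
                        if d <= params.contact_cutoff:
                            count += 1
                if count:
                    w = count / _size_norm(ri, rj, params)
            if w > 0:
                rin.add_edge((ri.chain_id, ri.label),
                             (rj.chain_id, rj.label), w, SPATIAL)
    for cid in sorted(structure.chains):
        for a, b, w in sequential_backbone_edges(structure.chains[cid], params):
            rin.add_edge(a, b, w, SEQUENTIAL)
    return rin
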