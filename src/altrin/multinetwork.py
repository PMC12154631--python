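"""Multinetwork assembly and comparison.

Individual residue interaction networks are re-indexed onto common MSA
columns, log-normalized by their total edge weight (so well-ordered
high-resolution structures with many alternate conformations do not swamp
the aggregate), and collected with their metadata into a *multinetwork*.
From there: sum networks over metadata-defined subsets, pruning to the
strongest edges, per-residue weighted degree, Δdegree between subsets,
a random-half negative control, and a resolution-balance test used to
check that two subsets are comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable

import networkx as nx
import numpy as np
from scipy import stats

from .msa_map import AlignmentMap
from .rin_builder import ResidueRIN
from .structure_io import StructureMetadata

EdgeKey = tuple[int, int]  # (column_i, column_j), i < j


@dataclass
class AlignedRIN:
    """A per-structure RIN keyed by alignment columns.

    ``dropped_edges`` counts edges lost because an endpoint residue has no
    alignment column.  ``raw_total`` and ``scale`` record the
    log-normalization applied (scale is 1.0 before normalization).
    """

    structure_id: str
    edges: dict[EdgeKey, float] = field(default_factory=dict)
    dropped_edges: int = 0
    raw_total: float | None = None
    scale: float = 1.0

    @property
    def nodes(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def total_weight(self) -> float:
        return float(sum(self.edges.values()))


@dataclass
class Multinetwork:
    """Normalized aligned RINs + metadata, sharing one column space."""

    rins: list[AlignedRIN]
    metadata: dict[str, StructureMetadata]
    reference_id: str
    column_to_reference: dict[int, int]

    def __len__(self) -> int:
        return len(self.rins)

    def structure_ids(self) -> list[str]:
        return [r.structure_id for r in self.rins]

    def select(self, predicate: Callable[[StructureMetadata], bool]) -> list[AlignedRIN]:
        return [r for r in self.rins if predicate(self.metadata[r.structure_id])]


@dataclass
class SumNetwork:
    """Per-edge aggregation of normalized RINs over a structure subset."""

    edges: dict[EdgeKey, float]
    n_contributing: int
    averaged: bool = False
    label: str = ""
    #: fraction this network was already trimmed at (None = untrimmed)
    trim_fraction: float | None = None

    @property
    def nodes(self) -> set[int]:
        out: set[int] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return out

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(label=self.label)
        g.add_nodes_from(sorted(self.nodes))
        for (a, b), w in sorted(self.edges.items()):
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class DeltaDegreeProfile:
    """Signed per-residue degree difference between two subset networks.

    ``by_reference`` is keyed by reference residue number; columns without
    an analogous reference residue are reported in ``unreferenced`` keyed
    by alignment column.  Sign convention: first subset minus second.
    """

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    by_reference: dict[int, float]
    unreferenced: dict[int, float]

    def mean_all(self) -> float:
        vals = list(self.by_reference.values()) + list(self.unreferenced.values())
        return float(np.mean(vals)) if vals else 0.0

    def mean_nonzero(self) -> float:
        vals = [v for v in
                list(self.by_reference.values()) + list(self.unreferenced.values())
                if v != 0.0]
        return float(np.mean(vals)) if vals else 0.0


# ---------------------------------------------------------------------------
# alignment & normalization


def align_rin(rin: ResidueRIN, amap: AlignmentMap) -> AlignedRIN:
    """Re-key a RIN's residues to alignment columns.

    Edges with both endpoints mapped are retained (summed if two residue
    pairs collapse onto one column pair, which cannot happen for an
    injective map); edges touching unmapped residues are dropped and
    counted.
    """
    if rin.structure_id != amap.structure_id:
        raise ValueError(
            f"structure_id mismatch: RIN {rin.structure_id!r} vs "
            f"map {amap.structure_id!r}"
        )
    out = AlignedRIN(structure_id=rin.structure_id)
    for ((_, label_a), (_, label_b)), w in rin.edges.items():
        ca = amap.column_of(label_a)
        cb = amap.column_of(label_b)
        if ca is None or cb is None:
            out.dropped_edges += 1
            continue
        key = (ca, cb) if ca < cb else (cb, ca)
        out.edges[key] = out.edges.get(key, 0.0) + w
    return out


def log_normalize(rin: AlignedRIN) -> AlignedRIN:
    """Scale a network so its total edge weight T becomes ln(1 + T).

    Networks with T <= 1 are left unchanged (ln(1+T) > T there, and tiny
    networks should not be amplified).  The raw total and scale factor are
    recorded, making the transform invertible.
    """
    t = rin.total_weight
    scale = math.log1p(t) / t if t > 1.0 else 1.0
    return AlignedRIN(
        structure_id=rin.structure_id,
        edges={k: w * scale for k, w in rin.edges.items()},
        dropped_edges=rin.dropped_edges,
        raw_total=t,
        scale=scale,
    )


def build_multinetwork(
    rins: list[AlignedRIN],
    metadata: Iterable[StructureMetadata],
    reference_id: str = "",
    column_to_reference: dict[int, int] | None = None,
) -> Multinetwork:
    """Join normalized aligned RINs with their metadata rows.

    Structures lacking a metadata row get a stub record with unknown fields.
    """
    if not rins:
        raise ValueError("cannot build a multinetwork from zero networks")
    ids = [r.structure_id for r in rins]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate structure_id values: {dupes}")
    meta_map = {m.structure_id: m for m in metadata}
    joined = {}
    for sid in ids:
        if sid in meta_map:
            joined[sid] = meta_map[sid]
        else:
            joined[sid] = StructureMetadata(structure_id=sid)
    return Multinetwork(
        rins=list(rins),
        metadata=joined,
        reference_id=reference_id,
        column_to_reference=dict(column_to_reference or {}),
    )


# ---------------------------------------------------------------------------
# aggregation


def sum_network(
    mn: Multinetwork,
    subset: Callable[[StructureMetadata], bool] | None = None,
    per_structure_average: bool = False,
    label: str = "",
) -> SumNetwork:
    """Per-edge sum of normalized weights over a structure subset.

    With ``per_structure_average`` the sum is divided by the subset size —
    required when comparing subsets of different sizes via Δdegree.
    """
    selected = mn.rins if subset is None else mn.select(subset)
    if not selected:
        raise ValueError(f"subset {label or subset!r} selects no structures")
    edges: dict[EdgeKey, float] = {}
    for rin in selected:
        for key, w in rin.edges.items():
            edges[key] = edges.get(key, 0.0) + w
    if per_structure_average:
        edges = {k: w / len(selected) for k, w in edges.items()}
    return SumNetwork(
        edges=edges,
        n_contributing=len(selected),
        averaged=per_structure_average,
        label=label,
    )


def trim_top_fraction(net: SumNetwork, keep_fraction: float) -> SumNetwork:
    """Keep the ceil(keep_fraction * n_edges) highest-weight edges.

    All edges tied with the threshold weight are retained (deterministic
    without arbitrary ordering), so the result may exceed the nominal
    count.  Isolated nodes disappear with their edges.  Re-trimming at the
    fraction a network was already trimmed at is a no-op (the operation
    restricts the underlying sum once, not repeatedly).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    if net.trim_fraction == keep_fraction:
        return net
    if not net.edges:
        raise ValueError("cannot trim an empty network")
    n_keep = math.ceil(keep_fraction * net.n_edges)
    threshold = sorted(net.edges.values(), reverse=True)[n_keep - 1]
    kept = {k: w for k, w in net.edges.items() if w >= threshold}
    return SumNetwork(
        edges=kept,
        n_contributing=net.n_contributing,
        averaged=net.averaged,
        label=net.label,
        trim_fraction=keep_fraction,
    )


def weighted_degree(net: SumNetwork | AlignedRIN) -> dict[int, float]:
    """degree(v) = sum of weights of edges incident to v."""
    deg: dict[int, float] = {}
    for (a, b), w in net.edges.items():
        deg[a] = deg.get(a, 0.0) + w
        deg[b] = deg.get(b, 0.0) + w
    return deg


def delta_degree(
    mn: Multinetwork,
    subset_a: Callable[[StructureMetadata], bool],
    subset_b: Callable[[StructureMetadata], bool],
    label_a: str = "A",
    label_b: str = "B",
) -> DeltaDegreeProfile:
    """Δdegree(r) = degree_A(r) − degree_B(r) on per-structure-averaged,
    untrimmed subset sum networks.

    Antisymmetric under subset swap.  Residues are reported on reference
    numbering; alignment columns without an analogous reference residue go
    to the ``unreferenced`` map.
    """
    net_a = sum_network(mn, subset_a, per_structure_average=True, label=label_a)
    net_b = sum_network(mn, subset_b, per_structure_average=True, label=label_b)
    deg_a = weighted_degree(net_a)
    deg_b = weighted_degree(net_b)
    by_ref: dict[int, float] = {}
    unref: dict[int, float] = {}
    for col in sorted(set(deg_a) | set(deg_b)):
        delta = deg_a.get(col, 0.0) - deg_b.get(col, 0.0)
        ref = mn.column_to_reference.get(col)
        if ref is None:
            unref[col] = delta
        else:
            by_ref[ref] = delta
    return DeltaDegreeProfile(
        label_a=label_a, label_b=label_b,
        n_a=net_a.n_contributing, n_b=net_b.n_contributing,
        by_reference=by_ref, unreferenced=unref,
    )


def random_half_control(
    mn: Multinetwork,
    n_samples: int = 70,
    seed: int | None = None,
) -> DeltaDegreeProfile:
    """Negative control: average Δdegree over random half-splits.

    Each sample partitions the structures uniformly at random into two
    complementary halves (sizes floor(n/2) and ceil(n/2)), computes Δdegree
    between them, and the profiles are averaged element-wise.  A featureless
    mean indicates that subset Δdegree signals are not sampling artifacts.
    Reproducible for a fixed seed.
    """
    if len(mn) < 2:
        raise ValueError("random-half control needs at least 2 structures")
    rng = np.random.default_rng(seed)
    ids = mn.structure_ids()
    half = len(ids) // 2
    acc_ref: dict[int, float] = {}
    acc_unref: dict[int, float] = {}
    for _ in range(n_samples):
        perm = rng.permutation(len(ids))
        group_a = {ids[i] for i in perm[:half]}
        prof = delta_degree(
            mn,
            lambda m: m.structure_id in group_a,
            lambda m: m.structure_id not in group_a,
            label_a="half1", label_b="half2",
        )
        for k, v in prof.by_reference.items():
            acc_ref[k] = acc_ref.get(k, 0.0) + v
        for k, v in prof.unreferenced.items():
            acc_unref[k] = acc_unref.get(k, 0.0) + v
    return DeltaDegreeProfile(
        label_a="random half 1", label_b="random half 2",
        n_a=half, n_b=len(ids) - half,
        by_reference={k: v / n_samples for k, v in acc_ref.items()},
        unreferenced={k: v / n_samples for k, v in acc_unref.items()},
    )


def resolution_balance_test(
    resolutions_a: list[float],
    resolutions_b: list[float],
    alternative: str = "less",
) -> tuple[float, float]:
    """One-tailed Mann–Whitney U on two resolution distributions.

    Used to check that two structure subsets have comparable resolution
    before interpreting their Δdegree (better-resolved structures carry
    more alternate conformations).  ``alternative='less'`` tests whether
    subset A's resolutions are stochastically smaller (higher resolution).
    Returns (U statistic, p-value).
    """
    if not resolutions_a or not resolutions_b:
        raise ValueError("both resolution lists must be non-empty")
    res = stats.mannwhitneyu(
        resolutions_a, resolutions_b, alternative=alternative,
        method="auto",
    )
    return float(res.statistic), float(res.pvalue)
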