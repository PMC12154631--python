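"""Sum-network analysis: community structure and colocalization statistics.

Two questions are answered here.  First, does the aggregate network of
coupled alternate conformations organize into cohesive communities?  This
uses Girvan–Newman edge-betweenness division, choosing the partition where
weighted modularity plateaus.  Second, does the network colocalize in 3D
with externally defined residue sets (coevolving sectors, NMR-dynamic
residues, interface residues, mutation catalogs)?  This compares
nearby-network-residue counts for the set of interest against size-matched
random residue sets with a two-sample Kolmogorov–Smirnov test, plus a
Jaccard overlap ratio; a mutation-bin analysis relates network proximity to
the fraction of mutations that perturb function.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .multinetwork import SumNetwork
from .structure_io import MulticonformerStructure

logger = logging.getLogger("altrin")


@dataclass
class CommunityPartition:
    """Result of edge-betweenness community division.

    ``membership`` maps node -> community label (0-based, ordered by the
    smallest node in each community).  ``trace`` records (n_communities,
    modularity) at every level visited; ``level`` indexes the chosen
    plateau partition.
    """

    membership: dict[int, int]
    modularity: float
    level: int
    trace: list[tuple[int, float]] = field(default_factory=list)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[int]]:
        groups: dict[int, set[int]] = {}
        for node, label in self.membership.items():
            groups.setdefault(label, set()).add(node)
        return [groups[k] for k in sorted(groups)]


@dataclass
class ColocalizationResult:
    set_id: str
    observed_counts: list[float]
    random_counts: list[float]
    ks_statistic: float
    p_value: float
    jaccard: float


@dataclass(frozen=True)
class MutationRecord:
    """One curated, experimentally characterized point mutation."""

    residue: int
    influential: bool


def _weighted_modularity(graph: nx.Graph, communities: list[set]) -> float:
    return nx.community.modularity(graph, communities, weight="weight")


def _components(graph: nx.Graph) -> list[set]:
    return sorted(nx.connected_components(graph), key=min)


def girvan_newman(
    net: SumNetwork | nx.Graph,
    epsilon: float = 0.005,
    use_weights: bool = True,
) -> CommunityPartition:
    """Girvan–Newman community detection with a modularity-plateau stop.

    Iteratively removes the edge with the highest betweenness (with
    ``use_weights``, edge weight is treated as connection strength: the
    path length of an edge is 1/weight) and records the partition and
    weighted modularity each time the component count increases.  The
    chosen partition is the first level whose modularity is within
    ``epsilon`` of the running maximum and whose successor gains less than
    ``epsilon`` ("plateau").  Betweenness ties are broken by canonical edge
    order, making the division deterministic.
    """
    graph = net if isinstance(net, nx.Graph) else net.to_networkx()
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    original = graph.copy()
    work = graph.copy()
    if use_weights:
        for _, _, data in work.edges(data=True):
            data["distance"] = 1.0 / data.get("weight", 1.0)

    levels: list[list[set]] = [_components(work)]
    while work.number_of_edges() > 0:
        n_before = nx.number_connected_components(work)
        betw = nx.edge_betweenness_centrality(
            work, weight="distance" if use_weights else None
        )
        best = max(betw.values())
        # canonical tie-break: lexicographically smallest edge among maxima
        edge = min(tuple(sorted(e)) for e, v in betw.items()
                   if v >= best - 1e-12)
        work.remove_edge(*edge)
        if nx.number_connected_components(work) > n_before:
            levels.append(_components(work))

    trace = [
        (len(comms), _weighted_modularity(original, comms))
        for comms in levels
    ]
    chosen = len(levels) - 1
    running_max = -np.inf
    for k, (_, q) in enumerate(trace):
        running_max = max(running_max, q)
        next_gain = trace[k + 1][1] - q if k + 1 < len(trace) else -np.inf
        if q >= running_max - epsilon and next_gain < epsilon:
            chosen = k
            break
    communities = levels[chosen]
    membership = {
        node: label
        for label, comm in enumerate(sorted(communities, key=min))
        for node in comm
    }
    return CommunityPartition(
        membership=membership,
        modularity=trace[chosen][1],
        level=chosen,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# colocalization


def nearby_network_count(
    structure: MulticonformerStructure,
    network_residues: set[int],
    residue_to_reference: dict[str, int] | None = None,
    cutoff: float = 4.0,
) -> dict[int, int]:
    """For every residue of a representative structure, count network
    residues (other than itself) within ``cutoff`` Å minimum heavy-atom
    distance.

    ``residue_to_reference`` maps residue labels to reference numbering;
    by default author residue numbers are used directly.
    """
    residues = structure.residues()
    refs: list[int | None] = []
    coords: list[np.ndarray] = []
    for res in residues:
        if residue_to_reference is None:
            refs.append(res.seq_num if not res.icode else None)
        else:
            refs.append(residue_to_reference.get(res.label))
        coords.append(res.coords())

    counts: dict[int, int] = {}
    cutoff2 = cutoff * cutoff
    for i, ref_i in enumerate(refs):
        if ref_i is None:
            continue
        n_near = 0
        for j, ref_j in enumerate(refs):
            if i == j or ref_j is None or ref_j not in network_residues:
                continue
            if ref_j == ref_i:
                continue
            d2 = np.min(
                np.sum(
                    (coords[i][:, None, :] - coords[j][None, :, :]) ** 2,
                    axis=-1,
                )
            )
            if d2 <= cutoff2:
                n_near += 1
        counts[ref_i] = n_near
    return counts


def colocalization_test(
    counts: dict[int, float],
    set_of_interest: set[int],
    network_residues: set[int],
    n_random: int = 1000,
    seed: int | None = None,
    set_id: str = "",
    pooled: bool = True,
) -> ColocalizationResult:
    """KS comparison of nearby-network counts for a residue set of interest
    vs size-matched random residue sets.

    Random sets are drawn without replacement from all counted residues;
    their counts are pooled over ``n_random`` draws (default) or each draw
    is tested separately and the median p reported (``pooled=False``).
    The Jaccard ratio |network ∩ set| / |network ∪ set| quantifies direct
    membership overlap.
    """
    if not set_of_interest:
        raise ValueError("set of interest is empty")
    missing = set_of_interest - set(counts)
    if missing:
        raise ValueError(
            f"set of interest contains residues without counts: {sorted(missing)[:5]}"
        )
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(counts), dtype=int)
    observed = [float(counts[r]) for r in sorted(set_of_interest)]
    size = len(set_of_interest)

    draws = []
    for _ in range(n_random):
        picked = rng.choice(universe, size=size, replace=False)
        draws.append([float(counts[int(r)]) for r in picked])

    union = set_of_interest | network_residues
    jaccard = len(set_of_interest & network_residues) / len(union) if union else 0.0

    if pooled:
        random_counts = [c for d in draws for c in d]
        ks = stats.ks_2samp(observed, random_counts)
        stat, p = float(ks.statistic), float(ks.pvalue)
    else:
        results = [stats.ks_2samp(observed, d) for d in draws]
        stat = float(np.median([r.statistic for r in results]))
        p = float(np.median([r.pvalue for r in results]))
        random_counts = [c for d in draws for c in d]
    return ColocalizationResult(
        set_id=set_id,
        observed_counts=observed,
        random_counts=random_counts,
        ks_statistic=stat,
        p_value=p,
        jaccard=jaccard,
    )


def mutation_bin_analysis(
    mutations: list[MutationRecord],
    counts: dict[int, float],
    bin_edges: list[float],
) -> pd.DataFrame:
    """Bin mutations by their residue's nearby-network count; report the
    per-bin fraction that are functionally influential.

    Bins are left-inclusive / right-exclusive except the last, which is
    closed on both sides.  Empty bins report NaN (undefined), not 0.
    """
    if len(bin_edges) < 2:
        raise ValueError("need at least two bin edges")
    missing = [m.residue for m in mutations if m.residue not in counts]
    if missing:
        raise ValueError(f"mutations at residues without counts: {missing[:5]}")
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi, last in zip(edges[:-1], edges[1:],
                            [False] * (len(edges) - 2) + [True]):
        in_bin = [
            m for m in mutations
            if lo <= counts[m.residue] < hi
            or (last and counts[m.residue] == hi)
        ]
        n = len(in_bin)
        n_infl = sum(m.influential for m in in_bin)
        rows.append({
            "bin_low": lo,
            "bin_high": hi,
            "n_mutations": n,
            "n_influential": n_infl,
            "fraction_influential": n_infl / n if n else np.nan,
        })
    return pd.DataFrame(rows)


@dataclass
class DegreeConservationFit:
    slope: float
    intercept: float
    r_squared: float
    slope_stderr: float
    table: pd.DataFrame


def degree_vs_conservation(
    degrees: dict[int, float],
    conservation: dict[int, float],
) -> DegreeConservationFit:
    """OLS fit of weighted degree against sequence conservation.

    Residues present in both inputs are paired; the returned table is
    sorted by descending residual, surfacing residues with high network
    connectivity relative to their conservation (candidate sites for
    mutagenesis).  A constant-conservation input is degenerate: the fit is
    reported with slope 0 and R² 0, with a warning.
    """
    shared = sorted(set(degrees) & set(conservation))
    if len(shared) < 3:
        raise ValueError("need at least 3 residues with both degree and conservation")
    x = np.array([conservation[r] for r in shared], dtype=float)
    y = np.array([degrees[r] for r in shared], dtype=float)
    if np.ptp(x) == 0:
        warnings.warn("conservation is constant; degenerate fit, R^2 = 0")
        slope, intercept, r2, stderr = 0.0, float(np.mean(y)), 0.0, float("nan")
    else:
        fit = stats.linregress(x, y)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2, stderr = float(fit.rvalue**2), float(fit.stderr)
    resid = y - (slope * x + intercept)
    table = pd.DataFrame({
        "residue": shared,
        "conservation": x,
        "degree": y,
        "residual": resid,
    }).sort_values("residual", ascending=False).reset_index(drop=True)
    return DegreeConservationFit(
        slope=slope, intercept=intercept, r_squared=r2,
        slope_stderr=stderr, table=table,
    )
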