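"""Writers (and matching readers) for networks, profiles, multinetworks and
structure-mapped attributes.

All writers emit deterministically ordered plain text, so identical inputs
produce byte-identical artifacts.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import networkx as nx

from .multinetwork import AlignedRIN, Multinetwork, SumNetwork
from .rin_builder import ResidueRIN
from .structure_io import MulticonformerStructure, StructureMetadata

#: B-factor sentinel for residues without a mapped value.
UNMAPPED_BFACTOR = -1.0
_BFACTOR_MAX = 999.99


def write_network(
    net: SumNetwork | ResidueRIN, path: str | Path, fmt: str = "tsv_edges"
) -> Path:
    """Write a network as a sorted edge-list TSV or as GraphML.

    Per-structure RINs carry chain/residue endpoints and edge provenance;
    sum networks carry alignment-column endpoints.
    """
    path = Path(path)
    if fmt == "tsv_edges":
        with open(path, "w") as fh:
            if isinstance(net, ResidueRIN):
                fh.write("chain_i\tresnum_i\tchain_j\tresnum_j\tweight\t"
                         "provenance\n")
                for (a, b), w in sorted(net.edges.items()):
                    fh.write(f"{a[0]}\t{a[1]}\t{b[0]}\t{b[1]}\t{w:.9g}\t"
                             f"{net.provenance[(a, b)]}\n")
            else:
                fh.write("node_i\tnode_j\tweight\n")
                for (a, b), w in sorted(net.edges.items()):
                    fh.write(f"{a}\t{b}\t{w:.9g}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_networkx(), str(path))
    else:
        raise ValueError(f"unknown network format {fmt!r}")
    return path


def read_network_graphml(path: str | Path) -> nx.Graph:
    g = nx.read_graphml(str(path))
    return nx.relabel_nodes(
        g, {n: _maybe_int(n) for n in g.nodes}
    )


def _maybe_int(node):
    if isinstance(node, str):
        try:
            return int(node)
        except ValueError:
            return node
    return node


def write_profile(values: dict[int, float], path: str | Path,
                  value_name: str = "value") -> Path:
    """Per-residue profile as a two-column TSV sorted by residue."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"reference_residue\t{value_name}\n")
        for residue in sorted(values):
            fh.write(f"{residue}\t{values[residue]:.9g}\n")
    return path


def write_structure_attribute(
    structure: MulticonformerStructure,
    values: dict[int, float],
    path: str | Path,
    residue_to_reference: dict[str, int] | None = None,
) -> tuple[Path, Path]:
    """Write a PDB copy with per-residue values in the B-factor field, plus
    a per-residue TSV.

    Residues with no value get the sentinel B-factor; values outside the
    PDB field width are clamped with a warning.  Enables sphere/putty
    rendering of degree or Δdegree in molecular viewers.
    """
    import warnings

    path = Path(path)
    mapped = 0
    lines: list[str] = []
    serial = 0
    tsv_rows: list[tuple[int, float]] = []
    for cid in sorted(structure.chains):
        for res in structure.chains[cid]:
            if residue_to_reference is None:
                ref = res.seq_num if not res.icode else None
            else:
                ref = residue_to_reference.get(res.label)
            value = values.get(ref) if ref is not None else None
            if value is None:
                bfac = UNMAPPED_BFACTOR
            else:
                mapped += 1
                bfac = float(value)
                if abs(bfac) > _BFACTOR_MAX:
                    warnings.warn(
                        f"value {bfac:g} at residue {ref} exceeds the PDB "
                        f"B-factor field; clamped"
                    )
                    bfac = _BFACTOR_MAX if bfac > 0 else -_BFACTOR_MAX
                tsv_rows.append((ref, bfac))
            for atom in sorted(res.atoms(), key=lambda a: (a.altloc, a.name)):
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{atom.altloc or ' '}"
                    f"{res.res_name:<3s} {cid:1s}{res.seq_num:4d}"
                    f"{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}"
                    f"{bfac:6.2f}          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    if mapped == 0:
        raise ValueError("no residues could be mapped to the given values")
    path.write_text("\n".join(lines) + "\n")
    tsv_path = path.with_suffix(".tsv")
    write_profile(dict(tsv_rows), tsv_path)
    return path, tsv_path


# ---------------------------------------------------------------------------
# multinetwork container


def save_multinetwork(mn: Multinetwork, path: str | Path) -> Path:
    """Serialize a multinetwork as a JSON container: per-structure edge
    records (alignment-column keyed), normalization records and metadata."""
    path = Path(path)
    payload = {
        "reference_id": mn.reference_id,
        "column_to_reference": {str(k): v for k, v in
                                sorted(mn.column_to_reference.items())},
        "structures": [
            {
                "structure_id": r.structure_id,
                "raw_total": r.raw_total,
                "scale": r.scale,
                "dropped_edges": r.dropped_edges,
                "edges": [[a, b, w] for (a, b), w in sorted(r.edges.items())],
            }
            for r in mn.rins
        ],
        "metadata": [asdict(mn.metadata[r.structure_id]) for r in mn.rins],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_multinetwork(path: str | Path) -> Multinetwork:
    payload = json.loads(Path(path).read_text())
    rins = [
        AlignedRIN(
            structure_id=rec["structure_id"],
            edges={(int(a), int(b)): float(w) for a, b, w in rec["edges"]},
            dropped_edges=rec.get("dropped_edges", 0),
            raw_total=rec.get("raw_total"),
            scale=rec.get("scale", 1.0),
        )
        for rec in payload["structures"]
    ]
    metadata = [StructureMetadata(**m) for m in payload["metadata"]]
    return Multinetwork(
        rins=rins,
        metadata={m.structure_id: m for m in metadata},
        reference_id=payload["reference_id"],
        column_to_reference={
            int(k): int(v)
            for k, v in payload["column_to_reference"].items()
        },
    )


def write_run_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return path
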