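"""Multiconformer structure parsing and metadata handling.

Crystallographic multiconformer models (e.g. qFit output) store alternate
conformations as PDB altloc groups with fractional occupancies.  This module
parses such models into a light-weight residue/conformer/atom hierarchy,
splits non-crystallographic-symmetry copies into independent single-chain
instances, and reads the per-structure metadata table that drives subset
selection downstream.

Parsing is delegated to :mod:`gemmi`; the data model here is format-agnostic.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger("altrin")

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})

#: Standard amino acids plus selenomethionine; everything else is dropped.
PROTEIN_RESIDUES = frozenset(
    """ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR
       TRP TYR VAL MSE""".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

WPD_STATES = frozenset({"open", "closed", "other", "unknown"})
LIGAND_CLASSES = frozenset({"apo", "active_site", "allosteric", "other"})


class StructureParseError(ValueError):
    """Raised when a structure file cannot be parsed into the model."""


class MetadataError(ValueError):
    """Raised for malformed metadata tables."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of one conformer.

    ``altloc`` is the PDB alternate-location indicator; the empty string
    marks an atom shared by all conformers of its residue.
    """

    name: str
    element: str
    altloc: str
    occupancy: float
    xyz: tuple[float, float, float]

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS


@dataclass
class ResidueModel:
    """A residue with one or more named conformers.

    ``conformers`` maps altloc label -> atom list.  A residue with only
    blank-altloc atoms has the single conformer ``''``.  Blank-altloc atoms
    are members of every conformer (a residue whose side chain alone is
    split still has a complete backbone per conformer).
    """

    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    conformers: dict[str, list[AtomRecord]]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def label(self) -> str:
        return f"{self.seq_num}{self.icode}".strip()

    @property
    def n_conformers(self) -> int:
        return len(self.conformers)

    @property
    def altloc_labels(self) -> list[str]:
        return sorted(self.conformers)

    def atoms(self) -> list[AtomRecord]:
        """All distinct atoms (shared atoms listed once)."""
        seen: dict[tuple[str, str], AtomRecord] = {}
        for atoms in self.conformers.values():
            for a in atoms:
                seen.setdefault((a.name, a.altloc), a)
        return list(seen.values())

    def unique_atom_names(self) -> set[str]:
        return {a.name for a in self.atoms()}

    def altloc_atoms(self) -> list[AtomRecord]:
        """Atoms that carry a non-blank altloc label."""
        return [a for a in self.atoms() if a.altloc]

    def backbone_altloc_labels(self) -> set[str]:
        """Altloc labels carried by backbone (N/CA/C/O) atoms."""
        return {a.altloc for a in self.atoms() if a.altloc and a.is_backbone}

    def has_backbone_altlocs(self) -> bool:
        return len(self.backbone_altloc_labels()) >= 2

    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms()], dtype=float)

    def occupancy_sum(self) -> float:
        """Sum of per-conformer occupancies (shared atoms excluded)."""
        total = 0.0
        for label, atoms in self.conformers.items():
            own = [a for a in atoms if a.altloc == label]
            if own:
                total += float(np.mean([a.occupancy for a in own]))
            elif label == "":
                own_blank = [a for a in atoms if a.altloc == ""]
                if own_blank:
                    total += float(np.mean([a.occupancy for a in own_blank]))
        return total


@dataclass
class MulticonformerStructure:
    """Protein chains -> ordered residues, with optional resolution."""

    structure_id: str
    chains: dict[str, list[ResidueModel]]
    resolution: float | None = None

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residues(self) -> list[ResidueModel]:
        out: list[ResidueModel] = []
        for cid in sorted(self.chains):
            out.extend(self.chains[cid])
        return out

    def one_letter_sequence(self, chain_id: str | None = None) -> str:
        if chain_id is None:
            chain_id = sorted(self.chains)[0]
        return "".join(
            THREE_TO_ONE.get(r.res_name, "X") for r in self.chains[chain_id]
        )


@dataclass
class StructureMetadata:
    """One row of the structure metadata table."""

    structure_id: str
    protein_name: str = "unknown"
    resolution: float = float("nan")
    wpd_state: str = "unknown"
    ligand_class: str = "other"
    tags: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PDB reading


def _gemmi_altloc(atom: gemmi.Atom) -> str:
    return atom.altloc if atom.altloc != "\x00" else ""


def read_multiconformer_model(
    path: str | Path,
    keep_chains: list[str] | None = None,
    keep_zero_occupancy: bool = True,
) -> MulticonformerStructure:
    """Parse a multiconformer PDB file.

    Hydrogens, waters and non-protein heteroatoms are removed; atoms are
    grouped by altloc within each residue, and blank-altloc atoms are
    attached to every conformer of their residue.

    Parameters
    ----------
    path
        PDB file with standard ATOM/HETATM records.
    keep_chains
        Restrict to these chain IDs (default: all protein chains).
    keep_zero_occupancy
        Retain conformers whose atoms have zero occupancy (edge weights are
        occupancy-agnostic, so these still contribute contacts).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()
    resolution = float(st.resolution) if st.resolution > 0 else None

    chains: dict[str, list[ResidueModel]] = {}
    model = st[0]
    for chain in model:
        if keep_chains is not None and chain.name not in keep_chains:
            continue
        residues: list[ResidueModel] = []
        for res in chain:
            if res.name not in PROTEIN_RESIDUES:
                continue
            blank: list[AtomRecord] = []
            by_altloc: dict[str, list[AtomRecord]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                occ = float(atom.occ)
                if not keep_zero_occupancy and occ <= 0.0:
                    continue
                rec = AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    altloc=_gemmi_altloc(atom),
                    occupancy=occ,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                )
                if not all(math.isfinite(v) for v in rec.xyz):
                    raise StructureParseError(
                        f"non-finite coordinates for {atom.name} in "
                        f"{chain.name}/{res.seqid.num} of {path}"
                    )
                if rec.altloc:
                    by_altloc.setdefault(rec.altloc, []).append(rec)
                else:
                    blank.append(rec)
            if not blank and not by_altloc:
                continue
            if by_altloc:
                conformers = {
                    label: blank + atoms for label, atoms in by_altloc.items()
                }
            else:
                conformers = {"": list(blank)}
            rm = ResidueModel(
                chain_id=chain.name,
                seq_num=res.seqid.num,
                icode=(res.seqid.icode or "").strip(),
                res_name=res.name,
                conformers=conformers,
            )
            occ_sum = rm.occupancy_sum()
            if rm.n_conformers > 1 and not (0.0 < occ_sum <= 1.02):
                logger.warning(
                    "%s %s/%s: conformer occupancies sum to %.2f",
                    path.name, chain.name, rm.label, occ_sum,
                )
            residues.append(rm)
        if residues:
            chains[chain.name] = residues

    if not chains:
        raise StructureParseError(f"{path}: no protein residues found")
    return MulticonformerStructure(
        structure_id=path.stem, chains=chains, resolution=resolution
    )


def write_multiconformer_pdb(
    structure: MulticonformerStructure, path: str | Path
) -> Path:
    """Serialize the model back to PDB (shared atoms written once, blank
    altloc; conformer atoms with their labels)."""
    path = Path(path)
    lines: list[str] = []
    serial = 0
    for cid in sorted(structure.chains):
        for res in structure.chains[cid]:
            for atom in sorted(res.atoms(), key=lambda a: (a.altloc, a.name)):
                serial += 1
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s}{atom.altloc or ' '}"
                    f"{res.res_name:<3s} {cid:1s}{res.seq_num:4d}"
                    f"{res.icode or ' '}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def split_single_chain_instances(
    structure: MulticonformerStructure,
) -> list[MulticonformerStructure]:
    """Split NCS copies: one structure per protein chain.

    Output IDs are ``{id}_{chain}``, in ascending chain-ID order.
    """
    out = []
    for cid in sorted(structure.chains):
        out.append(
            MulticonformerStructure(
                structure_id=f"{structure.structure_id}_{cid}",
                chains={cid: structure.chains[cid]},
                resolution=structure.resolution,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Metadata table


def _normalize_categorical(value: object, allowed: frozenset[str],
                           fallback: str, column: str) -> str:
    text = str(value).strip().lower().replace(" ", "_")
    if text in allowed:
        return text
    if text in {"", "nan", "none", "na"}:
        return fallback
    logger.warning("metadata: unknown %s value %r mapped to %r",
                   column, value, fallback)
    return fallback


def read_metadata_table(path: str | Path) -> list[StructureMetadata]:
    """Read the structure metadata table (CSV or TSV, header required).

    Unknown categorical values fold to ``unknown``/``other`` with a logged
    warning; duplicated structure IDs are an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "structure_id" not in df.columns:
        raise MetadataError(f"{path}: missing required column 'structure_id'")
    dupes = df["structure_id"][df["structure_id"].duplicated()].tolist()
    if dupes:
        raise MetadataError(f"{path}: duplicated structure_id values: {dupes}")

    known = {"structure_id", "protein_name", "resolution", "wpd_state",
             "ligand_class"}
    records = []
    for _, row in df.iterrows():
        res = float("nan")
        if "resolution" in df.columns and pd.notna(row.get("resolution")):
            res = float(row["resolution"])
            if res <= 0:
                raise MetadataError(
                    f"{path}: non-positive resolution for {row['structure_id']}"
                )
        records.append(
            StructureMetadata(
                structure_id=str(row["structure_id"]),
                protein_name=str(row.get("protein_name", "unknown")),
                resolution=res,
                wpd_state=_normalize_categorical(
                    row.get("wpd_state", "unknown"), WPD_STATES,
                    "unknown", "wpd_state"),
                ligand_class=_normalize_categorical(
                    row.get("ligand_class", "other"), LIGAND_CLASSES,
                    "other", "ligand_class"),
                tags={c: str(row[c]) for c in df.columns
                      if c not in known and pd.notna(row[c])},
            )
        )
    return records


def conformer_stats(
    structures: list[MulticonformerStructure],
) -> tuple[dict[str, float], float]:
    """Mean conformers per residue, per structure and residue-weighted global.

    Multiconformer refinement typically raises this mean by adding hidden
    alternate conformations; the statistic summarizes how much heterogeneity
    a model carries.
    """
    if not structures:
        raise ValueError("conformer_stats requires at least one structure")
    per_structure: dict[str, float] = {}
    total_conf = 0
    total_res = 0
    for st in structures:
        counts = [r.n_conformers for r in st.residues()]
        per_structure[st.structure_id] = float(np.mean(counts))
        total_conf += sum(counts)
        total_res += len(counts)
    return per_structure, total_conf / total_res
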