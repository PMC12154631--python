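"""Synthetic multiconformer fixtures with known ground-truth networks.

Every stage of the pipeline is testable without external downloads: this
module generates small multiconformer structures in which the coupled
alternate conformations — and therefore the exact residue interaction
network — are planted by construction.  Residues sit on a coarse extended
backbone template; alternate-conformation "side chain" atoms for a planted
contact pair are placed near a shared contact point within the cutoff,
while everything else is kept farther apart than the cutoff plus a safety
margin.  Planted backbone-altloc runs make consecutive residues' backbone
atoms carry A/B labels, exercising the sequential-coupling rule.

Geometric realism is explicitly not a goal; metric correctness (distances,
altloc bookkeeping, PDB formatting) is.  Atom placement is validated by
brute-force distance enumeration before a fixture is handed to any test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msa_map import Alignment
from .structure_io import (
    AtomRecord,
    MulticonformerStructure,
    ResidueModel,
    StructureMetadata,
    write_multiconformer_pdb,
)

#: spacing of consecutive residues along the chain axis, Å.  Chosen so that
#: backbone atoms of adjacent residues fall inside a 4 Å cutoff while
#: residues two apart stay beyond cutoff + 2 Å.
CHAIN_SPACING = 4.5

#: radial distance of planted contact points from the chain axis, Å.
CONTACT_RADIUS = 12.0

#: amino acids used for synthetic sequences (CB-bearing, unremarkable).
SYNTH_RESIDUES = ["ALA", "SER", "VAL", "LEU", "THR", "ASP", "LYS", "PHE"]

ONE_LETTER = {"ALA": "A", "SER": "S", "VAL": "V", "LEU": "L",
              "THR": "T", "ASP": "D", "LYS": "K", "PHE": "F"}

_STUB_NAMES = ["CG", "CD", "CE", "CZ", "CH", "CK", "CL", "CM"]


class GenerationError(ValueError):
    """Planted geometry cannot be realized (or failed validation)."""


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure family.

    ``planted_contacts`` are 1-based residue index pairs (non sequence
    adjacent) intended to interact through alternate conformations;
    ``backbone_runs`` are inclusive (start, end) index ranges whose
    backbone atoms are split into two altlocs.  ``subset_contact`` is an
    extra planted pair present only in subset-A structures, giving a known
    Δdegree signal.  ``noise_sigma`` is per-atom Gaussian coordinate noise
    in Å.  ``displacement`` is the altloc A→B offset (the ~1 Å scale of
    alternate conformations in multiconformer models).
    """

    seed: int
    n_structures: int = 10
    n_residues: int = 30
    planted_contacts: list[tuple[int, int]] = field(default_factory=list)
    backbone_runs: list[tuple[int, int]] = field(default_factory=list)
    subset_contact: tuple[int, int] | None = None
    displacement: float = 1.0
    noise_sigma: float = 0.0
    contact_cutoff: float = 4.0
    with_insertion: bool = False

    def __post_init__(self):
        for i, j in list(self.planted_contacts) + (
            [self.subset_contact] if self.subset_contact else []
        ):
            if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues):
                raise GenerationError(f"planted pair ({i},{j}) out of range")
            if abs(i - j) < 2:
                raise GenerationError(
                    f"planted spatial pair ({i},{j}) is sequence-adjacent"
                )
        for a, b in self.backbone_runs:
            if b - a < 1 or not (1 <= a <= b <= self.n_residues):
                raise GenerationError(f"invalid backbone run ({a},{b})")
        n_pairs = len(self.planted_contacts) + (1 if self.subset_contact else 0)
        if n_pairs > len(_STUB_NAMES):
            raise GenerationError(
                f"too many planted contacts ({n_pairs}) for the chain"
            )


@dataclass
class FamilyFixture:
    """A generated structure family with its ground truth."""

    structures: list[MulticonformerStructure]
    alignment: Alignment
    metadata: list[StructureMetadata]
    reference_id: str
    #: planted edges in core residue numbering, shared by all structures
    core_edges: set[tuple[int, int]]
    #: the subset-A-only planted edge, if any
    subset_edge: tuple[int, int] | None


def _backbone_template(index: int) -> dict[str, np.ndarray]:
    x = CHAIN_SPACING * (index - 1)
    return {
        "N": np.array([x - 1.2, 0.6, 0.0]),
        "CA": np.array([x, 0.0, 0.0]),
        "C": np.array([x + 1.2, 0.6, 0.0]),
        "O": np.array([x + 1.4, 1.7, 0.0]),
        "CB": np.array([x, -1.5, 0.5]),
    }


def _planted_pair_geometry(
    pair_rank: int, n_pairs: int, idx_i: int, idx_j: int
) -> tuple[np.ndarray, np.ndarray]:
    """Positions for the two stub atoms of a planted contact (2 Å apart),
    near a contact point on a ring around the chain axis."""
    theta = 2.0 * math.pi * pair_rank / max(n_pairs, 1)
    x_mid = CHAIN_SPACING * ((idx_i - 1) + (idx_j - 1)) / 2.0
    mid = np.array([
        x_mid,
        CONTACT_RADIUS * math.cos(theta),
        CONTACT_RADIUS * math.sin(theta),
    ])
    axis = np.array([1.0, 0.0, 0.0]) * (1.0 if idx_i < idx_j else -1.0)
    return mid - axis, mid + axis


def _sequence(rng: np.random.Generator, n: int) -> list[str]:
    return [SYNTH_RESIDUES[k] for k in rng.integers(0, len(SYNTH_RESIDUES), n)]


def generate_structure(
    spec: FixtureSpec,
    index: int = 0,
    include_subset_contact: bool = False,
    res_names: list[str] | None = None,
    insertion_at: int | None = None,
) -> tuple[MulticonformerStructure, set[tuple[str, str]]]:
    """Generate one structure realizing the spec's planted network.

    Returns the structure and its ground-truth edge set as pairs of residue
    labels (chain A).  ``insertion_at`` inserts one extra residue before
    the given core position, shifting subsequent numbering (used by
    :func:`generate_family` to exercise alignment gaps).  Deterministic for
    a fixed spec seed and index.
    """
    rng = np.random.default_rng((spec.seed, index))
    names = list(res_names) if res_names else _sequence(rng, spec.n_residues)

    if insertion_at is not None:
        for a, b in spec.backbone_runs:
            if a < insertion_at <= b:
                raise GenerationError(
                    f"insertion at {insertion_at} would break the backbone "
                    f"run ({a},{b})"
                )

    pairs = list(spec.planted_contacts)
    if include_subset_contact and spec.subset_contact:
        pairs.append(spec.subset_contact)
    n_pairs = len(pairs)

    # core position -> chain position after optional insertion
    def chain_pos(core: int) -> int:
        if insertion_at is not None and core >= insertion_at:
            return core + 1
        return core

    n_chain = spec.n_residues + (1 if insertion_at is not None else 0)
    chain_names = list(names)
    if insertion_at is not None:
        chain_names.insert(insertion_at - 1, "ALA")

    # collect per-chain-residue atoms: blank backbone + planted altloc atoms
    blank_atoms: dict[int, list[AtomRecord]] = {}
    alt_atoms: dict[int, dict[str, list[AtomRecord]]] = {}
    stub_counter: dict[int, int] = {}

    def jitter(p: np.ndarray) -> tuple[float, float, float]:
        if spec.noise_sigma > 0:
            p = p + rng.normal(0.0, spec.noise_sigma, 3)
        return (round(float(p[0]), 3), round(float(p[1]), 3),
                round(float(p[2]), 3))

    displacement = np.array([0.0, 0.0, spec.displacement])
    bb_displacement = np.array([0.0, 0.0, 0.6])

    run_members = set()
    for a, b in spec.backbone_runs:
        run_members.update(range(a, b + 1))

    for pos in range(1, n_chain + 1):
        template = _backbone_template(pos)
        blank_atoms[pos] = []
        alt_atoms[pos] = {}
        core = pos
        if insertion_at is not None:
            if pos == insertion_at:
                core = None  # the inserted residue maps to no core position
            elif pos > insertion_at:
                core = pos - 1
        in_run = core is not None and core in run_members
        for name, xyz in template.items():
            is_bb = name in {"N", "CA", "C", "O"}
            if in_run and is_bb:
                for label, offset in (("A", np.zeros(3)), ("B", bb_displacement)):
                    alt_atoms[pos].setdefault(label, []).append(
                        AtomRecord(name=name, element=name[0], altloc=label,
                                   occupancy=0.6 if label == "A" else 0.4,
                                   xyz=jitter(xyz + offset))
                    )
            else:
                blank_atoms[pos].append(
                    AtomRecord(name=name, element=name[0], altloc="",
                               occupancy=1.0, xyz=jitter(xyz))
                )

    for rank, (i, j) in enumerate(pairs):
        p_i, p_j = _planted_pair_geometry(rank, n_pairs, i, j)
        for core_idx, point in ((i, p_i), (j, p_j)):
            pos = chain_pos(core_idx)
            stub = _STUB_NAMES[stub_counter.get(pos, 0)]
            stub_counter[pos] = stub_counter.get(pos, 0) + 1
            for label, offset in (("A", np.zeros(3)), ("B", displacement * 0.5)):
                alt_atoms[pos].setdefault(label, []).append(
                    AtomRecord(name=stub, element="C", altloc=label,
                               occupancy=0.6 if label == "A" else 0.4,
                               xyz=jitter(point + offset))
                )

    residues = []
    for pos in range(1, n_chain + 1):
        if alt_atoms[pos]:
            conformers = {
                label: blank_atoms[pos] + atoms
                for label, atoms in sorted(alt_atoms[pos].items())
            }
        else:
            conformers = {"": blank_atoms[pos]}
        residues.append(
            ResidueModel(chain_id="A", seq_num=pos, icode="",
                         res_name=chain_names[pos - 1], conformers=conformers)
        )

    structure = MulticonformerStructure(
        structure_id=f"syn{index:03d}",
        chains={"A": residues},
        resolution=float(np.round(rng.uniform(1.2, 2.0), 2)),
    )

    truth: set[tuple[str, str]] = set()
    for i, j in pairs:
        a, b = sorted((str(chain_pos(i)), str(chain_pos(j))), key=int)
        truth.add((a, b))
    for a0, b0 in spec.backbone_runs:
        for k in range(a0, b0):
            truth.add((str(chain_pos(k)), str(chain_pos(k + 1))))

    _validate_geometry(structure, truth, spec)
    return structure, truth


def _validate_geometry(
    structure: MulticonformerStructure,
    truth: set[tuple[str, str]],
    spec: FixtureSpec,
) -> None:
    """Brute-force soundness check: altloc atoms of planted pairs lie within
    the cutoff; altloc atoms of all other residue pairs are beyond it."""
    residues = structure.residues()
    cutoff = spec.contact_cutoff
    for i in range(len(residues)):
        alt_i = residues[i].altloc_atoms()
        if not alt_i:
            continue
        for j in range(i + 1, len(residues)):
            alt_j = residues[j].altloc_atoms()
            if not alt_j:
                continue
            dmin = min(
                float(np.linalg.norm(np.array(a.xyz) - np.array(b.xyz)))
                for a in alt_i for b in alt_j
            )
            pair = tuple(sorted(
                (residues[i].label, residues[j].label), key=int))
            adjacent = abs(residues[i].seq_num - residues[j].seq_num) == 1
            if pair in truth:
                if dmin > cutoff:
                    raise GenerationError(
                        f"planted pair {pair} realized at {dmin:.2f} Å "
                        f"> cutoff {cutoff}"
                    )
            elif not adjacent and dmin <= cutoff:
                raise GenerationError(
                    f"spurious contact between {pair} at {dmin:.2f} Å"
                )


def generate_family(spec: FixtureSpec) -> FamilyFixture:
    """Generate a structure family: shared core sequence with per-structure
    substitutions, an optional insertion in the last structure, metadata
    splitting the family into subsets A and B, and the aligned FASTA rows.

    Subset-A structures carry the spec's ``subset_contact`` in addition to
    the shared planted contacts, so Δdegree(A, B) has a known positive sign
    at exactly those residues.
    """
    rng = np.random.default_rng(spec.seed)
    core = _sequence(rng, spec.n_residues)
    n = spec.n_structures
    ins_struct = n - 1 if spec.with_insertion and n > 1 else None
    ins_pos = spec.n_residues // 2 if ins_struct is not None else None

    structures, rows, metadata = [], {}, []
    ids = []
    for idx in range(n):
        names = list(core)
        # a couple of benign substitutions per structure (not the reference)
        if idx > 0:
            for p in rng.choice(spec.n_residues, size=2, replace=False):
                names[p] = SYNTH_RESIDUES[rng.integers(0, len(SYNTH_RESIDUES))]
        in_a = idx % 2 == 0
        insertion = ins_pos if idx == ins_struct else None
        st, _ = generate_structure(
            spec, idx,
            include_subset_contact=in_a and spec.subset_contact is not None,
            res_names=names,
            insertion_at=insertion,
        )
        structures.append(st)
        ids.append(st.structure_id)
        one = "".join(ONE_LETTER[r] for r in names)
        if ins_pos is not None:
            gap_col = ins_pos - 1
            if insertion is not None:
                row = one[:gap_col] + "A" + one[gap_col:]
            else:
                row = one[:gap_col] + "-" + one[gap_col:]
        else:
            row = one
        rows[st.structure_id] = row
        metadata.append(
            StructureMetadata(
                structure_id=st.structure_id,
                protein_name="synthetic",
                resolution=st.resolution,
                wpd_state="open" if in_a else "closed",
                ligand_class="apo",
                tags={"subset": "A" if in_a else "B"},
            )
        )

    alignment = Alignment(sequence_ids=ids, rows=rows)
    core_edges = {
        tuple(sorted(p)) for p in spec.planted_contacts
    } | {
        (k, k + 1)
        for a, b in spec.backbone_runs
        for k in range(a, b)
    }
    return FamilyFixture(
        structures=structures,
        alignment=alignment,
        metadata=metadata,
        reference_id=ids[0],
        core_edges={(min(p), max(p)) for p in core_edges},
        subset_edge=tuple(sorted(spec.subset_contact))
        if spec.subset_contact else None,
    )


def write_family(fixture: FamilyFixture, out_dir: str | Path) -> dict[str, Path]:
    """Write a family to disk: one PDB per structure, an aligned FASTA and a
    metadata CSV — the on-disk layout the CLI consumes."""
    out_dir = Path(out_dir)
    struct_dir = out_dir / "structures"
    struct_dir.mkdir(parents=True, exist_ok=True)
    for st in fixture.structures:
        write_multiconformer_pdb(st, struct_dir / f"{st.structure_id}.pdb")
    msa_path = out_dir / "family.fasta"
    with open(msa_path, "w") as fh:
        for sid in fixture.alignment.sequence_ids:
            fh.write(f">{sid}\n{fixture.alignment.rows[sid]}\n")
    meta_path = out_dir / "metadata.csv"
    with open(meta_path, "w") as fh:
        fh.write("structure_id,protein_name,resolution,wpd_state,"
                 "ligand_class,subset\n")
        for m in fixture.metadata:
            fh.write(f"{m.structure_id},{m.protein_name},{m.resolution},"
                     f"{m.wpd_state},{m.ligand_class},{m.tags['subset']}\n")
    return {"structures": struct_dir, "msa": msa_path, "metadata": meta_path}
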