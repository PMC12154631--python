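"""Shared fixtures: hand-built toy PDB files and synthetic families."""

from __future__ import annotations

import textwrap

import pytest

from altrin import (
    FixtureSpec,
    build_multinetwork,
    build_residue_map,
    generate_family,
    log_normalize,
    align_rin,
    build_network,
    reference_numbering,
)


def pdb_atom(serial, name, altloc, resname, chain, resnum, x, y, z,
             occ=1.0, element=None, icode=" "):
    element = element or name[0]
    name_f = name if len(name) >= 4 else f" {name:<3s}"
    return (f"ATOM  {serial:5d} {name_f:<4s}{altloc:1s}{resname:<3s} "
            f"{chain:1s}{resnum:4d}{icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2s}")


def write_pdb(path, lines):
    path.write_text("\n".join(lines + ["END"]) + "\n")
    return path


@pytest.fixture
def toy_pdb(tmp_path):
    """Three residues; residue 10 has CB in altlocs A/B; residue 11 has a
    hydrogen; residue 12 is a water (dropped)."""
    lines = [
        pdb_atom(1, "N", " ", "ALA", "A", 10, 0.0, 0.0, 0.0),
        pdb_atom(2, "CA", " ", "ALA", "A", 10, 1.5, 0.0, 0.0),
        pdb_atom(3, "C", " ", "ALA", "A", 10, 2.2, 1.2, 0.0),
        pdb_atom(4, "O", " ", "ALA", "A", 10, 3.4, 1.2, 0.0),
        pdb_atom(5, "CB", "A", "ALA", "A", 10, 1.5, -1.5, 0.0, occ=0.6),
        pdb_atom(6, "CB", "B", "ALA", "A", 10, 1.5, -1.2, 0.9, occ=0.4),
        pdb_atom(7, "N", " ", "GLY", "A", 11, 2.2, 2.4, 0.0),
        pdb_atom(8, "CA", " ", "GLY", "A", 11, 3.6, 2.8, 0.0),
        pdb_atom(9, "C", " ", "GLY", "A", 11, 4.2, 4.0, 0.0),
        pdb_atom(10, "O", " ", "GLY", "A", 11, 5.4, 4.2, 0.0),
        pdb_atom(11, "H", " ", "GLY", "A", 11, 1.5, 3.0, 0.0, element="H"),
        "HETATM   12  O  HOH A  12      8.000   8.000   8.000  1.00  0.00           O",
    ]
    return write_pdb(tmp_path / "toy.pdb", lines)


@pytest.fixture
def backbone_altloc_pdb(tmp_path):
    """Residue 5 with altlocs only on backbone O; side-chain CB blank."""
    lines = [
        pdb_atom(1, "N", " ", "SER", "A", 5, 0.0, 0.0, 0.0),
        pdb_atom(2, "CA", " ", "SER", "A", 5, 1.5, 0.0, 0.0),
        pdb_atom(3, "C", " ", "SER", "A", 5, 2.2, 1.2, 0.0),
        pdb_atom(4, "O", "A", "SER", "A", 5, 3.4, 1.2, 0.0, occ=0.5),
        pdb_atom(5, "O", "B", "SER", "A", 5, 3.3, 1.4, 0.8, occ=0.5),
        pdb_atom(6, "CB", " ", "SER", "A", 5, 1.5, -1.5, 0.0),
    ]
    return write_pdb(tmp_path / "bb.pdb", lines)


@pytest.fixture
def two_chain_pdb(tmp_path):
    """Chains C and A (out of order) with one residue each."""
    lines = []
    serial = 0
    for chain in ("C", "A"):
        offset = 50.0 if chain == "C" else 0.0
        for name, dx in (("N", 0.0), ("CA", 1.5), ("C", 2.2), ("O", 3.4)):
            serial += 1
            lines.append(pdb_atom(serial, name, " ", "GLY", chain, 1,
                                  dx + offset, 0.0, 0.0))
    return write_pdb(tmp_path / "twochain.pdb", lines)


@pytest.fixture(scope="session")
def family_spec():
    """Mixed family: shared spatial contacts, one backbone run, one
    subset-specific contact, an insertion, mild coordinate noise."""
    return FixtureSpec(
        seed=20260922,
        n_structures=10,
        n_residues=30,
        planted_contacts=[(3, 17), (5, 22)],
        backbone_runs=[(8, 10)],
        subset_contact=(6, 25),
        noise_sigma=0.1,
        with_insertion=True,
    )


@pytest.fixture(scope="session")
def family(family_spec):
    return generate_family(family_spec)


@pytest.fixture(scope="session")
def family_multinetwork(family):
    rins = []
    for st in family.structures:
        amap = build_residue_map(
            family.alignment, st.structure_id, st, family.reference_id)
        rins.append(log_normalize(align_rin(build_network(st), amap)))
    return build_multinetwork(
        rins, family.metadata, reference_id=family.reference_id,
        column_to_reference=reference_numbering(
            family.alignment, family.reference_id),
    )


def in_subset(label):
    return lambda m: m.tags.get("subset") == label
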