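"""Structure-based MSA handling: residue-number to alignment-column maps
and per-column sequence conservation.

Per-structure networks are indexed by author residue numbers, which are not
comparable between homologs.  A structure-based multiple sequence alignment
(e.g. PROMALS3D output) provides the common coordinate system: every residue
is assigned an alignment column, and columns are labelled with the residue
numbering of a designated reference row (e.g. PTP1B numbering) where the
reference has a residue in that column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

from .structure_io import MulticonformerStructure

logger = logging.getLogger("altrin")


class AlignmentFormatError(ValueError):
    """Malformed alignment file (ragged rows, unknown dialect...)."""


class MappingError(ValueError):
    """Sequence/structure reconciliation failed."""


@dataclass
class Alignment:
    sequence_ids: list[str]
    rows: dict[str, str]

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequence_ids)


@dataclass
class AlignmentMap:
    """Residue-number <-> alignment-column correspondence for one structure.

    ``residue_to_column`` keys are residue labels (author number + insertion
    code, as strings); columns are 0-based.  ``column_to_reference`` carries
    a reference residue number only for columns where the reference row is
    ungapped — residues aligned to reference gaps have a column but no
    analogous reference residue.
    """

    structure_id: str
    residue_to_column: dict[str, int]
    column_to_reference: dict[int, int]
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)

    def column_of(self, residue_label: str) -> int | None:
        return self.residue_to_column.get(residue_label)


@dataclass
class ConservationProfile:
    """Per-column conservation: modal non-gap residue fraction in [0, 1]."""

    values: list[float]

    def __getitem__(self, column: int) -> float:
        return self.values[column]

    def __len__(self) -> int:
        return len(self.values)


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned FASTA or CLUSTAL file.

    Format is inferred from the suffix unless ``fmt`` is given.
    """
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise AlignmentFormatError(f"cannot read {path} as {fmt}: {exc}") from exc
    rows = {rec.id: str(rec.seq).upper() for rec in msa}
    if len(rows) != len(msa):
        raise AlignmentFormatError(f"{path}: duplicate sequence IDs")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise AlignmentFormatError(f"{path}: rows of differing lengths {lengths}")
    return Alignment(sequence_ids=[rec.id for rec in msa], rows=rows)


def _ungapped_positions(row: str) -> list[int]:
    return [i for i, c in enumerate(row) if c != "-"]


def build_residue_map(
    alignment: Alignment,
    seq_id: str,
    structure: MulticonformerStructure,
    reference_id: str,
    mismatch_tolerance: float = 0.02,
) -> AlignmentMap:
    """Map a structure's residues to alignment columns and reference numbering.

    The ungapped MSA row for ``seq_id`` must equal the structure's one-letter
    sequence up to ``mismatch_tolerance`` (fraction of positions; engineered
    point mutants in crystal structures are tolerated and logged).

    Reference numbering is the 1-based ungapped position in the
    ``reference_id`` row.
    """
    for sid in (seq_id, reference_id):
        if sid not in alignment.rows:
            raise MappingError(f"sequence {sid!r} not in alignment")
    row = alignment.rows[seq_id]
    cols = _ungapped_positions(row)
    chain_id = sorted(structure.chains)[0]
    residues = structure.chains[chain_id]
    seq = structure.one_letter_sequence(chain_id)
    if len(cols) != len(seq):
        raise MappingError(
            f"{structure.structure_id}: alignment row for {seq_id!r} has "
            f"{len(cols)} residues but structure has {len(seq)}"
        )
    mismatches = [
        (col, row[col], seq[i])
        for i, col in enumerate(cols)
        if row[col] != seq[i]
    ]
    if seq and len(mismatches) / len(seq) > mismatch_tolerance:
        col, aln_c, str_c = mismatches[0]
        raise MappingError(
            f"{structure.structure_id}: {len(mismatches)}/{len(seq)} sequence "
            f"mismatches vs alignment (first at column {col}: "
            f"alignment {aln_c!r} vs structure {str_c!r})"
        )
    for col, aln_c, str_c in mismatches:
        logger.warning("%s: sequence mismatch at column %d (%s vs %s)",
                       structure.structure_id, col, aln_c, str_c)

    residue_to_column = {
        res.label: col for res, col in zip(residues, cols)
    }
    column_to_reference = reference_numbering(alignment, reference_id)
    return AlignmentMap(
        structure_id=structure.structure_id,
        residue_to_column=residue_to_column,
        column_to_reference=column_to_reference,
        mismatches=mismatches,
    )


def reference_numbering(alignment: Alignment, reference_id: str) -> dict[int, int]:
    """Column -> reference residue number (1-based ungapped position of the
    reference row)."""
    if reference_id not in alignment.rows:
        raise MappingError(f"reference {reference_id!r} not in alignment")
    return {
        col: i + 1
        for i, col in enumerate(_ungapped_positions(alignment.rows[reference_id]))
    }


def conservation_profile(
    alignment: Alignment, count_gaps_in_denominator: bool = True
) -> ConservationProfile:
    """Modal-residue fraction per column.

    conservation(column) = count of the most frequent non-gap residue divided
    by the number of sequences (default) or by the number of non-gap entries
    (``count_gaps_in_denominator=False``).  An all-gap column scores 0.
    """
    if alignment.n_sequences < 2:
        raise ValueError("conservation requires at least 2 sequences")
    values = []
    rows = list(alignment.rows.values())
    for col in range(alignment.n_columns):
        chars = [r[col] for r in rows]
        non_gap = [c for c in chars if c != "-"]
        if not non_gap:
            values.append(0.0)
            continue
        modal = max(non_gap.count(c) for c in set(non_gap))
        denom = len(chars) if count_gaps_in_denominator else len(non_gap)
        values.append(modal / denom)
    return ConservationProfile(values=values)
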