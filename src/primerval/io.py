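"""Reading and writing aligned FASTA, species maps and primer tables.

Header convention for aligned FASTA: ``>id|species`` with an optional
third ``|taxon`` field.  A TSV species map (columns ``sequence_id``,
``species_label``, ``taxon_group``) overrides header-derived labels.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO

from .exceptions import AlignmentError, LabelingError
from .model import AlignedRecord, AlignedSequenceSet, DegeneratePrimer

_SPECIES_MAP_COLUMNS = ("sequence_id", "species_label", "taxon_group")


def read_species_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV mapping sequence_id -> (species_label, taxon_group)."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = [c for c in _SPECIES_MAP_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise LabelingError(f"species map {path} lacks columns: {', '.join(missing)}")
        for row in reader:
            mapping[row["sequence_id"]] = (row["species_label"], row["taxon_group"] or "")
    return mapping


def read_aligned_fasta(
    path: str | Path,
    species_map: str | Path | None = None,
    *,
    default_taxon: str = "",
) -> AlignedSequenceSet:
    """Read an aligned FASTA file into an :class:`AlignedSequenceSet`.

    Record order is preserved.  Ragged lengths raise
    :class:`AlignmentError` naming the offending record; headers that
    cannot be mapped to a species raise :class:`LabelingError`.
    """
    mapping = read_species_map(species_map) if species_map is not None else None
    records: list[AlignedRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description or rec.id
        fields = header.split("|")
        seq_id = fields[0].strip()
        if mapping is not None:
            if seq_id not in mapping:
                raise LabelingError(f"record {i} ({seq_id!r}) absent from species map")
            species, taxon = mapping[seq_id]
        else:
            if len(fields) < 2 or not fields[1].strip():
                raise LabelingError(
                    f"record {i} ({seq_id!r}): header has no '|species' field and "
                    "no species map was supplied"
                )
            species = fields[1].strip()
            taxon = fields[2].strip() if len(fields) > 2 else default_taxon
        records.append(AlignedRecord(seq_id, species, taxon or default_taxon, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no records in {path}")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        ref = len(records[0].sequence)
        for i, r in enumerate(records, start=1):
            if len(r.sequence) != ref:
                raise AlignmentError(
                    f"record {i} ({r.sequence_id!r}) has length {len(r.sequence)}, "
                    f"expected {ref}: not an alignment"
                )
    return AlignedSequenceSet(records)


def write_aligned_fasta(aln: AlignedSequenceSet, path: str | Path) -> None:
    """Write an alignment with ``>id|species|taxon`` headers."""
    with open(path, "w") as fh:
        for rec in aln:
            fh.write(f">{rec.sequence_id}|{rec.species}|{rec.taxon}\n{rec.sequence}\n")


def write_species_map(aln: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_SPECIES_MAP_COLUMNS)
        for rec in aln:
            writer.writerow([rec.sequence_id, rec.species, rec.taxon])


def read_primers_tsv(path: str | Path) -> list[DegeneratePrimer]:
    """Read primers from a TSV with columns name, sequence, orientation."""
    primers: list[DegeneratePrimer] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "sequence", "orientation"}
        if not required <= set(reader.fieldnames or []):
            raise ValueError(f"primer table {path} needs columns {sorted(required)}")
        for row in reader:
            primers.append(
                DegeneratePrimer(row["name"], row["sequence"], row["orientation"].lower())
            )
    return primers
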