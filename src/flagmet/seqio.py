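"""Sequence and feature-table primitives shared by every pipeline stage.

Conventions used throughout the package:

* genomic coordinates are 1-based and inclusive (GFF style);
* all spacings downstream (promoter spacers, RBS gaps) count nucleotides
  *strictly between* two elements;
* FASTA headers use the first whitespace-delimited token as the record id;
* writers emit UTF-8 with Unix newlines, sequences wrapped at 60 columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: Average (isotope-abundance weighted) residue masses in Da for the 20
#: standard amino acids, i.e. the mass each residue contributes inside a
#: peptide chain.  One water mass is added per chain.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2099, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153


class FormatError(ValueError):
    """Malformed input file (FASTA or feature table)."""


class CoordinateError(ValueError):
    """Feature coordinates violate the 1-based inclusive contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class GenomeRecord:
    """A nucleotide sequence (genome, contig or locus) with a species label."""

    id: str
    sequence: str
    species: str | None = None

    @property
    def size_bp(self) -> int:
        return len(self.sequence)

    def validate_acgt(self) -> None:
        """Reject IUPAC ambiguity codes; simulation stages require plain ACGT."""
        bad = set(self.sequence) - set(NUCLEOTIDES)
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-ACGT characters {sorted(bad)} are not "
                "accepted by the simulation stages"
            )


@dataclass
class GeneFeature:
    """A CDS/ORF with coordinates, strand, product class and locus membership.

    ``locus_label`` groups genes into the motility loci observed in these
    genomes (``flgB-fliA``, ``mbl-flgJ``, ``flgM-flgN/fliC``) or ``none`` for
    dispersed genes such as most flagellin CDSs.
    """

    id: str
    genome_id: str
    start: int
    end: int
    strand: str
    product: str
    locus_label: str = "none"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"feature {self.id!r}: start {self.start} < 1")
        if self.start > self.end:
            raise CoordinateError(
                f"feature {self.id!r}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"feature {self.id!r}: unknown strand symbol {self.strand!r}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """An amino-acid sequence with its deterministic average-mass estimate."""

    id: str
    sequence: str
    mass_kda: float = field(init=False)

    def __post_init__(self) -> None:
        self.mass_kda = protein_mass_kda(self.sequence, record_id=self.id)

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


def protein_mass_kda(sequence: str, record_id: str = "<anonymous>") -> float:
    """Average molecular mass of a protein in kDa.

    Sum of average residue masses plus one water, divided by 1000.  Reports
    and tables round the result to two decimals; the full-precision value is
    returned so that mass is exactly additive (mass(AB) = mass(A) + mass(B)
    - water/1000).
    """
    if not sequence:
        raise FormatError(f"record {record_id!r}: empty protein sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise FormatError(
                f"record {record_id!r}: non-standard amino acid {aa!r} at "
                f"position {pos}"
            ) from None
    return total / 1000.0


def _check_unique_ids(ids: Sequence[str], path) -> None:
    seen: dict[str, int] = {}
    dups = []
    for i in ids:
        seen[i] = seen.get(i, 0) + 1
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise FormatError(f"{path}: duplicate record ids {dups}")


def read_fasta(path, molecule: str = "dna") -> list[GenomeRecord] | list[ProteinRecord]:
    """Read a FASTA file into :class:`GenomeRecord` or :class:`ProteinRecord` objects.

    Sequences are uppercased and file order is preserved.  ``molecule`` is
    ``"dna"`` (default) or ``"protein"``.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise FormatError(f"{path}: not FASTA (first record lacks a '>' header)")
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    _check_unique_ids(ids, path)
    out = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        if molecule == "protein":
            out.append(ProteinRecord(id=rec.id, sequence=seq))
        else:
            out.append(GenomeRecord(id=rec.id, sequence=seq, species=rec.id))
    return out


def write_fasta(records: Iterable[GenomeRecord | ProteinRecord], path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


FEATURE_COLUMNS = ["id", "genome_id", "start", "end", "strand", "product", "locus_label"]


def read_feature_table(path, genome_sizes: dict[str, int] | None = None) -> list[GeneFeature]:
    """Read a tab-separated gene-feature table (header row required).

    Features are validated and returned sorted by ``(genome_id, start)``.
    When ``genome_sizes`` is given, features extending beyond their genome
    raise a :class:`CoordinateError`.
    """
    path = Path(path)
    if path.stat().st_size == 0 or not path.read_text().strip():
        log.warning("feature table %s is empty", path)
        return []
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    _check_unique_ids(list(df["id"]), path)
    features = []
    for row in df.itertuples(index=False):
        feat = GeneFeature(
            id=row.id,
            genome_id=row.genome_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            product=row.product,
            locus_label=row.locus_label,
        )
        if genome_sizes is not None:
            size = genome_sizes.get(feat.genome_id)
            if size is not None and feat.end > size:
                raise CoordinateError(
                    f"feature {feat.id!r}: end {feat.end} beyond genome "
                    f"{feat.genome_id!r} size {size}"
                )
        features.append(feat)
    features.sort(key=lambda f: (f.genome_id, f.start))
    return features


def write_feature_table(features: Iterable[GeneFeature], path) -> None:
    rows = [
        {
            "id": f.id, "genome_id": f.genome_id, "start": f.start, "end": f.end,
            "strand": f.strand, "product": f.product, "locus_label": f.locus_label,
        }
        for f in features
    ]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
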