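"""Gene-model I/O: genome FASTA, GFF3 gene structures, spliced CDS, translation.

External coordinates follow the GFF3 convention (1-based, inclusive).  Every
internal protein or CDS offset in this package is 0-based half-open.  The GFF3
``phase`` column is ignored on input: intron phase is recomputed downstream
from CDS segment lengths, which makes it testable and strand-independent.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, FormatError, InputError, ValidationError

__all__ = [
    "GeneModel",
    "ProteinRecord",
    "read_genome",
    "read_gff3",
    "spliced_cds",
    "translate",
    "write_gff3",
    "write_protein_fasta",
    "validation_report",
]


@dataclass(frozen=True)
class GeneModel:
    """One annotated protein-coding gene (its longest transcript).

    ``cds_segments`` holds 1-based inclusive genomic intervals sorted in
    translation order: ascending genomic start on "+", descending on "-".
    """

    gene_id: str
    scaffold_id: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        segs = tuple(tuple(s) for s in self.cds_segments)
        object.__setattr__(self, "cds_segments", segs)
        if not segs:
            raise ValidationError(f"{self.gene_id}: no CDS segments")
        for start, end in segs:
            if start < 1 or start > end:
                raise ValidationError(
                    f"{self.gene_id}: bad CDS interval ({start}, {end})"
                )
        by_start = sorted(segs)
        for (s1, e1), (s2, e2) in zip(by_start, by_start[1:]):
            if s2 <= e1:
                raise ValidationError(
                    f"{self.gene_id}: overlapping CDS segments "
                    f"({s1},{e1}) and ({s2},{e2})"
                )
        expected = by_start if self.strand == "+" else by_start[::-1]
        if segs != tuple(expected):
            raise ValidationError(
                f"{self.gene_id}: CDS segments not in translation order for "
                f"strand {self.strand}"
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def segment_lengths(self) -> tuple[int, ...]:
        return tuple(end - start + 1 for start, end in self.cds_segments)


@dataclass(frozen=True)
class ProteinRecord:
    """A conceptual translation; ``*`` marks stop codons.

    ``has_internal_stop`` is true iff a stop occurs before the final residue
    (the pseudogene criterion).  ``complete_cds`` requires an ATG start and a
    length divisible by three.
    """

    gene_id: str
    sequence: str
    has_internal_stop: bool = field(init=False)
    complete_cds: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "has_internal_stop", "*" in self.sequence[:-1]
        )

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome(path: str | Path) -> dict[str, str]:
    """Read a (possibly multi-record, line-wrapped) genome FASTA.

    Sequences are uppercased; IUPAC ambiguity letters are preserved.
    Raises :class:`FormatError` on an empty file, a malformed first header
    (naming the offending line), or duplicate record identifiers.
    """
    path = Path(path)
    with open(path) as handle:
        text = handle.read()
    stripped_lines = [
        (i + 1, ln) for i, ln in enumerate(text.splitlines()) if ln.strip()
    ]
    if not stripped_lines:
        raise FormatError(f"{path}: empty FASTA file")
    first_no, first_line = stripped_lines[0]
    if not first_line.startswith(">"):
        raise FormatError(
            f"{path}: line {first_no}: expected FASTA header, got "
            f"{first_line[:40]!r}"
        )
    genome: dict[str, str] = {}
    for record in SeqIO.parse(io.StringIO(text), "fasta"):
        if not record.id:
            raise FormatError(f"{path}: FASTA record with empty identifier")
        if record.id in genome:
            raise FormatError(f"{path}: duplicate FASTA identifier {record.id!r}")
        genome[record.id] = str(record.seq).upper()
    return genome


def _longest_cds_mrna(db: gffutils.FeatureDB, gene) -> object | None:
    best = None
    best_len = -1
    for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
        length = sum(
            c.end - c.start + 1
            for c in db.children(mrna, featuretype="CDS", order_by="start")
        )
        if length > best_len:
            best, best_len = mrna, length
    return best


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into :class:`GeneModel` objects.

    One model per gene: alternative transcripts are collapsed to the mRNA
    with the longest total CDS (the survey counts genes, not transcripts).
    CDS rows lacking a Parent attribute raise :class:`FormatError`.
    """
    path = Path(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    for cds in db.features_of_type("CDS"):
        if not cds.attributes.get("Parent"):
            raise FormatError(
                f"{path}: CDS at {cds.seqid}:{cds.start}-{cds.end} has no Parent"
            )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrna = _longest_cds_mrna(db, gene)
        if mrna is None:
            continue
        cds_rows = list(db.children(mrna, featuretype="CDS", order_by="start"))
        if not cds_rows:
            continue
        intervals = [(c.start, c.end) for c in cds_rows]
        if gene.strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                scaffold_id=gene.seqid,
                strand=gene.strand,
                cds_segments=tuple(intervals),
            )
        )
    return models


_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def spliced_cds(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Concatenate the CDS segment sequences in translation order.

    Minus-strand segments are reverse-complemented.  Raises
    :class:`CoordinateError` when a segment exceeds its scaffold.
    """
    try:
        scaffold = genome[gene.scaffold_id]
    except KeyError:
        raise CoordinateError(
            f"{gene.gene_id}: scaffold {gene.scaffold_id!r} absent from genome"
        ) from None
    parts: list[str] = []
    for start, end in gene.cds_segments:
        if end > len(scaffold):
            raise CoordinateError(
                f"{gene.gene_id}: segment ({start}, {end}) beyond scaffold end "
                f"({len(scaffold)} nt)"
            )
        piece = scaffold[start - 1 : end]
        if gene.strand == "-":
            piece = piece.translate(_COMPLEMENT)[::-1]
        parts.append(piece)
    return "".join(parts)


def translate(cds: str, gene_id: str = "") -> ProteinRecord:
    """Translate a spliced CDS with the standard genetic code.

    A trailing incomplete codon is dropped (and ``complete_cds`` is False).
    Codons containing ambiguity letters translate to ``X`` and never count
    as stops.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise InputError(f"{gene_id or 'CDS'}: shorter than one codon")
    usable = len(cds) - len(cds) % 3
    protein = str(Seq(cds[:usable]).translate())
    complete = len(cds) % 3 == 0 and cds[:3] == "ATG"
    return ProteinRecord(gene_id=gene_id, sequence=protein, complete_cds=complete)


def write_gff3(
    genes: Iterable[GeneModel],
    path: str | Path,
    scaffold_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write gene/mRNA/CDS rows (CDS phase column recomputed from lengths)."""
    genes = list(genes)
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        if scaffold_lengths:
            for sid, length in scaffold_lengths.items():
                out.write(f"##sequence-region {sid} 1 {length}\n")
        for gene in genes:
            span = [c for seg in gene.cds_segments for c in seg]
            lo, hi = min(span), max(span)
            base = f"{gene.scaffold_id}\tnbsarch\t"
            out.write(
                f"{base}gene\t{lo}\t{hi}\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            mrna = f"{gene.gene_id}.t1"
            out.write(
                f"{base}mRNA\t{lo}\t{hi}\t.\t{gene.strand}\t.\t"
                f"ID={mrna};Parent={gene.gene_id}\n"
            )
            consumed = 0
            for i, (start, end) in enumerate(gene.cds_segments):
                phase = (3 - consumed % 3) % 3
                out.write(
                    f"{base}CDS\t{start}\t{end}\t.\t{gene.strand}\t{phase}\t"
                    f"ID={mrna}.cds{i};Parent={mrna}\n"
                )
                consumed += end - start + 1


def write_protein_fasta(
    proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as out:
        for rec in proteins:
            out.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.sequence), width):
                out.write(rec.sequence[i : i + width] + "\n")


def validation_report(
    genes: Iterable[GeneModel], genome: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene structural summary (TSV-ready)."""
    rows = []
    for gene in genes:
        cds = spliced_cds(gene, genome)
        prot = translate(cds, gene.gene_id)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_segments": len(gene.cds_segments),
                "cds_len": len(cds),
                "complete_cds": prot.complete_cds,
                "has_internal_stop": prot.has_internal_stop,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "n_segments",
            "cds_len",
            "complete_cds",
            "has_internal_stop",
        ],
    )
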