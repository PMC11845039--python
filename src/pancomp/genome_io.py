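"""Sequence I/O and coordinate primitives for the phage comparison pipeline.

All genomic coordinates in this package are 1-based and inclusive at both
ends (the GFF3 convention). Conversions to Python slices happen only inside
this module. Genome sequences are uppercased on ingest and may contain 'N';
codons containing 'N' translate to 'X'.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "FeatureCall",
    "ProteinSeq",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "translate_orf",
    "write_features_gff3",
    "read_features_gff3",
    "read_feature_table",
    "write_feature_table",
    "load_isolate_table",
]

VALID_BASES = set("ACGTN")

FEATURE_TABLE_COLUMNS = ["genome_id", "start", "end", "strand", "caller_id", "call_type"]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """A single nucleotide genome (phage or host)."""

    genome_id: str
    sequence: str
    source: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise FormatError(f"genome {self.genome_id!r}: empty sequence")
        bad = set(seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"genome {self.genome_id!r}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FeatureCall:
    """One interval call (CDS, tRNA, intron) from one predictor."""

    genome_id: str
    start: int
    end: int
    strand: str
    caller_id: str
    call_type: str = "CDS"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature on {self.genome_id}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature on {self.genome_id}: bad strand {self.strand!r}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinSeq:
    """An amino-acid sequence tied to a gene and its genome of origin."""

    gene_id: str
    genome_id: str
    aa_sequence: str
    has_internal_stop: bool = False

    def __post_init__(self) -> None:
        if not self.aa_sequence:
            raise ValueError(f"protein {self.gene_id}: empty sequence")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a multi-record nucleotide FASTA into GenomeRecords.

    Sequences are uppercased; record order is preserved; duplicate or empty
    ids and empty sequences raise :class:`FormatError` naming the record.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        seen.add(rec.id)
        records.append(
            GenomeRecord(rec.id, str(rec.seq), source=rec.description[len(rec.id):].strip())
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord | ProteinSeq], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, ProteinSeq):
                header, seq = rec.gene_id, rec.aa_sequence
            else:
                header = rec.genome_id + (f" {rec.source}" if rec.source else "")
                seq = rec.sequence
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Sequence primitives
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _start_codons(table_id: int) -> set[str]:
    return set(CodonTable.unambiguous_dna_by_id[table_id].start_codons)


def translate_orf(
    genome: GenomeRecord,
    start: int,
    end: int,
    strand: str,
    code: int = 11,
    alt_start_as_met: bool = True,
    gene_id: str | None = None,
) -> ProteinSeq:
    """Translate the ORF at ``start..end`` (1-based, inclusive) on ``strand``.

    Uses the bacterial/phage translation table (11) by default. Internal stop
    codons are preserved as '*' and flagged. Codons containing 'N' become 'X'.
    When ``alt_start_as_met`` is set, an alternative initiator codon of the
    table (GTG/TTG under table 11) renders as 'M' at the gene start.
    """
    if not (1 <= start <= end <= genome.length_bp):
        raise ValueError(
            f"{genome.genome_id}: ORF {start}..{end} outside genome of "
            f"{genome.length_bp} bp"
        )
    n = end - start + 1
    if n % 3 != 0:
        raise ValueError(
            f"{genome.genome_id}: ORF {start}..{end} length {n} not divisible by 3"
        )
    sub = genome.sequence[start - 1 : end]
    if strand == "-":
        sub = reverse_complement(sub)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    aa = str(Seq(sub).translate(table=code))
    if alt_start_as_met and sub[:3] in _start_codons(code):
        aa = "M" + aa[1:]
    internal = "*" in aa[:-1]
    gid = gene_id or f"{genome.genome_id}:{start}-{end}({strand})"
    return ProteinSeq(gid, genome.genome_id, aa, has_internal_stop=internal)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_features_gff3(
    features: Sequence,
    path: str | Path,
    genome_lengths: dict[str, int] | None = None,
) -> None:
    """Write FeatureCall-like or ConsensusGene-like features as GFF3.

    Any object exposing genome_id/start/end/strand (plus optional caller_id,
    call_type, score, and ``gff_attributes()``) is accepted. Coordinates are
    validated against ``genome_lengths`` when provided.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            if genome_lengths is not None:
                glen = genome_lengths.get(feat.genome_id)
                if glen is not None and not (1 <= feat.start <= feat.end <= glen):
                    raise ValueError(
                        f"feature {feat.start}..{feat.end} outside genome "
                        f"{feat.genome_id} ({glen} bp)"
                    )
            source = getattr(feat, "caller_id", "pancomp")
            ftype = getattr(feat, "call_type", "CDS")
            score = getattr(feat, "score", None)
            score_s = "." if score is None else str(score)
            if hasattr(feat, "gff_attributes"):
                attrs = feat.gff_attributes()
            else:
                attrs = f"caller_id={source};call_type={ftype}"
            fh.write(
                "\t".join(
                    [
                        feat.genome_id,
                        source,
                        ftype,
                        str(feat.start),
                        str(feat.end),
                        score_s,
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_features_gff3(path: str | Path) -> list[FeatureCall]:
    """Read a GFF3 file written by :func:`write_features_gff3` back to calls."""
    calls: list[FeatureCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            seqid, source, ftype, start, end, _score, strand, _phase, _attrs = parts
            calls.append(
                FeatureCall(seqid, int(start), int(end), strand, source, ftype)
            )
    return calls


# ---------------------------------------------------------------------------
# TSV feature tables (the multi-predictor call dialect)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path) -> list[FeatureCall]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "caller_id": str})
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        FeatureCall(
            r.genome_id, int(r.start), int(r.end), r.strand, r.caller_id, r.call_type
        )
        for r in df.itertuples()
    ]


def write_feature_table(calls: Iterable[FeatureCall], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (c.genome_id, c.start, c.end, c.strand, c.caller_id, c.call_type)
            for c in calls
        ],
        columns=FEATURE_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_isolate_table() -> pd.DataFrame:
    """Published summary table for the 24 Klebsiella sp. M5al phage isolates.

    Columns: phage_name, genome_size_bp, n_genes, n_introns, n_trnas, family,
    genus, accession. Ships with the package as reference input data.
    """
    ref = importlib.resources.files("pancomp") / "data" / "klebsiella_phage_isolates.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")
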