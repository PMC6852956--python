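"""Genome containers and on-disk formats.

All internal coordinates are 0-based half-open on the forward strand.
Conversions to the 1-based conventions of GFF3 and BLAST tabular output
happen only inside the readers/writers in this module.  Circular sequences
are stored linearly with a ``circular`` flag; features that wrap the origin
carry ``end > len(sequence)`` together with a ``wrap=true`` attribute.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

COMPARTMENTS = ("nuclear", "mitochondrial", "chloroplast")
_VALID_SEQ = re.compile(r"^[ACGTN]*$")

_COMP_TABLE = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP_TABLE)[::-1]


@dataclass
class GenomeRecord:
    """A named, possibly circular sequence belonging to one species and
    one cellular compartment."""

    id: str
    species: str
    compartment: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not _VALID_SEQ.match(self.sequence):
            pos = next(i for i, c in enumerate(self.sequence) if c not in "ACGTN")
            raise ValueError(
                f"record {self.id!r}: invalid character {self.sequence[pos]!r} "
                f"at position {pos}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Extract ``[start, end)``; on circular records the interval may
        wrap (``end`` may exceed the length, ``start`` may be negative)."""
        n = len(self.sequence)
        if not self.circular:
            if start < 0 or end > n:
                raise ValueError(f"interval [{start},{end}) out of bounds for {self.id!r}")
            return self.sequence[start:end]
        length = end - start
        if length > n:
            raise ValueError("interval longer than circular sequence")
        start %= n
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]


@dataclass
class FeatureRecord:
    """One annotated interval (gene, repeat, planted insertion, ...)."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"
    feature_type: str = "gene"
    name: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSet:
    """All genomes and annotations of one study, indexed by record id."""

    records: list[GenomeRecord] = field(default_factory=list)
    features: list[FeatureRecord] = field(default_factory=list)
    species_list: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in GenomeSet")
        self._by_id = {r.id: r for r in self.records}
        for f in self.features:
            if f.seq_id not in self._by_id:
                raise ValueError(f"feature {f.name!r} references unknown sequence {f.seq_id!r}")
            rec = self._by_id[f.seq_id]
            wraps = f.attributes.get("wrap") == "true"
            if f.end > len(rec) and not (rec.circular and wraps):
                raise ValueError(f"feature {f.name!r} extends past end of {f.seq_id!r}")
        if not self.species_list:
            seen: list[str] = []
            for r in self.records:
                if r.species not in seen:
                    seen.append(r.species)
            self.species_list = seen

    def record(self, rec_id: str) -> GenomeRecord:
        return self._by_id[rec_id]

    def records_for(self, species: str, compartment: str | None = None) -> list[GenomeRecord]:
        return [
            r for r in self.records
            if r.species == species and (compartment is None or r.compartment == compartment)
        ]

    def features_for(self, seq_id: str, feature_type: str | None = None) -> list[FeatureRecord]:
        return [
            f for f in self.features
            if f.seq_id == seq_id and (feature_type is None or f.feature_type == feature_type)
        ]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path, species: str, compartment: str,
               circular: bool = False) -> list[GenomeRecord]:
    """Read a FASTA file into :class:`GenomeRecord` objects.

    Sequences are uppercased and U is mapped to T; any character outside
    {A,C,G,T,N} is rejected with its position reported.
    """
    out = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"{path}: entry {entry.id!r} has an empty sequence")
        out.append(GenomeRecord(entry.id, species, compartment, seq, circular))
    return out


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# Features (GFF3 / BED)

_GFF_COLS = ["seq_id", "source", "feature_type", "start", "end",
             "score", "strand", "phase", "attributes"]


def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_features(path: str | Path, dialect: str = "gff3") -> list[FeatureRecord]:
    """Read gene/repeat/insertion annotations from GFF3 or BED.

    GFF3 1-based closed coordinates are converted to the internal 0-based
    half-open convention; BED is already 0-based half-open.
    """
    if dialect == "gff3":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=_GFF_COLS, dtype=str)
        out = []
        for row in df.itertuples(index=False):
            start, end = int(row.start) - 1, int(row.end)
            if end <= start:
                raise ValueError(f"{path}: feature with end < start at {row.seq_id}:{row.start}")
            attrs = _parse_gff_attributes(row.attributes)
            out.append(FeatureRecord(row.seq_id, start, end,
                                     row.strand if row.strand in "+-" else "+",
                                     row.feature_type, attrs.get("Name", attrs.get("ID", "")),
                                     attrs))
        return out
    if dialect == "bed":
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype=str)
        out = []
        for row in df.itertuples(index=False):
            fields = list(row)
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}: BED interval with end <= start on {fields[0]}")
            name = fields[3] if len(fields) > 3 and isinstance(fields[3], str) else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            out.append(FeatureRecord(fields[0], start, end, strand, "gene", name))
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def write_features_gff3(features: Iterable[FeatureRecord], path: str | Path,
                        source: str = "igtscan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            if f.name and "Name" not in attrs:
                attrs["Name"] = f.name
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(f"{f.seq_id}\t{source}\t{f.feature_type}\t{f.start + 1}\t{f.end}"
                     f"\t.\t{f.strand}\t.\t{attr_text}\n")


def write_features_bed(features: Iterable[FeatureRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{f.name or '.'}\t0\t{f.strand}\n")


# ---------------------------------------------------------------------------
# Hit tables (BLAST outfmt-6-like TSV)

HIT_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def write_hits_tsv(hits, path: str | Path, header: bool = False) -> None:
    """Write hits as a 12-column BLAST-tabular-style TSV.

    Coordinates are emitted 1-based inclusive; a subject start greater than
    the subject end encodes a reverse-orientation match.
    """
    rows = []
    for h in hits:
        mism = round((1.0 - h.identity) * h.aln_length)
        qs, qe = h.donor_start + 1, h.donor_end
        if h.orientation == "positive":
            ss, se = h.recipient_start + 1, h.recipient_end
        else:
            ss, se = h.recipient_end, h.recipient_start + 1
        rows.append([h.donor_seq, h.recipient_seq, f"{100.0 * h.identity:.3f}",
                     h.aln_length, mism, 0, qs, qe, ss, se,
                     f"{h.evalue:.3e}", h.score])
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, header=header)


def read_hits_tsv(path: str | Path, direction: str = "", header: bool = False) -> list:
    """Read an outfmt-6-like TSV back into :class:`~igtscan.search.TransferHit`."""
    from .search import TransferHit  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", header=0 if header else None,
                     names=HIT_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        ss, se = int(row.sstart), int(row.send)
        if ss <= se:
            orientation, rs, re_ = "positive", ss - 1, se
        else:
            orientation, rs, re_ = "reverse", se - 1, ss
        hits.append(TransferHit(
            donor_seq=row.qseqid, donor_start=int(row.qstart) - 1, donor_end=int(row.qend),
            recipient_seq=row.sseqid, recipient_start=rs, recipient_end=re_,
            orientation=orientation, identity=float(row.pident) / 100.0,
            aln_length=int(row.length), score=int(row.bitscore),
            evalue=float(row.evalue), direction=direction))
    return hits


# ---------------------------------------------------------------------------
# FASTQ

def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write ``(name, sequence)`` pairs as FASTQ with uniform quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]
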