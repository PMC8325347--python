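"""File I/O with fixed coordinate conventions.

Internal coordinates are 1-based inclusive everywhere (GFF3-native).  The only
conversion happens at the BED boundary, where an internal interval ``[s, e]``
becomes the 0-based half-open pair ``(s-1, e)``.  TSS tables are headered TSV
(replicon, position, strand, read_count) since no standard container exists for
Cappable-seq output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, InputError

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon: uppercase DNA over {A,C,G,T,N}."""

    replicon_id: str
    sequence: str
    topology: str = "linear"  # linear | circular

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene span, 1-based inclusive."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str  # "+" | "-"
    product: str = ""


@dataclass(frozen=True)
class TSSRecord:
    """A mapped transcription start: the +1 base of a transcript."""

    replicon_id: str
    position: int
    strand: str
    read_count: int


def read_genome(fasta_path: str | Path) -> list[GenomeRecord]:
    """Load replicons from FASTA, uppercased and alphabet-checked."""
    records = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{fasta_path}: empty sequence for record {rec.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{fasta_path}: record {rec.id!r} contains non-DNA characters {sorted(bad)}"
            )
        records.append(GenomeRecord(replicon_id=rec.id, sequence=seq))
    return records


def write_genome(records: Iterable[GenomeRecord], fasta_path: str | Path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.replicon_id, description="") for r in records],
        str(fasta_path),
        "fasta",
    )


def _gff_line_of(gff_path: Path, gene_id: str) -> int:
    # error path only: recover the line number of the offending feature
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if f"ID={gene_id}" in line:
                return lineno
    return 0


def read_features(
    gff_path: str | Path,
    feature_type: str = "gene",
    replicon_lengths: dict[str, int] | None = None,
) -> list[GeneFeature]:
    """Parse GFF3 rows of one feature type into GeneFeature records.

    Coordinates are preserved verbatim (GFF3 is already 1-based inclusive).
    When ``replicon_lengths`` is given, out-of-bounds features raise a
    FormatError naming the offending line.
    """
    gff_path = Path(gff_path)
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if gene_id in seen:
            raise FormatError(
                f"{gff_path}: duplicate gene id {gene_id!r} "
                f"(line {_gff_line_of(gff_path, gene_id)})"
            )
        seen.add(gene_id)
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{gff_path}: unknown strand {feat.strand!r} for {gene_id!r} "
                f"(line {_gff_line_of(gff_path, gene_id)})"
            )
        if replicon_lengths is not None:
            length = replicon_lengths.get(feat.seqid)
            if length is not None and not (1 <= feat.start <= feat.end <= length):
                raise FormatError(
                    f"{gff_path}: feature {gene_id!r} [{feat.start},{feat.end}] outside "
                    f"replicon {feat.seqid!r} of length {length} "
                    f"(line {_gff_line_of(gff_path, gene_id)})"
                )
        product = feat.attributes.get("product", [""])[0]
        features.append(
            GeneFeature(
                gene_id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                product=product,
            )
        )
    return features


def write_features(
    features: Iterable[GeneFeature], gff_path: str | Path, feature_type: str = "gene"
) -> None:
    """Write GeneFeature records as a minimal GFF3 file."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"ID={f.gene_id}"
            if f.product:
                attrs += f";product={f.product}"
            fh.write(
                f"{f.replicon_id}\tsigmaswitch\t{feature_type}\t{f.start}\t{f.end}"
                f"\t.\t{f.strand}\t.\t{attrs}\n"
            )


def read_tss_table(tsv_path: str | Path) -> list[TSSRecord]:
    """Read a headered TSS TSV (replicon, position, strand, read_count)."""
    df = pd.read_csv(tsv_path, sep="\t")
    required = {"replicon", "position", "strand", "read_count"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{tsv_path}: missing TSS columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise FormatError(f"{tsv_path}: unknown strand {row.strand!r}")
        if row.read_count < 0:
            raise FormatError(f"{tsv_path}: negative read_count {row.read_count}")
        records.append(
            TSSRecord(
                replicon_id=str(row.replicon),
                position=int(row.position),
                strand=str(row.strand),
                read_count=int(row.read_count),
            )
        )
    return records


def write_tss_table(records: Iterable[TSSRecord], tsv_path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "replicon": r.replicon_id,
                "position": r.position,
                "strand": r.strand,
                "read_count": r.read_count,
            }
            for r in records
        ],
        columns=["replicon", "position", "strand", "read_count"],
    ).to_csv(tsv_path, sep="\t", index=False)


def write_bed(
    intervals: Sequence[tuple[str, int, int, str, str]], bed_path: str | Path
) -> None:
    """Write internal 1-based inclusive intervals as BED6.

    Each interval is (replicon_id, start, end, name, strand); internal
    ``[s, e]`` maps to BED ``(s-1, e)``.  Score column is 0.
    """
    with open(bed_path, "w") as fh:
        for replicon_id, start, end, name, strand in intervals:
            if start < 1 or end < start:
                raise InputError(f"invalid internal interval [{start},{end}]")
            fh.write(f"{replicon_id}\t{start - 1}\t{end}\t{name}\t0\t{strand}\n")


def read_bed(bed_path: str | Path) -> list[tuple[str, int, int, str, str]]:
    """Read BED6 back into internal 1-based inclusive intervals."""
    intervals = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{bed_path}: line {lineno}: expected 6 BED columns")
            replicon_id, bed_start, bed_end, name, _score, strand = fields[:6]
            intervals.append((replicon_id, int(bed_start) + 1, int(bed_end), name, strand))
    return intervals
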