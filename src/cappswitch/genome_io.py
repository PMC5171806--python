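"""Input/output for every external format the pipeline touches.

Coordinate contract used throughout the package: all public genomic
coordinates are 1-based inclusive (the convention of GFF3 and of published
bacterial TSS tables). BED6 input, which is 0-based half-open, is converted
on read. Strand is ``"+"`` or ``"-"``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

VALID_STRANDS = ("+", "-")
_ALPHABET = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class Gene:
    """An annotated feature with 1-based inclusive genomic coordinates.

    ``start`` is always the leftmost coordinate and ``end`` the rightmost,
    regardless of strand; the translation start of a minus-strand gene is
    therefore at ``end``.
    """

    gene_id: str
    strand: str
    start: int
    end: int
    product: str = ""

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise FormatError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id}: invalid coordinates {self.start}..{self.end}"
            )

    @property
    def tx_start(self) -> int:
        """Translation/transcription-direction start (first base of the gene)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tx_stop(self) -> int:
        """3'-terminal base of the gene in its transcription direction."""
        return self.end if self.strand == "+" else self.start


@dataclass
class Annotation:
    """An ordered gene set on a single (by default circular) chromosome."""

    genes: list[Gene]
    genome_length: int
    circular: bool = True

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.end > self.genome_length:
                raise FormatError(
                    f"gene {g.gene_id} extends past genome end "
                    f"({g.end} > {self.genome_length})"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)


@dataclass
class StartCountTrack:
    """Strand-specific read 5'-end counts for one condition+replicate library.

    ``counts`` maps ``(strand, position)`` to the number of reads whose 5'
    end is at that 1-based position; ``library_size`` is the number of
    counted alignments, used for RPM normalization.
    """

    counts: dict[tuple[str, int], float]
    library_size: int
    label: str = ""
    genome_length: int | None = None

    def total(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class OperonTable:
    """Predicted operons: transcription direction plus ordered member genes."""

    operons: list[tuple[str, list[str]]] = field(default_factory=list)

    def __post_init__(self):
        seen: set[str] = set()
        for strand, members in self.operons:
            if strand not in VALID_STRANDS:
                raise FormatError(f"operon strand {strand!r} invalid")
            for gid in members:
                if gid in seen:
                    raise FormatError(f"gene {gid!r} appears in more than one operon")
                seen.add(gid)

    def start_genes(self) -> set[str]:
        """Gene ids that begin an operon in its transcription direction."""
        return {members[0] for _, members in self.operons if members}

    def member_genes(self) -> set[str]:
        return {g for _, members in self.operons for g in members}


# ---------------------------------------------------------------------------
# readers


def read_genome(fasta_path) -> tuple[str, int]:
    """Read the chromosome sequence from a FASTA file.

    The first record is taken as the chromosome (the organisms targeted here
    have single-chromosome genomes); additional records are ignored. Returns
    the uppercase sequence and its length.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: empty FASTA, no records")
    seq = str(records[0].seq).upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise FormatError(
            f"{fasta_path}: record {records[0].id!r} contains non-nucleotide "
            f"characters {sorted(bad)}"
        )
    if not seq:
        raise FormatError(f"{fasta_path}: record {records[0].id!r} is empty")
    return seq, len(seq)


def read_annotation(path, dialect: str = "auto", genome_length: int | None = None,
                    circular: bool = True) -> Annotation:
    """Read a gene annotation from GFF3 or a 5-column TSV.

    TSV columns: gene_id, strand, start, end, product (header optional).
    GFF3: ``gene`` features are used; if none are present, ``CDS`` features
    are used instead. Coordinates are kept as-is (both formats are 1-based
    inclusive).
    """
    path = str(path)
    if dialect == "auto":
        dialect = "gff3" if path.endswith((".gff", ".gff3")) else "tsv"
    if dialect == "gff3":
        genes, declared_length = _read_gff3(path)
    elif dialect == "tsv":
        genes, declared_length = _read_gene_tsv(path), None
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if genome_length is None:
        genome_length = declared_length or max((g.end for g in genes), default=1)
    return Annotation(genes=genes, genome_length=genome_length, circular=circular)


def _read_gff3(path) -> tuple[list[Gene], int | None]:
    genes: dict[str, list[Gene]] = {"gene": [], "CDS": []}
    declared_length = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    declared_length = int(parts[3])
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            ftype, start, end, strand, attrs = (
                fields[2], fields[3], fields[4], fields[6], fields[8])
            if ftype not in genes:
                continue
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            start, end = int(start), int(end)
            if start > end:
                raise FormatError(f"{path}:{lineno}: start > end ({start} > {end})")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = (attr.get("locus_tag") or attr.get("ID")
                   or attr.get("Name") or f"feature{lineno}")
            genes[ftype].append(Gene(gid, strand, start, end,
                                     product=attr.get("product", "")))
    chosen = genes["gene"] or genes["CDS"]
    if not chosen:
        raise FormatError(f"{path}: no gene or CDS features found")
    return chosen, declared_length


def _read_gene_tsv(path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f.strip() for f in line.replace(",", "\t").split("\t")]
            if fields[0] == "gene_id":  # header
                continue
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: need gene_id,strand,start,end")
            gid, strand, start, end = fields[:4]
            product = fields[4] if len(fields) > 4 else ""
            try:
                gene = Gene(gid, strand, int(start), int(end), product)
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            genes.append(gene)
    return genes


def read_start_track(path, dialect: str = "auto", condition: str = "",
                     replicate: str = "", genome_length: int | None = None,
                     invert_strand: bool = False,
                     min_mapq: int = 0) -> StartCountTrack:
    """Count read 5'-end positions from a BAM/SAM or BED6 file.

    For a plus-strand alignment the 5' end is its leftmost genomic
    coordinate; for a minus-strand alignment, its rightmost. ``invert_strand``
    flips the recorded strand, for library chemistries in which R1 maps
    antisense to the transcript. Only primary, mapped alignments are counted
    from BAM; every BED6 record is one pre-extracted read start.
    """
    path = str(path)
    if dialect == "auto":
        dialect = "bed6" if path.endswith((".bed", ".bed6")) else "bam"
    if dialect in ("bam", "sam"):
        counts, n = _count_bam(path, min_mapq)
    elif dialect == "bed6":
        counts, n = _count_bed6(path)
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    if n == 0:
        raise FormatError(f"{path}: empty track (no counted reads)")
    if invert_strand:
        counts = {("-" if s == "+" else "+", p): c for (s, p), c in counts.items()}
    if genome_length is not None:
        for (s, p) in counts:
            if not (1 <= p <= genome_length):
                raise FormatError(
                    f"{path}: read start at position {p} outside genome "
                    f"[1, {genome_length}]")
    label = f"{condition}/{replicate}" if condition or replicate else path
    return StartCountTrack(counts=counts, library_size=n, label=label,
                           genome_length=genome_length)


def _count_bam(path, min_mapq):
    import pysam

    mode = "r" if path.endswith(".sam") else "rb"
    counts: dict[tuple[str, int], float] = {}
    n = 0
    with pysam.AlignmentFile(path, mode) as bam:
        ref_names = list(bam.references)
        keep_ref = ref_names[0] if ref_names else None
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.is_paired and not aln.is_read1:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            if keep_ref is not None and aln.reference_name != keep_ref:
                continue
            if aln.is_reverse:
                key = ("-", aln.reference_end)  # reference_end is 0-based excl = 1-based incl
            else:
                key = ("+", aln.reference_start + 1)
            counts[key] = counts.get(key, 0) + 1
            n += 1
    return counts, n


def _count_bed6(path):
    counts: dict[tuple[str, int], float] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 columns")
            chrom_start, chrom_end, strand = int(fields[1]), int(fields[2]), fields[5]
            if strand not in VALID_STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            # BED is 0-based half-open; a 5'-end record covers one base.
            pos = chrom_start + 1 if strand == "+" else chrom_end
            counts[(strand, pos)] = counts.get((strand, pos), 0) + 1
            n += 1
    return counts, n


def trim_nontemplate_fastq(fastq_in, fastq_out, n: int = 3) -> int:
    """Remove the first ``n`` bases (and qualities) from every R1 read.

    Template-switching reverse transcription leaves a short non-template
    extension (3 bp for MMLV RT) at the 5' end of R1 reads that must be
    trimmed before the first aligned base can be read as the TSS. Reads of
    length <= n are dropped. Returns the number of dropped reads.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    dropped = 0
    with open(str(fastq_in)) as fin, open(str(fastq_out), "w") as fout:
        for i, rec in enumerate(_iter_fastq(fin, str(fastq_in))):
            name, seq, qual = rec
            if len(seq) <= n:
                dropped += 1
                continue
            fout.write(f"@{name}\n{seq[n:]}\n+\n{qual[n:]}\n")
    return dropped


def _iter_fastq(fh, path):
    idx = 0
    while True:
        header = fh.readline()
        if not header:
            return
        seq, plus, qual = fh.readline(), fh.readline(), fh.readline()
        if not header.startswith("@") or not plus.startswith("+") or not qual:
            raise FormatError(f"{path}: malformed FASTQ record at read index {idx}")
        seq, qual = seq.strip(), qual.strip()
        if len(seq) != len(qual):
            raise FormatError(f"{path}: length mismatch at read index {idx}")
        yield header[1:].strip(), seq, qual
        idx += 1


# ---------------------------------------------------------------------------
# TSS table serialization (mirrors the shape of published TSS classification
# tables: position, strand, class, downstream gene, gene start, distance,
# product, and one mean-RPM column per condition)

TSS_TABLE_FIXED_COLUMNS = [
    "position", "strand", "class", "gene_id", "gene_start", "distance",
    "product", "primary_global", "detected",
]


def write_tss_table(classified, path, conditions: list[str] | None = None,
                    header_comment: str | None = None) -> None:
    """Write classified TSS to a TSV with one mean-RPM column per condition."""
    if conditions is None:
        seen: list[str] = []
        for c in classified:
            for cond in c.tss.mean_rpm_by_condition:
                if cond not in seen:
                    seen.append(cond)
        conditions = seen
    rows = []
    for c in sorted(classified, key=lambda c: (c.tss.position, c.tss.strand)):
        row = {
            "position": c.tss.position,
            "strand": c.tss.strand,
            "class": c.tss_class,
            "gene_id": c.gene_id,
            "gene_start": "" if c.gene_start is None else c.gene_start,
            "distance": "" if c.distance is None else c.distance,
            "product": c.product,
            "primary_global": int(c.is_primary_global),
            "detected": ",".join(sorted(c.tss.detected_conditions)),
        }
        for cond in conditions:
            row[f"rpm_{cond}"] = round(c.tss.mean_rpm_by_condition.get(cond, 0.0), 6)
        rows.append(row)
    cols = TSS_TABLE_FIXED_COLUMNS + [f"rpm_{c}" for c in conditions]
    df = pd.DataFrame(rows, columns=cols)
    buf = io.StringIO()
    if header_comment:
        for line in header_comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(str(path), "w") as fh:
        fh.write(buf.getvalue())


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS table written by :func:`write_tss_table`."""
    df = pd.read_csv(str(path), sep="\t", comment="#")
    for col in ("gene_start", "distance"):
        if col in df:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def read_operon_table(path) -> OperonTable:
    """Read operons from a TSV of ``direction<TAB>comma-separated gene ids``."""
    operons = []
    with open(str(path)) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("direction"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: need direction<TAB>genes")
            strand, members = fields[0], [g.strip() for g in fields[1].split(",") if g.strip()]
            operons.append((strand, members))
    return OperonTable(operons=operons)


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as FASTA, 70 columns per line."""
    with open(str(path), "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
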