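"""Input/output for SELEX reads, genomic intervals and SNP tables.

Coordinates follow the field conventions: BED intervals are 0-based
half-open, SNP positions are 1-based (VCF style).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from pyfaidx import Fasta

from .patterns import encode_reads, revcomp

log = logging.getLogger(__name__)


@dataclass
class ReadSet:
    """An ordered collection of equal-length DNA reads.

    ``total_reads`` is the symbol T (library) or T_b (bound sample) used in
    enrichment normalization.  Reads containing N are retained (they count
    toward the total) but are flagged so pattern counting can skip them.
    """

    reads: list[str]
    read_length: int | None = None
    name: str = ""

    def __post_init__(self):
        self.reads = [r.upper() for r in self.reads]
        if self.read_length is None and self.reads:
            self.read_length = len(self.reads[0])

    @property
    def total_reads(self) -> int:
        return len(self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)

    def encoded(self) -> tuple[np.ndarray, np.ndarray]:
        """(N, L) uint8 base-code array and a validity mask (no ambiguous bases)."""
        return encode_reads(self.reads, self.read_length)


@dataclass
class BarcodeMap:
    """6-nt (by default) barcode -> sample mapping plus the read layout.

    The default layout places the barcode at the 5' end immediately followed
    by the variable region; constant flanks are configurable because SELEX
    construct designs vary.
    """

    barcodes: dict[str, str]
    flank5: str = ""
    flank3: str = ""
    variable_length: int = 20

    def __post_init__(self):
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")
        lens = {len(b) for b in self.barcodes}
        if len(lens) > 1:
            raise ValueError("barcodes must have uniform length")
        samples = list(self.barcodes.values())
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcode in map")
        if len(set(samples)) != len(samples):
            raise ValueError("barcode collision: two barcodes map to one sample "
                             "is allowed, but identical sample ids for distinct "
                             "barcodes would merge bins ambiguously")

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcodes))) if self.barcodes else 0

    @property
    def min_read_length(self) -> int:
        return self.barcode_length + len(self.flank5) + self.variable_length


@dataclass
class GenomicInterval:
    """0-based half-open genomic interval, optionally carrying its sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    sequence: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class SnpRecord:
    """A biallelic SNP with both allele-substituted flank windows."""

    id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_flank: str = ""
    alt_flank: str = ""

    def __post_init__(self):
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("alleles must be single bases")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


def _open_text(path, gz: bool | None = None):
    path = Path(path)
    if gz is None:
        gz = path.suffix == ".gz"
    return gzip.open(path, "rt") if gz else open(path)


def load_reads(path, format: str | None = None, gz: bool | None = None,
               name: str = "") -> ReadSet:
    """Load a FASTA/FASTQ (optionally gzipped) file into a ReadSet.

    The format is inferred from the file name when not given.  Sequences are
    uppercased.  An empty file yields an empty ReadSet with a warning.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        format = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    with _open_text(path, gz) as fh:
        reads = [str(rec.seq).upper() for rec in SeqIO.parse(fh, format)]
    if not reads:
        warnings.warn(f"no records in {path}", stacklevel=2)
    return ReadSet(reads, name=name or path.stem)


def write_fasta(readset: ReadSet, path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(readset):
            fh.write(f">{prefix}{i}\n{seq}\n")


def write_fastq(readset: ReadSet, path, prefix: str = "read", qual_char: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(readset):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{qual_char * len(seq)}\n")


def demultiplex_and_trim(raw: ReadSet, barcodes: BarcodeMap
                         ) -> tuple[dict[str, ReadSet], ReadSet]:
    """Split raw reads by exact barcode match and trim to the variable region.

    Every input read lands in exactly one bin: the matching sample or the
    discard bin (unknown barcode, or read too short for the layout).
    """
    blen = barcodes.barcode_length
    offset = blen + len(barcodes.flank5)
    vlen = barcodes.variable_length
    bins: dict[str, list[str]] = {s: [] for s in barcodes.barcodes.values()}
    discarded: list[str] = []
    for read in raw:
        if len(read) < barcodes.min_read_length:
            discarded.append(read)
            continue
        sample = barcodes.barcodes.get(read[:blen])
        if sample is None:
            discarded.append(read)
        else:
            bins[sample].append(read[offset:offset + vlen])
    out = {s: ReadSet(rs, read_length=vlen, name=s) for s, rs in bins.items()}
    return out, ReadSet(discarded, read_length=None, name="discard")


def load_intervals_with_sequence(bed_path, genome_path,
                                 ) -> list[GenomicInterval]:
    """Load BED intervals (3-6 columns) and fill sequences from an indexed FASTA.

    Minus-strand intervals are reverse-complemented.  Unknown chromosomes or
    out-of-bounds coordinates raise with the offending line number.
    """
    genome = Fasta(str(genome_path))
    out = []
    with _open_text(bed_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name = f[3] if len(f) > 3 else ""
                strand = f[5] if len(f) > 5 else "."
                iv = GenomicInterval(chrom, start, end, strand, name)
            except (ValueError, IndexError) as e:
                raise ValueError(f"{bed_path} line {lineno}: {e}") from e
            if chrom not in genome:
                raise ValueError(f"{bed_path} line {lineno}: unknown chromosome {chrom}")
            if end > len(genome[chrom]):
                raise ValueError(f"{bed_path} line {lineno}: interval beyond "
                                 f"chromosome end ({end} > {len(genome[chrom])})")
            seq = str(genome[chrom][start:end]).upper()
            iv.sequence = revcomp(seq) if strand == "-" else seq
            out.append(iv)
    return out


def load_snp_table(path, genome_path, flank: int = 20) -> tuple[list[SnpRecord], dict]:
    """Load SNPs from a minimal VCF or TSV and build +/- ``flank`` windows.

    Accepted TSV columns: id, chrom, pos (1-based), ref, alt -- or VCF order
    (chrom, pos, id, ref, alt) which is auto-detected for ``.vcf`` input and
    for header-less rows whose second column is numeric.

    Rows are skipped (with counted warnings) when: indel/multiallelic, ref ==
    alt, reference base disagrees with the genome, or the window would run off
    the chromosome.  Returns (records, skip_counters).
    """
    genome = Fasta(str(genome_path))
    skipped = {"indel_or_multiallelic": 0, "ref_mismatch": 0,
               "identical_alleles": 0, "out_of_bounds": 0}
    records: list[SnpRecord] = []
    is_vcf = str(path).endswith((".vcf", ".vcf.gz"))
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if f[0].lower() in ("id", "snp", "rsid", "chrom"):
                continue  # header row
            if is_vcf or (len(f) >= 5 and f[1].isdigit() and not f[2].isdigit()):
                chrom, pos, sid, ref, alt = f[0], f[1], f[2], f[3], f[4]
            else:
                sid, chrom, pos, ref, alt = f[0], f[1], f[2], f[3], f[4]
            pos = int(pos)
            ref, alt = ref.upper(), alt.upper()
            if len(ref) != 1 or len(alt) != 1 or "," in alt:
                skipped["indel_or_multiallelic"] += 1
                continue
            if ref == alt:
                skipped["identical_alleles"] += 1
                continue
            if chrom not in genome:
                raise ValueError(f"{path} line {lineno}: unknown chromosome {chrom}")
            chrom_len = len(genome[chrom])
            lo, hi = pos - 1 - flank, pos + flank  # 0-based half-open window
            if lo < 0 or hi > chrom_len:
                skipped["out_of_bounds"] += 1
                continue
            genome_base = str(genome[chrom][pos - 1]).upper()
            if genome_base != ref:
                log.warning("%s line %d: ref %s disagrees with genome %s; row dropped",
                            path, lineno, ref, genome_base)
                skipped["ref_mismatch"] += 1
                continue
            window = str(genome[chrom][lo:hi]).upper()
            center = pos - 1 - lo
            alt_flank = window[:center] + alt + window[center + 1:]
            records.append(SnpRecord(sid, chrom, pos, ref, alt,
                                     ref_flank=window, alt_flank=alt_flank))
    return records, skipped
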