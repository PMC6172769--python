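"""Readers and writers for the on-disk formats the pipeline consumes.

All coordinates are 0-based, half-open internally.  GFF3 (1-based, closed)
is converted on the way in and out; BED is already 0-based half-open.  The
transcription start site (TSS) of a minus-strand gene is ``end - 1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

REPEAT_CLASSES = ("LINE", "SINE", "DNA", "LTR", "simple", "other")

GENE_SUBFEATURES = ("five_prime_utr", "exon", "intron", "three_prime_utr")

_GFF_TYPE_MAP = {
    "five_prime_UTR": "five_prime_utr",
    "5'UTR": "five_prime_utr",
    "exon": "exon",
    "intron": "intron",
    "three_prime_UTR": "three_prime_utr",
    "3'UTR": "three_prime_utr",
}


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""


@dataclass
class GenomeIndex:
    """In-memory genome: scaffold name -> sequence (upper-case string)."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside scaffold length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass
class GeneRecord:
    """A gene interval with strand, optional sub-features and flags.

    ``features`` maps a sub-feature type (five_prime_utr, exon, intron,
    three_prime_utr) to a list of (start, end) intervals contained in the
    gene interval.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    features: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    housekeeping: bool = False

    @property
    def tss(self) -> int:
        """Transcription start site; for '-' strand genes this is end - 1."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepeatRecord:
    chrom: str
    start: int
    end: int
    repeat_class: str
    intragenic: bool = False


@dataclass
class AnnotationSet:
    """Genes plus repeats; repeat ``intragenic`` flags are kept consistent."""

    genes: list[GeneRecord]
    repeats: list[RepeatRecord] = field(default_factory=list)

    def gene_by_id(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "strand": [g.strand for g in self.genes],
                "tss": [g.tss for g in self.genes],
                "housekeeping": [g.housekeeping for g in self.genes],
            }
        )

    def repeat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.repeats],
                "start": [r.start for r in self.repeats],
                "end": [r.end for r in self.repeats],
                "repeat_class": [r.repeat_class for r in self.repeats],
                "intragenic": [r.intragenic for r in self.repeats],
            }
        )

    def compute_intragenic_flags(self) -> None:
        """Set each repeat's intragenic flag from overlap with any gene."""
        trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end)
        for r in self.repeats:
            tree = trees.get(r.chrom)
            r.intragenic = bool(tree is not None and tree.overlap(r.start, r.end))


class ReadObservation(NamedTuple):
    """One read's evidence at a cytosine position.

    ``flanks`` holds the Phred qualities of the two read bases before and
    after the C within the read (read coordinates, not reference);
    observations with the C within 2 bases of a read end carry ``None``
    entries and cannot pass the flanking-quality filter.
    """

    base: str
    quality: int
    flanks: tuple[Optional[int], Optional[int], Optional[int], Optional[int]]
    read_name: str = ""


@dataclass
class PileupColumn:
    chrom: str
    pos: int
    strand: str
    observations: list[ReadObservation] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.observations)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeIndex:
    """Load a FASTA file into a :class:`GenomeIndex`.

    Raises :class:`FastaParseError` (naming the line) on malformed input,
    including an empty file.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line[:20]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FastaParseError(f"{path}: record {rec.id} has empty sequence")
        sequences[rec.id] = str(rec.seq).upper()
    return GenomeIndex(sequences)


def write_fasta(genome: GenomeIndex, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation (GFF3 / BED12 genes, BED repeats)


def _finalize_gene(gene: GeneRecord) -> GeneRecord:
    """Derive introns as the gaps between sorted exons when absent."""
    exons = sorted(gene.features.get("exon", []))
    if exons and "intron" not in gene.features:
        introns = [
            (exons[i][1], exons[i + 1][0])
            for i in range(len(exons) - 1)
            if exons[i + 1][0] > exons[i][1]
        ]
        if introns:
            gene.features["intron"] = introns
    return gene


def read_annotation(
    path: str | Path,
    fmt: str = "gff3",
    repeats_path: str | Path | None = None,
    genome: GenomeIndex | None = None,
) -> AnnotationSet:
    """Read gene annotation (GFF3 or BED12) and optional repeats (BED).

    Intervals are converted to 0-based half-open coordinates.  Unknown
    feature types are skipped with a logged warning; a feature outside its
    scaffold's bounds (when ``genome`` is given) is an error.  Repeat
    intragenic flags are computed from gene overlap.
    """
    if fmt == "gff3":
        genes = _read_gff3_genes(Path(path), genome)
    elif fmt == "bed12":
        genes = _read_bed12_genes(Path(path), genome)
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    annotation = AnnotationSet(genes=genes)
    if repeats_path is not None:
        annotation.repeats = read_repeats_bed(repeats_path)
    annotation.compute_intragenic_flags()
    return annotation


def _check_bounds(
    chrom: str, start: int, end: int, genome: GenomeIndex | None, what: str
) -> None:
    if genome is None:
        return
    if chrom not in genome:
        raise ValueError(f"{what}: unknown scaffold {chrom!r}")
    length = len(genome.sequences[chrom])
    if start < 0 or end > length:
        raise ValueError(
            f"{what}: interval {chrom}:{start}-{end} outside scaffold length {length}"
        )


def _read_gff3_genes(path: Path, genome: GenomeIndex | None) -> list[GeneRecord]:
    genes: dict[str, GeneRecord] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = fields
            start, end = int(start1) - 1, int(end1)  # GFF3 is 1-based closed
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID", f"gene_{lineno}")
                _check_bounds(chrom, start, end, genome, f"gene {gid}")
                hk = attr.get("housekeeping", "0") in ("1", "true", "True")
                genes[gid] = GeneRecord(gid, chrom, start, end, strand, {}, hk)
            elif ftype in _GFF_TYPE_MAP:
                parent = attr.get("Parent")
                if parent is None or parent not in genes:
                    log.warning("%s line %d: %s without known Parent, skipped", path, lineno, ftype)
                    continue
                _check_bounds(chrom, start, end, genome, f"{ftype} of {parent}")
                genes[parent].features.setdefault(_GFF_TYPE_MAP[ftype], []).append(
                    (start, end)
                )
            else:
                log.warning("%s line %d: unknown feature type %r skipped", path, lineno, ftype)
    return [_finalize_gene(g) for g in genes.values()]


def _read_bed12_genes(path: Path, genome: GenomeIndex | None) -> list[GeneRecord]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED columns")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            _check_bounds(chrom, start, end, genome, f"gene {name}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            gene = GeneRecord(name, chrom, start, end, strand, {"exon": exons})
            genes.append(_finalize_gene(gene))
    return genes


def read_repeats_bed(path: str | Path) -> list[RepeatRecord]:
    repeats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            cls = f[3] if len(f) > 3 else "other"
            if cls not in REPEAT_CLASSES:
                cls = "other"
            repeats.append(RepeatRecord(f[0], int(f[1]), int(f[2]), cls))
    return repeats


def write_gff3(annotation: AnnotationSet, path: str | Path) -> None:
    """Write genes and sub-features as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.chrom, g.start)):
            hk = "1" if g.housekeeping else "0"
            fh.write(
                f"{g.chrom}\tgbmethyl\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};housekeeping={hk}\n"
            )
            rev = {v: k for k, v in _GFF_TYPE_MAP.items() if k in GENE_SUBFEATURES}
            for ftype in GENE_SUBFEATURES:
                for (s, e) in sorted(g.features.get(ftype, [])):
                    gff_type = rev.get(ftype, ftype)
                    fh.write(
                        f"{g.chrom}\tgbmethyl\t{gff_type}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"Parent={g.gene_id}\n"
                    )


def write_repeats_bed(repeats: Sequence[RepeatRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.repeat_class}\t0\t+\n")


# ---------------------------------------------------------------------------
# Alignments -> pileup

#: bisulfite read base -> informative state, per strand of the cytosine.
#: '+' strand cytosines read C (methylated) / T (converted); '-' strand
#: cytosines appear in forward reference orientation as G / A.
_STATE_BASES = {"+": {"C": "C", "T": "T"}, "-": {"G": "C", "A": "T"}}


def cpg_positions(genome: GenomeIndex) -> dict[str, np.ndarray]:
    """0-based positions of the C of each CpG dyad (plus-strand C)."""
    out = {}
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        out[name] = np.where((arr[:-1] == b"C") & (arr[1:] == b"G"))[0]
    return out


def non_cpg_cytosines(genome: GenomeIndex) -> dict[str, dict[str, np.ndarray]]:
    """Per-scaffold non-CpG cytosine positions on each strand."""
    out = {}
    for name, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c = arr == b"C"
        is_g = arr == b"G"
        cpg_c = np.zeros(len(arr), dtype=bool)
        cpg_c[:-1] = is_c[:-1] & is_g[1:]
        cpg_g = np.zeros(len(arr), dtype=bool)
        cpg_g[1:] = is_c[:-1] & is_g[1:]
        out[name] = {
            "+": np.where(is_c & ~cpg_c)[0],
            "-": np.where(is_g & ~cpg_g)[0],
        }
    return out


def _read_strand(read: pysam.AlignedSegment) -> str:
    """Bisulfite strand of the fragment, from the aligner's ZS tag."""
    if read.has_tag("ZS"):
        return str(read.get_tag("ZS"))[0]
    return "-" if read.is_reverse else "+"


def read_alignments_to_pileup(
    path: str | Path,
    genome: GenomeIndex,
    min_mapq: int = 20,
    positions: dict[str, dict[str, np.ndarray]] | None = None,
) -> Iterator[PileupColumn]:
    """Stream pileup columns at cytosine positions from a sorted SAM/BAM.

    Only proper pairs with both mates uniquely mapped (MAPQ >= ``min_mapq``,
    not secondary/supplementary) to the same scaffold contribute.  Overlapping
    mates of one pair count once per position (first mate encountered wins).
    Columns are emitted in (scaffold, position) order; ``positions`` may
    restrict emission (default: all CpG and non-CpG cytosines).

    Raises on coordinate-unsorted input or reads without base qualities.
    """
    if positions is None:
        cpg = cpg_positions(genome)
        noncpg = non_cpg_cytosines(genome)
        positions = {}
        for chrom in genome.sequences:
            positions[chrom] = {
                "+": np.union1d(cpg[chrom], noncpg[chrom]["+"]),
                "-": np.union1d(cpg[chrom] + 1, noncpg[chrom]["-"]),
            }

    # per (pos, strand): {read_name: ReadObservation}
    buffer: dict[tuple[int, str], dict[str, ReadObservation]] = {}
    current_chrom: str | None = None
    last_start = -1

    def flush(chrom: str, before: int | None) -> Iterator[PileupColumn]:
        for key in sorted(k for k in buffer if before is None or k[0] < before):
            pos, strand = key
            obs = list(buffer.pop(key).values())
            yield PileupColumn(chrom, pos, strand, obs)

    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if (
                read.is_unmapped
                or not read.is_proper_pair
                or read.is_secondary
                or read.is_supplementary
                or read.mapping_quality < min_mapq
            ):
                continue
            if read.next_reference_id != read.reference_id:
                continue  # mates must map to the same scaffold
            chrom = read.reference_name
            if chrom != current_chrom:
                if current_chrom is not None:
                    yield from flush(current_chrom, None)
                current_chrom = chrom
                last_start = -1
            if read.reference_start < last_start:
                raise ValueError(f"{path}: input not coordinate-sorted at {chrom}")
            last_start = read.reference_start
            yield from flush(chrom, read.reference_start)
            quals = read.query_qualities
            if quals is None:
                raise ValueError(f"{path}: read {read.query_name} has no base qualities")
            strand = _read_strand(read)
            want = positions.get(chrom, {}).get(strand)
            if want is None or len(want) == 0:
                continue
            seq = read.query_sequence
            lo = np.searchsorted(want, read.reference_start)
            hi = np.searchsorted(want, read.reference_end)
            if lo == hi:
                continue
            ref_to_q = dict(
                (r, q)
                for q, r in read.get_aligned_pairs(matches_only=True)
            )
            n = len(seq)
            for pos in want[lo:hi]:
                qpos = ref_to_q.get(int(pos))
                if qpos is None:
                    continue
                flanks = tuple(
                    quals[qpos + d] if 0 <= qpos + d < n else None
                    for d in (-2, -1, 1, 2)
                )
                obs = ReadObservation(seq[qpos], int(quals[qpos]), flanks, read.query_name)
                col = buffer.setdefault((int(pos), strand), {})
                col.setdefault(read.query_name, obs)  # first mate wins
    if current_chrom is not None:
        yield from flush(current_chrom, None)


# ---------------------------------------------------------------------------
# bedGraph and tabular site tracks


def write_bedgraph(sites: pd.DataFrame, prefix: str | Path) -> tuple[Path, Path]:
    """Write per-CpG methylation ratios as strand-split bedGraph files.

    ``sites`` needs columns chrom, pos, strand, ratio; ratios must lie in
    [0, 1].  Returns the (.plus, .minus) paths.  Lines are ordered by
    (scaffold, position).
    """
    if len(sites) and ((sites["ratio"] < 0) | (sites["ratio"] > 1)).any():
        raise ValueError("methylation ratios must lie in [0, 1]")
    prefix = Path(prefix)
    paths = (
        prefix.with_suffix(prefix.suffix + ".plus.bedGraph"),
        prefix.with_suffix(prefix.suffix + ".minus.bedGraph"),
    )
    for strand, path in zip("+-", paths):
        sub = sites[sites["strand"] == strand].sort_values(["chrom", "pos"])
        with open(path, "w") as fh:
            fh.write(f'track type=bedGraph name="CpG methylation ({strand})"\n')
            for row in sub.itertuples():
                fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{row.ratio:g}\n")
    return paths


def read_bedgraph(path: str | Path, strand: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#")) or not line.strip():
                continue
            chrom, start, _end, value = line.split("\t")
            rows.append((chrom, int(start), strand, float(value)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "ratio"])


SITE_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "coverage", "ratio"]


def write_sites_tsv(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=SITE_COLUMNS)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fragments_bed(fragments: pd.DataFrame, path: str | Path) -> None:
    fragments.sort_values(["chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False, columns=["chrom", "start", "end"]
    )


def read_fragments_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"],
        dtype={0: str},
    )
    if len(df) and (df["start"] >= df["end"]).any():
        raise ValueError(f"{path}: fragment with start >= end")
    return df


def write_pileup_tsv(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Serialize pileup columns as TSV: one column per line, observations
    encoded ``base:qual:f-2,f-1,f+1,f+2`` (``.`` for a missing flank)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tstrand\tobservations\n")
        for col in columns:
            obs = ";".join(
                f"{o.base}:{o.quality}:"
                + ",".join("." if q is None else str(q) for q in o.flanks)
                for o in col.observations
            )
            fh.write(f"{col.chrom}\t{col.pos}\t{col.strand}\t{obs}\n")


def read_pileup_tsv(path: str | Path) -> Iterator[PileupColumn]:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom"):
            raise ValueError(f"{path}: missing pileup TSV header")
        for line in fh:
            chrom, pos, strand, encoded = line.rstrip("\n").split("\t")
            observations = []
            if encoded:
                for i, tok in enumerate(encoded.split(";")):
                    base, qual, flanks = tok.split(":")
                    observations.append(
                        ReadObservation(
                            base,
                            int(qual),
                            tuple(
                                None if q == "." else int(q)
                                for q in flanks.split(",")
                            ),
                            read_name=f"r{i}",
                        )
                    )
            yield PileupColumn(chrom, int(pos), strand, observations)


def write_peaks_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.sort_values(["chrom", "start", "end"]).to_csv(
        path, sep="\t", index=False, header=False, columns=["chrom", "start", "end"]
    )


read_peaks_bed = read_fragments_bed
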