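"""Gene-model parsing, intron extraction, and intron sequence features.

Ciliate genes carry extremely short introns (here 15-100 nt, median ~24 nt).
This module turns GTF gene models plus a genome FASTA into per-intron records
with the features the downstream analyses consume: length, GC content,
relative position within the gene, splice-site dinucleotides, and the
canonical GT-AG flag.

Coordinates are 1-based inclusive internally (GTF convention); BED export is
0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pyranges

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

LENGTH_GROUPS = ("15-22", "23-26", ">=27")
POSITION_GROUPS = ("five_prime", "middle", "three_prime")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def fetch(genome, contig: str, start: int, end: int) -> str:
    """Return the forward-strand sequence for a 1-based inclusive interval.

    ``genome`` may be a plain mapping of contig -> sequence string or a
    ``pyfaidx.Fasta`` object.
    """
    if start < 1:
        raise ValueError(f"coordinate {start} < 1 on {contig}")
    record = genome[contig]
    if isinstance(record, str):
        if end > len(record):
            raise ValueError(f"interval {start}-{end} beyond end of {contig}")
        return record[start - 1 : end].upper()
    # pyfaidx record
    if end > len(record):
        raise ValueError(f"interval {start}-{end} beyond end of {contig}")
    return str(record[start - 1 : end]).upper()


@dataclass
class GeneModel:
    """A single representative transcript of a protein-coding gene."""

    gene_id: str
    contig: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # transcription order, 1-based inclusive
    species: str = ""
    cds_start: int | None = None  # genomic position of the first codon base

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        # store in transcription order
        self.exons = genomic if self.strand == "+" else genomic[::-1]
        if self.cds_start is None:
            self.cds_start = self.exons[0][0] if self.strand == "+" else self.exons[0][1]

    @property
    def span(self) -> tuple[int, int]:
        genomic = sorted(self.exons)
        return genomic[0][0], genomic[-1][1]

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1


@dataclass
class IntronRecord:
    """One intron with its gene context and sequence features."""

    intron_id: str
    gene_id: str
    index: int  # 1-based ordinal, 5'->3' in transcription order
    contig: str
    strand: str
    start: int  # genomic, 1-based inclusive
    end: int
    seq: str = ""  # transcribed-strand sequence
    length: int = 0
    gc: float = float("nan")
    rel_pos: float = float("nan")
    donor: str = ""
    acceptor: str = ""
    canonical: bool = False

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"intron {self.intron_id}: end < start")
        self.length = self.end - self.start + 1


def read_gtf(path: str | Path, species: str = "") -> dict[str, GeneModel]:
    """Read exon features from a GTF and return one GeneModel per gene.

    Multi-transcript genes are collapsed to the transcript with the largest
    summed exon length (a proxy for the longest CDS); the choice is logged.
    """
    df = pyranges.read_gtf(str(path)).df
    df = df[df["Feature"] == "exon"]
    if df.empty:
        raise ValueError(f"no exon features in {path}")
    genes: dict[str, GeneModel] = {}
    for gene_id, gdf in df.groupby("gene_id", sort=True):
        tx_col = gdf["transcript_id"] if "transcript_id" in gdf else gdf["gene_id"]
        by_tx = gdf.groupby(tx_col)
        if by_tx.ngroups > 1:
            sizes = by_tx.apply(lambda t: int((t["End"] - t["Start"]).sum()), include_groups=False)
            chosen = sizes.idxmax()
            logger.info("gene %s: %d transcripts, keeping %s", gene_id, by_tx.ngroups, chosen)
            gdf = gdf[tx_col == chosen]
        exons = [(int(s) + 1, int(e)) for s, e in zip(gdf["Start"], gdf["End"])]
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            contig=str(gdf["Chromosome"].iloc[0]),
            strand=str(gdf["Strand"].iloc[0]),
            exons=exons,
            species=species,
        )
    return genes


def extract_introns(gene: GeneModel, genome) -> list[IntronRecord]:
    """Extract the sequences between consecutive exons of one gene.

    Returns ``n_exons - 1`` records in 5'->3' transcription order with all
    sequence features populated; minus-strand introns are reverse
    complemented so that ``seq``, ``donor`` and ``acceptor`` read in the
    transcribed orientation.
    """
    genomic = sorted(gene.exons)
    contig_len = len(genome[gene.contig])
    if genomic[-1][1] > contig_len:
        raise ValueError(
            f"gene {gene.gene_id}: exon end {genomic[-1][1]} beyond contig "
            f"{gene.contig} ({contig_len} nt)"
        )
    gaps = [
        (genomic[i][1] + 1, genomic[i + 1][0] - 1) for i in range(len(genomic) - 1)
    ]
    if gene.strand == "-":
        gaps = gaps[::-1]
    records = []
    for i, (start, end) in enumerate(gaps, start=1):
        seq = fetch(genome, gene.contig, start, end)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        rec = IntronRecord(
            intron_id=f"{gene.gene_id}.i{i}",
            gene_id=gene.gene_id,
            index=i,
            contig=gene.contig,
            strand=gene.strand,
            start=start,
            end=end,
            seq=seq,
        )
        intron_features(rec, gene)
        records.append(rec)
    return records


def intron_features(intron: IntronRecord, gene: GeneModel) -> IntronRecord:
    """Populate gc, rel_pos, splice-site dinucleotides and the canonical flag.

    ``gc`` counts G and C over the intron length (ambiguous bases count as
    non-GC). ``rel_pos`` is the distance from the first codon to the intron's
    transcribed 5' end, divided by the gene span, clamped to [0, 1].
    """
    seq = intron.seq.upper()
    if not seq:
        raise ValueError(f"intron {intron.intron_id} has no sequence")
    gc_count = seq.count("G") + seq.count("C")
    if set(seq) <= {"N"}:
        warnings.warn(f"intron {intron.intron_id} is all-N; gc set to 0")
    intron.gc = gc_count / len(seq)
    five_prime = intron.start if intron.strand == "+" else intron.end
    if intron.strand == "+":
        offset = five_prime - gene.cds_start
    else:
        offset = gene.cds_start - five_prime
    intron.rel_pos = min(1.0, max(0.0, offset / gene.length))
    intron.donor = seq[:2]
    intron.acceptor = seq[-2:]
    intron.canonical = intron.donor == "GT" and intron.acceptor == "AG"
    return intron


def classify_position(rel_pos: float) -> str:
    """Bin a relative intron position into 5'/middle/3' thirds of the gene.

    Boundaries are inclusive: rel_pos <= 0.25 is 5', >= 0.75 is 3'.
    """
    if not 0.0 <= rel_pos <= 1.0:
        raise ValueError(f"rel_pos {rel_pos} outside [0,1]")
    if rel_pos <= 0.25:
        return "five_prime"
    if rel_pos >= 0.75:
        return "three_prime"
    return "middle"


def classify_first_intron_group(introns: list[IntronRecord]) -> str:
    """Group a gene by the relative position of its first intron.

    Returns "5p" / "middle" / "3p", or "intronless" for genes without
    introns (excluded from position-group comparisons).
    """
    if not introns:
        return "intronless"
    first = min(introns, key=lambda r: r.index)
    return {"five_prime": "5p", "middle": "middle", "three_prime": "3p"}[
        classify_position(first.rel_pos)
    ]


def classify_length_group(length: int) -> str:
    """Assign an intron length to the 15-22 / 23-26 / >=27 nt quartile groups."""
    if length < 15:
        raise ValueError(f"intron length {length} below the 15 nt minimum")
    if length <= 22:
        return "15-22"
    if length <= 26:
        return "23-26"
    return ">=27"


def splice_site_pfm(
    introns: list[IntronRecord],
    genome,
    exon_flank: int = 3,
    intron_flank: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Position frequency matrices around donor and acceptor sites.

    Donor columns run exon_flank exonic bases then intron_flank intronic
    bases (transcribed orientation); acceptor columns run intron_flank
    intronic bases then exon_flank exonic bases. Counts, not frequencies;
    column sums equal the number of contributing introns.
    """
    bases = ["A", "C", "G", "T", "N"]
    n_cols = exon_flank + intron_flank
    donor = pd.DataFrame(0, index=bases, columns=range(n_cols))
    acceptor = pd.DataFrame(0, index=bases, columns=range(n_cols))
    if not introns:
        return donor.iloc[:, :0], acceptor.iloc[:, :0]
    for rec in introns:
        if rec.strand == "+":
            d = fetch(genome, rec.contig, rec.start - exon_flank, rec.start + intron_flank - 1)
            a = fetch(genome, rec.contig, rec.end - intron_flank + 1, rec.end + exon_flank)
        else:
            d = reverse_complement(
                fetch(genome, rec.contig, rec.end - intron_flank + 1, rec.end + exon_flank)
            )
            a = reverse_complement(
                fetch(genome, rec.contig, rec.start - exon_flank, rec.start + intron_flank - 1)
            )
        for j, b in enumerate(d):
            donor.loc[b if b in bases else "N", j] += 1
        for j, b in enumerate(a):
            acceptor.loc[b if b in bases else "N", j] += 1
    return donor, acceptor


def pfm_frequencies(pfm: pd.DataFrame) -> pd.DataFrame:
    """Normalize a count PFM so each column sums to 1."""
    totals = pfm.sum(axis=0)
    return pfm / totals.replace(0, 1)


def feature_table(introns: list[IntronRecord]) -> pd.DataFrame:
    rows = [
        {
            "intron_id": r.intron_id,
            "gene_id": r.gene_id,
            "index": r.index,
            "contig": r.contig,
            "strand": r.strand,
            "start": r.start,
            "end": r.end,
            "length": r.length,
            "gc": r.gc,
            "rel_pos": r.rel_pos,
            "donor": r.donor,
            "acceptor": r.acceptor,
            "canonical": r.canonical,
            "length_group": classify_length_group(r.length) if r.length >= 15 else "out_of_range",
            "position_group": classify_position(r.rel_pos),
        }
        for r in introns
    ]
    columns = [
        "intron_id", "gene_id", "index", "contig", "strand", "start", "end",
        "length", "gc", "rel_pos", "donor", "acceptor", "canonical",
        "length_group", "position_group",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_intron_bed(introns: list[IntronRecord], path: str | Path) -> None:
    """Write introns as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for r in introns:
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.intron_id}\t0\t{r.strand}\n")


def read_intron_bed(path: str | Path) -> list[IntronRecord]:
    """Read a BED6 of introns back into (coordinate-only) records."""
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _score, strand = line.rstrip("\n").split("\t")[:6]
            gene_id, _, idx = name.rpartition(".i")
            records.append(
                IntronRecord(
                    intron_id=name,
                    gene_id=gene_id,
                    index=int(idx) if idx.isdigit() else 0,
                    contig=contig,
                    strand=strand,
                    start=int(start) + 1,
                    end=int(end),
                )
            )
    return records


def intron_codon_positions(gene: GeneModel) -> list[tuple[int, int, int]]:
    """Intron junction positions in protein coordinates.

    Returns (intron_index, residues_upstream, phase) per intron, where
    residues_upstream counts complete codons 5' of the junction and phase is
    the junction offset within the interrupted codon (0/1/2). Assumes the
    representative model's exons are CDS (first codon at the transcript
    start), which holds for the cohorts this pipeline consumes.
    """
    positions = []
    cum = 0
    for i, (s, e) in enumerate(gene.exons[:-1], start=1):
        cum += e - s + 1
        positions.append((i, cum // 3, cum % 3))
    return positions


def annotate_genome(gtf: str | Path, fasta, species: str = "") -> tuple[dict[str, GeneModel], list[IntronRecord]]:
    """Run the full annotation stage: GTF + genome -> gene models + introns."""
    genes = read_gtf(gtf, species=species)
    introns: list[IntronRecord] = []
    for gene in genes.values():
        introns.extend(extract_introns(gene, fasta))
    return genes, introns
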