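"""Gene models, region partitions and isoform-aware k-mer indexing.

Coordinates are 0-based half-open internally; GTF input is converted from
1-based inclusive on read and back on write.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REGION_LABELS = ("five_utr", "cds", "three_utr", "intron", "ambiguous")

# integer codes used in the per-base collapse
_UNCOVERED = 0
_CODE = {"five_utr": 1, "cds": 2, "three_utr": 3, "intron": 4, "ambiguous": 5}
_LABEL = {v: k for k, v in _CODE.items()}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript: sorted, non-overlapping exons plus an optional CDS span."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in self.exons:
            if b <= a:
                raise ValueError(f"empty exon {a}-{b} in {self.transcript_id}")
        for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]):
            if a1 < b0:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} in {self.transcript_id}")
        if self.cds is not None:
            c0, c1 = self.cds
            if not (self.start <= c0 < c1 <= self.end):
                raise ValueError(f"CDS outside exon span in {self.transcript_id}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds is not None

    @property
    def mature_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def introns(self) -> List[Tuple[int, int]]:
        return [
            (b0, a1) for (_, b0), (a1, _) in zip(self.exons, self.exons[1:]) if a1 > b0
        ]

    def exonic_base_label(self, pos: int) -> str:
        """Structure label of an exonic genomic base (strand aware)."""
        if self.cds is None:
            return "ambiguous"
        c0, c1 = self.cds
        if c0 <= pos < c1:
            return "cds"
        if pos < c0:
            return "five_utr" if self.strand == "+" else "three_utr"
        return "three_utr" if self.strand == "+" else "five_utr"

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of each mature-transcript base, 5'->3'."""
        parts = [np.arange(a, b) for a, b in self.exons]
        coords = np.concatenate(parts)
        if self.strand == "-":
            coords = coords[::-1]
        return coords

    def mature_sequence(self, genome: "GenomeAccessor") -> str:
        seq = "".join(genome.fetch(self.chrom, a, b) for a, b in self.exons)
        if self.strand == "-":
            seq = reverse_complement(seq)
        return seq.upper()


@dataclass
class GeneModel:
    gene_id: str
    transcripts: List[TranscriptModel]

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def locus_span(self) -> Tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )

    @property
    def locus_length(self) -> int:
        a, b = self.locus_span
        return b - a

    @property
    def is_spliced(self) -> bool:
        return any(len(t.exons) >= 2 for t in self.transcripts)

    @property
    def is_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts)


@dataclass
class RegionPartition:
    """Unambiguous per-base structure labels over a gene locus.

    A base gets a non-ambiguous label only when every transcript covering it
    agrees on that label; disagreement (including exon-vs-intron conflicts)
    and non-coding exonic bases collapse to ``ambiguous``.
    """

    gene_id: str
    locus_span: Tuple[int, int]
    regions: List[Tuple[Tuple[int, int], str]]
    label_lengths: Dict[str, int] = field(default_factory=dict)

    def label_at(self, pos: int) -> Optional[str]:
        for (a, b), lab in self.regions:
            if a <= pos < b:
                return lab
        return None

    def segments(self, label: str) -> List[Tuple[int, int]]:
        return [iv for iv, lab in self.regions if lab == label]


@dataclass
class ExpressionSummary:
    gene_id: str
    rpkm_control: float
    expressed: bool


class GenomeAccessor:
    """Thin wrapper over an indexed FASTA (or an in-memory dict of contigs)."""

    def __init__(self, source) -> None:
        self._source = source

    @classmethod
    def from_fasta(cls, path) -> "GenomeAccessor":
        from pyfaidx import Fasta

        return cls(Fasta(str(path), as_raw=True, sequence_always_upper=True))

    @classmethod
    def from_dict(cls, contigs: Dict[str, str]) -> "GenomeAccessor":
        return cls({k: v.upper() for k, v in contigs.items()})

    def __contains__(self, contig: str) -> bool:
        if isinstance(self._source, dict):
            return contig in self._source
        return contig in self._source.keys()

    def fetch(self, contig: str, start: int, end: int) -> str:
        if contig not in self:
            raise KeyError(f"contig {contig!r} not present in genome")
        return str(self._source[contig][start:end]).upper()


def load_annotation(gtf_path, fasta_path) -> Tuple[List[GeneModel], GenomeAccessor]:
    """Read exon/CDS features from a GTF and pair them with an indexed FASTA.

    Genes whose transcripts disagree on strand are rejected with a warning;
    features on contigs absent from the FASTA are a hard error.
    """
    import gffutils

    genome = GenomeAccessor.from_fasta(fasta_path)
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: Dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            if feat.seqid not in genome:
                raise ValueError(
                    f"feature on contig {feat.seqid!r} missing from FASTA"
                )
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
            rec = exons.setdefault(
                tid,
                {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": [], "cds": []},
            )
            # GTF is 1-based inclusive
            iv = (feat.start - 1, feat.end)
            rec["exons" if ftype == "exon" else "cds"].append(iv)

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for tid, rec in exons.items():
        if not rec["exons"]:
            raise ValueError(f"transcript {tid} has CDS but no exons")
        cds = None
        if rec["cds"]:
            cds = (min(a for a, _ in rec["cds"]), max(b for _, b in rec["cds"]))
        tm = TranscriptModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
            cds=cds,
        )
        by_gene.setdefault(rec["gene_id"], []).append(tm)

    genes: List[GeneModel] = []
    for gid, tms in sorted(by_gene.items()):
        strands = {t.strand for t in tms}
        chroms = {t.chrom for t in tms}
        if len(strands) > 1 or len(chroms) > 1:
            log.warning("rejecting mixed-strand/contig gene %s", gid)
            continue
        genes.append(GeneModel(gene_id=gid, transcripts=sorted(tms, key=lambda t: t.transcript_id)))
    return genes, genome


def collapse_regions(gene: GeneModel) -> RegionPartition:
    """Collapse all transcripts of a gene into unambiguous structure regions."""
    lo, hi = gene.locus_span
    n = hi - lo
    codes = np.zeros(n, dtype=np.int8)  # 0 = uncovered
    for t in gene.transcripts:
        tcodes = np.zeros(n, dtype=np.int8)
        span = slice(t.start - lo, t.end - lo)
        tcodes[span] = _CODE["intron"]
        for a, b in t.exons:
            if t.cds is None:
                tcodes[a - lo: b - lo] = _CODE["ambiguous"]
            else:
                c0, c1 = t.cds
                e0, e1 = a - lo, b - lo
                g = np.arange(a, b)
                lab = np.full(b - a, _CODE["cds"], dtype=np.int8)
                if t.strand == "+":
                    lab[g < c0] = _CODE["five_utr"]
                    lab[g >= c1] = _CODE["three_utr"]
                else:
                    lab[g < c0] = _CODE["three_utr"]
                    lab[g >= c1] = _CODE["five_utr"]
                tcodes[e0:e1] = lab
        covered = tcodes != _UNCOVERED
        newly = covered & (codes == _UNCOVERED)
        codes[newly] = tcodes[newly]
        conflict = covered & (codes != _UNCOVERED) & (codes != tcodes)
        codes[conflict] = _CODE["ambiguous"]
    codes[codes == _UNCOVERED] = _CODE["ambiguous"]

    regions: List[Tuple[Tuple[int, int], str]] = []
    boundaries = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for s, e in zip(starts, ends):
        regions.append(((int(s) + lo, int(e) + lo), _LABEL[int(codes[s])]))
    lengths = {lab: 0 for lab in REGION_LABELS}
    for (a, b), lab in regions:
        lengths[lab] += b - a
    return RegionPartition(gene.gene_id, (lo, hi), regions, lengths)


@dataclass
class KmerLocation:
    gene_id: str
    kmer: str
    gpos: int  # genomic coordinate of the 5'-most transcript base
    junction: Tuple[int, ...]  # genomic exon-boundary signature, () if contiguous


@dataclass
class KmerIndex:
    k: int
    locations: Dict[str, List[KmerLocation]]  # gene_id -> unique locations

    def gene_kmers(self, gene_id: str) -> set:
        return {loc.kmer for loc in self.locations.get(gene_id, [])}

    def genes_with_kmer(self) -> Dict[str, set]:
        """kmer -> set of gene_ids containing it."""
        out: Dict[str, set] = {}
        for gid, locs in self.locations.items():
            for loc in locs:
                out.setdefault(loc.kmer, set()).add(gid)
        return out


def build_kmer_index(
    genes: Sequence[GeneModel], genome: GenomeAccessor, k: int = 7
) -> KmerIndex:
    """Unique k-mer locations per gene across all transcripts.

    A location is keyed by the genomic coordinate of its first (5'-most in
    transcript orientation) base plus a junction signature, so isoforms
    sharing a junction contribute the location once. Windows containing a
    non-ACGT base are dropped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    index: Dict[str, List[KmerLocation]] = {}
    for gene in genes:
        seen = set()
        locs: List[KmerLocation] = []
        any_window = False
        for t in gene.transcripts:
            seq = t.mature_sequence(genome)
            if len(seq) < k:
                continue
            any_window = True
            coords = t.genomic_positions()
            # exon boundary positions in transcript coordinates (5'->3')
            cum, bounds = 0, set()
            exon_order = t.exons if t.strand == "+" else t.exons[::-1]
            for a, b in exon_order[:-1]:
                cum += b - a
                bounds.add(cum)
            for i in range(len(seq) - k + 1):
                kmer = seq[i: i + k]
                if any(c not in "ACGT" for c in kmer):
                    continue
                junc = tuple(
                    int(coords[j]) for j in range(i + 1, i + k) if j in bounds
                )
                key = (int(coords[i]), junc)
                if key in seen:
                    continue
                seen.add(key)
                locs.append(KmerLocation(gene.gene_id, kmer, key[0], junc))
        if not any_window:
            log.warning("k=%d exceeds longest transcript of %s", k, gene.gene_id)
        index[gene.gene_id] = locs
    return KmerIndex(k=k, locations=index)


def expression_summary(
    counts: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    genes: Sequence[GeneModel],
    threshold: float = 1.0,
) -> List[ExpressionSummary]:
    """Mean control-sample RPKM per gene and the expressed flag.

    RPKM = count / (locus length in kb x mapped reads in sample / 1e6),
    averaged over control samples.
    """
    ctrl = sample_sheet.loc[sample_sheet["is_control"], "sample_id"].tolist()
    if not ctrl:
        raise ValueError("no control samples in sample sheet")
    sub = counts[ctrl]
    totals = sub.sum(axis=0).astype(float)
    if (totals <= 0).any():
        raise ValueError("control sample with zero total mapped reads")
    lengths = {g.gene_id: g.locus_length for g in genes}
    out = []
    for g in genes:
        L_kb = lengths[g.gene_id] / 1000.0
        if L_kb <= 0:
            raise ValueError(f"gene {g.gene_id} has non-positive locus length")
        if g.gene_id in sub.index:
            row = sub.loc[g.gene_id].astype(float)
            rpkm = float((row / (L_kb * totals / 1e6)).mean())
        else:
            rpkm = 0.0
        out.append(ExpressionSummary(g.gene_id, rpkm, rpkm >= threshold))
    return out


def write_partition_bed(partitions: Iterable[RegionPartition], chrom_of: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for part in partitions:
            for (a, b), lab in part.regions:
                fh.write(
                    f"{chrom_of[part.gene_id]}\t{a}\t{b}\t{lab}\t{b - a}\t.\n"
                )
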