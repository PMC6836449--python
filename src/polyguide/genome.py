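"""Genome and annotation model: FASTA/GFF3 loading and region classification.

The four-way region classification (coding / promoter / other_genic /
intergenic) drives both on-target guide selection and the tiered
off-target search depth, so it is built once per genome and treated as a
total function over every contig position.

Coordinate convention: everything internal is 0-based half-open.  GFF3
comes in 1-based closed and is converted on load; BED exports are 0-based
half-open as the format requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from ._seq import encode, normalize
from .errors import (
    CdsOutsideExonError,
    DuplicateContigError,
    EmptyFileError,
    FeatureBoundsError,
    MissingFileError,
    OrphanFeatureError,
    OutOfBoundsError,
    UnknownContigError,
)

logger = logging.getLogger(__name__)

#: region labels in increasing priority; on overlap the highest code wins.
REGION_LABELS = ("intergenic", "other_genic", "promoter", "coding")
_LABEL_CODE = {name: i for i, name in enumerate(REGION_LABELS)}

DEFAULT_PROMOTER_LENGTH = 2000


@dataclass
class GenomeSequence:
    """An ordered collection of uppercased contig sequences."""

    contigs: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if len(seq) < 1:
                raise EmptyFileError(f"contig {cid!r} has empty sequence")

    @property
    def contig_ids(self) -> list[str]:
        return list(self.contigs)

    def length(self, contig_id: str) -> int:
        return len(self.contigs[contig_id])

    def encoded(self, contig_id: str) -> np.ndarray:
        """uint8 encoding of a contig, cached."""
        arr = self._encoded.get(contig_id)
        if arr is None:
            arr = encode(self.contigs[contig_id])
            self._encoded[contig_id] = arr
        return arr


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    exons: tuple[tuple[int, int], ...]  # merged, sorted, 0-based half-open
    cds: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    span: tuple[int, int]
    isoforms: tuple[Isoform, ...]

    def cds_union(self) -> list[tuple[int, int]]:
        return merge_intervals(iv for iso in self.isoforms for iv in iso.cds)

    def first_cds_base(self) -> int | None:
        """Start-codon position: lowest CDS coordinate on '+', highest on '-'."""
        ivs = self.cds_union()
        if not ivs:
            return None
        return ivs[0][0] if self.strand == "+" else ivs[-1][1] - 1


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _contains(union: list[tuple[int, int]], s: int, e: int) -> bool:
    """True if [s, e) is fully inside the merged interval union."""
    return any(us <= s and e <= ue for us, ue in union)


def load_genome(fasta_path: str | Path) -> GenomeSequence:
    """Load a (multi-)FASTA file into memory, uppercasing sequences.

    Raises distinct errors for a missing path, an empty file and
    duplicated contig ids.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise MissingFileError(f"FASTA file not found: {path}")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise DuplicateContigError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = normalize(str(rec.seq))
    if not contigs:
        raise EmptyFileError(f"no FASTA records in {path}")
    return GenomeSequence(contigs)


def load_annotation(gff3_path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse a GFF3 gene/mRNA/exon/CDS hierarchy into validated GeneModels.

    Coordinates are converted from GFF3's 1-based closed convention to
    0-based half-open.  Validation failures raise distinct subclasses of
    AnnotationError: unknown contig, feature beyond contig end, CDS not
    contained in its isoform's exons, and parentless mRNA/exon/CDS.
    """
    path = Path(gff3_path)
    if not path.exists():
        raise MissingFileError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )

    gene_ids = {f.id for f in db.features_of_type("gene")}

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        if gene.seqid not in genome.contigs:
            raise UnknownContigError(
                f"gene {gene.id} on unknown contig {gene.seqid!r}"
            )
        clen = genome.length(gene.seqid)
        if gene.end > clen or gene.start < 1:
            raise FeatureBoundsError(
                f"gene {gene.id} [{gene.start},{gene.end}] exceeds contig "
                f"{gene.seqid} length {clen}"
            )
        isoforms: list[Isoform] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons: list[tuple[int, int]] = []
            cds: list[tuple[int, int]] = []
            for feat in db.children(mrna, order_by="start"):
                if feat.featuretype not in ("exon", "CDS"):
                    continue
                if feat.end > clen or feat.start < 1:
                    raise FeatureBoundsError(
                        f"{feat.featuretype} of {mrna.id} "
                        f"[{feat.start},{feat.end}] exceeds contig length {clen}"
                    )
                iv = (feat.start - 1, feat.end)
                (exons if feat.featuretype == "exon" else cds).append(iv)
            exon_union = merge_intervals(exons)
            cds_sorted = sorted(cds)
            for s, e in cds_sorted:
                if not _contains(exon_union, s, e):
                    raise CdsOutsideExonError(
                        f"CDS [{s},{e}) of isoform {mrna.id} not contained in "
                        "its exon union"
                    )
            isoforms.append(
                Isoform(mrna.id, tuple(exon_union), tuple(cds_sorted))
            )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig_id=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                span=(gene.start - 1, gene.end),
                isoforms=tuple(isoforms),
            )
        )

    # orphan check: every mRNA must name a known gene parent; every exon/CDS
    # an mRNA parent.
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents or not any(p in gene_ids for p in parents):
            raise OrphanFeatureError(f"mRNA {mrna.id} has no gene parent")
    mrna_ids = {f.id for f in db.features_of_type("mRNA")}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            parents = feat.attributes.get("Parent", [])
            if not parents or not any(p in mrna_ids for p in parents):
                raise OrphanFeatureError(
                    f"{ftype} at {feat.seqid}:{feat.start} has no mRNA parent"
                )
    return genes


@dataclass
class RegionMap:
    """Total position → region-label function for every contig.

    ``labels[contig]`` is a uint8 array with codes indexing REGION_LABELS;
    because a position's code is the maximum over all features covering
    it, the priority coding > promoter > other_genic > intergenic holds
    structurally.  ``owners[contig]`` is an IntervalTree whose payloads
    are (gene_id, kind) with kind in {"coding", "promoter"}, used for
    on-target gene assignment and homoeologue-hit diversion.
    """

    labels: dict[str, np.ndarray]
    owners: dict[str, IntervalTree]
    promoter_length: int = DEFAULT_PROMOTER_LENGTH

    def classify(self, contig_id: str, position: int) -> str:
        arr = self.labels.get(contig_id)
        if arr is None:
            raise OutOfBoundsError(f"unknown contig {contig_id!r}")
        if position < 0 or position >= arr.shape[0]:
            raise OutOfBoundsError(
                f"position {position} outside contig {contig_id} "
                f"[0,{arr.shape[0]})"
            )
        return REGION_LABELS[arr[position]]

    def owner_genes(self, contig_id: str, position: int) -> list[tuple[str, str]]:
        """(gene_id, kind) pairs whose coding/promoter interval covers position."""
        tree = self.owners.get(contig_id)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree[position]))

    def intervals(self, label: str) -> dict[str, list[tuple[int, int]]]:
        """Maximal runs of a given label per contig (for BED export and fixtures)."""
        code = _LABEL_CODE[label]
        out: dict[str, list[tuple[int, int]]] = {}
        for cid, arr in self.labels.items():
            mask = arr == code
            if not mask.any():
                out[cid] = []
                continue
            d = np.diff(mask.astype(np.int8))
            starts = list(np.nonzero(d == 1)[0] + 1)
            ends = list(np.nonzero(d == -1)[0] + 1)
            if mask[0]:
                starts.insert(0, 0)
            if mask[-1]:
                ends.append(arr.shape[0])
            out[cid] = list(zip(starts, ends))
        return out

    def to_bed(self) -> str:
        """4-track BED: one row per maximal same-label run, name = label."""
        lines = []
        for label in REGION_LABELS:
            for cid, ivs in self.intervals(label).items():
                for s, e in ivs:
                    lines.append(f"{cid}\t{s}\t{e}\t{label}")
        lines.sort(key=lambda l: (l.split("\t")[0], int(l.split("\t")[1])))
        return "\n".join(lines) + "\n"


def promoter_interval(
    gene: GeneModel, contig_length: int, promoter_length: int
) -> tuple[int, int] | None:
    """Strand-aware promoter window upstream of the start codon, clipped.

    Upstream means lower coordinates for '+' genes and higher for '-';
    genes without CDS have no start codon hence no promoter.
    """
    anchor = gene.first_cds_base()
    if anchor is None:
        return None
    if gene.strand == "+":
        s, e = max(0, anchor - promoter_length), anchor
    else:
        s, e = anchor + 1, min(contig_length, anchor + 1 + promoter_length)
    return (s, e) if e > s else None


def build_region_map(
    genes: Iterable[GeneModel],
    genome: GenomeSequence,
    promoter_length: int = DEFAULT_PROMOTER_LENGTH,
) -> RegionMap:
    """Partition every contig into coding/promoter/other_genic/intergenic.

    coding = union of CDS across all isoforms of all genes; promoter =
    up to ``promoter_length`` bases strand-wise upstream of each gene's
    first CDS base; other_genic = gene bodies (introns + UTRs) minus the
    two above; intergenic = the rest.  Overlaps resolve by priority
    coding > promoter > other_genic > intergenic.
    """
    labels = {
        cid: np.zeros(genome.length(cid), dtype=np.uint8)
        for cid in genome.contigs
    }
    owners = {cid: IntervalTree() for cid in genome.contigs}

    def paint(cid: str, s: int, e: int, label: str) -> None:
        code = _LABEL_CODE[label]
        arr = labels[cid]
        np.maximum(arr[s:e], code, out=arr[s:e])

    genes = list(genes)
    for gene in genes:
        paint(gene.contig_id, gene.span[0], gene.span[1], "other_genic")
    for gene in genes:
        clen = genome.length(gene.contig_id)
        prom = promoter_interval(gene, clen, promoter_length)
        if prom is None:
            logger.warning(
                "gene %s has no CDS in any isoform; contributes other_genic "
                "only (no promoter, no coding)", gene.gene_id
            )
            continue
        paint(gene.contig_id, prom[0], prom[1], "promoter")
        owners[gene.contig_id][prom[0]:prom[1]] = (gene.gene_id, "promoter")
    for gene in genes:
        for s, e in gene.cds_union():
            paint(gene.contig_id, s, e, "coding")
            owners[gene.contig_id][s:e] = (gene.gene_id, "coding")
    return RegionMap(labels=labels, owners=owners, promoter_length=promoter_length)


def classify_position(region_map: RegionMap, contig_id: str, position: int) -> str:
    """Label of a single position; raises OutOfBoundsError outside the contig."""
    return region_map.classify(contig_id, position)
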