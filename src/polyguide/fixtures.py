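"""Deterministic synthetic genomes for desk-scale testing.

Generates uniform-background toy genomes with annotated multi-exon
genes (optional alternative isoforms), homoeolog triplets at a
controlled per-base divergence, and planted guide/off-target pairs at
exact Hamming distances in chosen genomic regions.  Planted guides are
rejection-sampled to be far (> the deepest search cap) from every
background 20-mer window on either strand, so the emitted truth table
is exact: the pipeline must recover precisely the planted hits within
the caps and nothing else.

Same spec + seed → byte-identical FASTA/GFF3/TSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._seq import BASES, encode, revcomp
from .errors import FixtureError
from .genome import (
    GeneModel,
    GenomeSequence,
    Isoform,
    RegionMap,
    build_region_map,
)
from .offtarget import hamming20
from .pam import FOOTPRINT, PAM_CLASSES, PROTOSPACER_LEN

logger = logging.getLogger(__name__)

_MARGIN = 500  # intergenic spacer in front of every gene slot


@dataclass(frozen=True)
class PlantSpec:
    """One planted off-target: a copy of guide ``guide_index``'s
    protospacer mutated at exactly ``k`` positions, written into the
    requested region with a PAM of the requested class."""

    guide_index: int
    k: int
    region: str
    pam_class: str = "NGG"


@dataclass(frozen=True)
class FixtureSpec:
    n_contigs: int = 1
    contig_length: int = 60_000
    n_genes: int = 10
    isoforms_per_gene: int = 1
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 200
    utr_length: int = 60
    promoter_length: int = 2000
    n_planted_guides: int = 0
    plants: tuple[PlantSpec, ...] = ()
    n_homoeolog_groups: int = 0  # groups of 3 copies of the first group genes
    homoeolog_divergence: float = 0.0
    seed: int = 0

    def n_guides(self) -> int:
        wanted = max((p.guide_index + 1 for p in self.plants), default=0)
        return max(self.n_planted_guides, wanted)


@dataclass
class Fixture:
    """In-memory fixture plus text serialisations of every artefact."""

    spec: FixtureSpec
    genome: GenomeSequence
    genes: list[GeneModel]
    region_map: RegionMap
    guide_seqs: list[str]  # planted protospacers, by guide index
    truth: list[dict]      # one row per planted guide or off-target
    groups: dict[str, str]  # gene_id -> group_id

    @property
    def fasta_text(self) -> str:
        lines = []
        for cid, seq in self.genome.contigs.items():
            lines.append(f">{cid}")
            for i in range(0, len(seq), 70):
                lines.append(seq[i : i + 70])
        return "\n".join(lines) + "\n"

    @property
    def gff3_text(self) -> str:
        lines = ["##gff-version 3"]
        for g in self.genes:
            s, e = g.span
            lines.append(
                f"{g.contig_id}\tpolyguide\tgene\t{s + 1}\t{e}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}"
            )
            for iso in g.isoforms:
                ms = min(x[0] for x in iso.exons)
                me = max(x[1] for x in iso.exons)
                lines.append(
                    f"{g.contig_id}\tpolyguide\tmRNA\t{ms + 1}\t{me}\t.\t"
                    f"{g.strand}\t.\tID={iso.isoform_id};Parent={g.gene_id}"
                )
                for xs, xe in iso.exons:
                    lines.append(
                        f"{g.contig_id}\tpolyguide\texon\t{xs + 1}\t{xe}\t.\t"
                        f"{g.strand}\t.\tParent={iso.isoform_id}"
                    )
                for cs, ce in iso.cds:
                    lines.append(
                        f"{g.contig_id}\tpolyguide\tCDS\t{cs + 1}\t{ce}\t.\t"
                        f"{g.strand}\t0\tParent={iso.isoform_id}"
                    )
        return "\n".join(lines) + "\n"

    @property
    def groups_text(self) -> str:
        lines = ["# homoeolog groups", "gene_id\tgroup_id"]
        for gid in sorted(self.groups):
            lines.append(f"{gid}\t{self.groups[gid]}")
        return "\n".join(lines) + "\n"

    @property
    def truth_text(self) -> str:
        cols = ["kind", "guide_index", "contig", "footprint_start", "strand",
                "region", "pam_class", "k", "protospacer", "pam"]
        lines = ["\t".join(cols)]
        for row in self.truth:
            lines.append("\t".join(str(row[c]) for c in cols))
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "truth": out / "truth.tsv",
            "groups": out / "groups.tsv",
        }
        paths["fasta"].write_text(self.fasta_text)
        paths["gff3"].write_text(self.gff3_text)
        paths["truth"].write_text(self.truth_text)
        paths["groups"].write_text(self.groups_text)
        return paths


def _isoform_intervals(
    exons: list[tuple[int, int]], utr: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exon list plus CDS list (exons trimmed by the UTR at both ends)."""
    cds = [list(iv) for iv in exons]
    cds[0][0] += utr
    cds[-1][1] -= utr
    cds_ivs = [(s, e) for s, e in cds if e > s]
    if not cds_ivs:
        raise FixtureError("UTR length leaves no CDS in an exon layout")
    return exons, cds_ivs


def _layout_genes(spec: FixtureSpec) -> list[GeneModel]:
    """Place equal-geometry genes sequentially on each contig."""
    span_len = (
        spec.exons_per_gene * spec.exon_length
        + (spec.exons_per_gene - 1) * spec.intron_length
    )
    slot = spec.promoter_length + _MARGIN + span_len
    per_contig = [spec.n_genes // spec.n_contigs] * spec.n_contigs
    for i in range(spec.n_genes % spec.n_contigs):
        per_contig[i] += 1
    genes: list[GeneModel] = []
    gi = 0
    grouped = set(range(3 * spec.n_homoeolog_groups))
    for ci in range(spec.n_contigs):
        needed = per_contig[ci] * slot + spec.promoter_length + _MARGIN
        if needed > spec.contig_length:
            raise FixtureError(
                f"contig_length {spec.contig_length} too small for "
                f"{per_contig[ci]} genes (need {needed})"
            )
        cursor = 0
        for _ in range(per_contig[ci]):
            start = cursor + spec.promoter_length + _MARGIN
            exons = []
            pos = start
            for _e in range(spec.exons_per_gene):
                exons.append((pos, pos + spec.exon_length))
                pos += spec.exon_length + spec.intron_length
            end = exons[-1][1]
            # homoeolog-group members share a strand so blocks are copyable
            strand = "+" if (gi in grouped or gi % 2 == 0) else "-"
            isoforms = []
            for iso_i in range(spec.isoforms_per_gene):
                if iso_i == 0 or len(exons) < 3:
                    iso_exons = list(exons)
                else:
                    drop = len(exons) // 2  # alternative isoform skips an exon
                    iso_exons = exons[:drop] + exons[drop + 1 :]
                ex, cds = _isoform_intervals(iso_exons, spec.utr_length)
                isoforms.append(
                    Isoform(f"gene{gi:03d}.{iso_i + 1}", tuple(ex), tuple(cds))
                )
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:03d}",
                    contig_id=f"contig{ci + 1}",
                    strand=strand,
                    span=(start, end),
                    isoforms=tuple(isoforms),
                )
            )
            gi += 1
            cursor = start + span_len
    return genes


def _min_hamming_to_genome(guide: str, contigs: list[bytearray]) -> int:
    """Minimum Hamming distance from ``guide`` to any 20-mer window on
    either strand of the current (partially built) genome."""
    g = encode(guide)
    grc = encode(revcomp(guide))
    best = PROTOSPACER_LEN
    for ba in contigs:
        arr = encode(ba.decode("ascii"))
        if arr.shape[0] < PROTOSPACER_LEN:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, PROTOSPACER_LEN)
        for q in (g, grc):
            mism = (win != q).sum(axis=1)
            best = min(best, int(mism.min()))
            if best == 0:
                return 0
    return best


def _mutate(proto: str, k: int, rng: np.random.Generator) -> str:
    """Substitute exactly k distinct positions, each to a different base."""
    positions = rng.choice(PROTOSPACER_LEN, size=k, replace=False)
    out = list(proto)
    for p in positions:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(0, 3)]
    return "".join(out)


def _realize_pam(pam_class: str, rng: np.random.Generator) -> str:
    suffix = PAM_CLASSES[pam_class]
    return BASES[rng.integers(0, 4)] + suffix


class _Occupied:
    """Per-contig list of reserved intervals (planted features)."""

    def __init__(self) -> None:
        self.by_contig: dict[str, list[tuple[int, int]]] = {}

    def overlaps(self, cid: str, s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in self.by_contig.get(cid, []))

    def add(self, cid: str, s: int, e: int) -> None:
        self.by_contig.setdefault(cid, []).append((s, e))


def _place_in_region(
    region_map: RegionMap,
    label: str,
    width: int,
    occupied: _Occupied,
) -> tuple[str, int]:
    """Leftmost free slot of ``width`` fully inside a run of ``label``.

    Deterministic sequential placement keeps fixtures reproducible
    without extra state.
    """
    pad = 5
    for cid, ivs in region_map.intervals(label).items():
        for s, e in ivs:
            pos = s + pad
            while pos + width + pad <= e:
                if not occupied.overlaps(cid, pos - pad, pos + width + pad):
                    occupied.add(cid, pos, pos + width)
                    return cid, pos
                pos += pad
    raise FixtureError(f"no room to plant a {width}-nt feature in {label!r}")


def make_homoeolog_triplet(
    base_seq: str,
    divergence: float,
    seed: int,
    gene_ids: tuple[str, str, str] = ("gene_A", "gene_B", "gene_C"),
) -> tuple[list[str], dict[str, str]]:
    """Three homoeologous copies of a sequence plus their group mapping.

    The first copy is the base sequence; the others carry independent
    substitutions at the given per-base rate.  Substitution positions
    are nested across rates for a fixed seed (position i is mutated iff
    its uniform draw < rate), so divergence is monotone in the rate.
    """
    if not 0.0 <= divergence <= 0.2:
        raise FixtureError("divergence rate must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    copies = [base_seq]
    for _ in range(2):
        u = rng.random(len(base_seq))
        repl = rng.integers(0, 3, len(base_seq))
        chars = list(base_seq)
        for i in np.nonzero(u < divergence)[0]:
            alts = [b for b in BASES if b != chars[i]]
            chars[i] = alts[repl[i]]
        copies.append("".join(chars))
    groups = {gid: "group1" for gid in gene_ids}
    return copies, groups


def make_toy_genome(spec: FixtureSpec) -> Fixture:
    """Generate genome + annotation + exact truth table per the spec."""
    rng = np.random.default_rng(spec.seed)
    genes = _layout_genes(spec)

    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    contigs = [
        bytearray(base_codes[rng.integers(0, 4, spec.contig_length)].tobytes())
        for _ in range(spec.n_contigs)
    ]
    contig_ids = [f"contig{i + 1}" for i in range(spec.n_contigs)]
    cindex = {cid: i for i, cid in enumerate(contig_ids)}

    stub = GenomeSequence({cid: "A" * spec.contig_length for cid in contig_ids})
    region_map = build_region_map(genes, stub, spec.promoter_length)

    occupied = _Occupied()
    truth: list[dict] = []
    guide_seqs: list[str] = []

    # --- planted on-target guides (unique in the background) -------------
    gene_pool = [
        g for g in genes
        if spec.n_homoeolog_groups == 0
        or int(g.gene_id[4:]) >= 3 * spec.n_homoeolog_groups
        or int(g.gene_id[4:]) % 3 == 0  # first member of each triplet
    ]
    max_cap = 6
    for gi in range(spec.n_guides()):
        gene = gene_pool[gi % len(gene_pool)]
        for _try in range(200):
            cand = base_codes[rng.integers(0, 4, PROTOSPACER_LEN)].tobytes().decode()
            if any(
                hamming20(cand, prev) < 15 for prev in guide_seqs
            ):
                continue
            if _min_hamming_to_genome(cand, contigs) > max_cap:
                break
        else:
            raise FixtureError("could not sample a unique planted guide")
        cds0 = gene.isoforms[0].cds[0]
        pos = cds0[0] + 10 + 30 * (gi // len(gene_pool))
        if pos + FOOTPRINT + 5 > cds0[1]:
            raise FixtureError(
                f"first CDS of {gene.gene_id} too small for planted guides"
            )
        ba = contigs[cindex[gene.contig_id]]
        pam = "TGG"
        ba[pos : pos + FOOTPRINT] = (cand + pam).encode("ascii")
        occupied.add(gene.contig_id, pos - 5, pos + FOOTPRINT + 5)
        guide_seqs.append(cand)
        truth.append(dict(
            kind="guide", guide_index=gi, contig=gene.contig_id,
            footprint_start=pos, strand="+", region="coding",
            pam_class="NGG", k=0, protospacer=cand, pam=pam,
        ))

    # --- homoeolog triplet copies ----------------------------------------
    groups: dict[str, str] = {}
    for grp in range(spec.n_homoeolog_groups):
        members = genes[3 * grp : 3 * grp + 3]
        if len(members) < 3:
            raise FixtureError("n_genes too small for the requested groups")
        src = members[0]
        flank = 30
        bs = src.span[0] - spec.promoter_length - flank
        be = src.span[1] + flank
        ba = contigs[cindex[src.contig_id]]
        block = ba[bs:be].decode("ascii")
        copies, _ = make_homoeolog_triplet(
            block, spec.homoeolog_divergence, seed=int(spec.seed) + 101 + grp
        )
        for m, copy in zip(members[1:], copies[1:]):
            shift = m.span[0] - src.span[0]
            mb = contigs[cindex[m.contig_id]]
            mb[bs + shift : be + shift] = copy.encode("ascii")
        for m in members:
            groups[m.gene_id] = f"group{grp + 1}"

    # --- planted off-targets ----------------------------------------------
    for pi, plant in enumerate(spec.plants):
        guide = guide_seqs[plant.guide_index]
        target = _mutate(guide, plant.k, rng)
        pam = _realize_pam(plant.pam_class, rng)
        cid, pos = _place_in_region(region_map, plant.region, FOOTPRINT, occupied)
        contigs[cindex[cid]][pos : pos + FOOTPRINT] = (target + pam).encode("ascii")
        truth.append(dict(
            kind="offtarget", guide_index=plant.guide_index, contig=cid,
            footprint_start=pos, strand="+", region=plant.region,
            pam_class=plant.pam_class, k=plant.k, protospacer=target, pam=pam,
        ))

    genome = GenomeSequence(
        {cid: contigs[i].decode("ascii") for i, cid in enumerate(contig_ids)}
    )
    final_map = build_region_map(genes, genome, spec.promoter_length)

    # post-hoc verification against the pipeline's own primitives
    for row in truth:
        realized = final_map.classify(row["contig"], row["footprint_start"])
        if realized != row["region"]:
            raise FixtureError(
                f"planted feature at {row['contig']}:{row['footprint_start']} "
                f"landed in {realized!r}, wanted {row['region']!r}"
            )
        if row["kind"] == "offtarget":
            d = hamming20(guide_seqs[row["guide_index"]], row["protospacer"])
            if d != row["k"]:
                raise FixtureError("planted Hamming distance drifted")

    return Fixture(
        spec=spec, genome=genome, genes=genes, region_map=final_map,
        guide_seqs=guide_seqs, truth=truth, groups=groups,
    )
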