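"""End-to-end orchestration: database build, gene queries and the
on-the-fly pasted-sequence mode.

A build runs the three-step workflow — (1) genome-wide PAM scanning,
(2) complete tiered-k off-target mapping, (3) on-target (rs2) and
off-target (CFD) scoring — and keeps everything in memory; persistence
is flat TSV exports plus a JSON manifest (inputs, checksums, config),
so two builds from identical inputs are byte-identical on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import InputError, UnknownGeneError, UsageError
from .genome import (
    GeneModel,
    GenomeSequence,
    RegionMap,
    build_region_map,
    load_annotation,
    load_genome,
)
from .offtarget import (
    KCapPolicy,
    OffTargetHit,
    SeedIndex,
    build_seed_index,
    find_offtargets,
    hits_to_tsv,
)
from .pam import (
    FOOTPRINT,
    OnTargetGuide,
    PamSite,
    PROTOSPACER_LEN,
    scan_pam_sites,
    select_on_targets,
    sites_to_bed,
)
from .ranking import (
    GuideReport,
    HomoeologGroups,
    aggregate_region_cfd,
    isoform_coverage,
    overall_score_default,
    overall_score_homoeolog,
    rank_guides,
    reports_to_tsv,
)
from .scoring import CfdTables, Rs2Model, cfd_score, load_cfd_tables, load_rs2_model
from ._seq import normalize, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BuildConfig:
    """Everything that determines a database build besides the inputs."""

    promoter_length: int = 2000
    pam_classes: tuple[str, ...] = ("NGG", "NAG", "NCG", "NGA")
    policy: KCapPolicy = field(default_factory=KCapPolicy)
    cfd_mismatch_path: str | None = None
    cfd_pam_path: str | None = None
    rs2_weights_path: str | None = None
    top: int = 10

    def to_dict(self) -> dict:
        return {
            "promoter_length": self.promoter_length,
            "pam_classes": list(self.pam_classes),
            "caps": {f"{g}:{r}": v for (g, r), v in self.policy.caps.items()},
            "early_stop_threshold": self.policy.early_stop_threshold,
            "early_stop_enabled": self.policy.early_stop_enabled,
            "cfd_mismatch_path": self.cfd_mismatch_path,
            "cfd_pam_path": self.cfd_pam_path,
            "rs2_weights_path": self.rs2_weights_path,
            "top": self.top,
        }


@dataclass
class GuideDatabase:
    genome: GenomeSequence
    genes: dict[str, GeneModel]
    region_map: RegionMap
    sites: list[PamSite]
    index: SeedIndex
    guides: list[OnTargetGuide]
    hits: dict[str, list[OffTargetHit]]  # guide_id -> hits
    config: BuildConfig
    tables: CfdTables
    rs2_model: Rs2Model
    provenance: dict = field(default_factory=dict)

    def guides_of_gene(self, gene_id: str) -> list[OnTargetGuide]:
        return [g for g in self.guides if g.gene_id == gene_id]


def _score_hits(
    hits: list[OffTargetHit], guide20: str, tables: CfdTables
) -> None:
    for h in hits:
        h.cfd = cfd_score(guide20, h.site.protospacer, h.site.pam, tables)


def build_database(
    genome: str | Path | GenomeSequence,
    annotation: str | Path | list[GeneModel],
    config: BuildConfig | None = None,
) -> GuideDatabase:
    """Scan → select on-targets → index → tiered search → score."""
    config = config or BuildConfig()
    provenance: dict = {"polyguide_version": __version__}
    if not isinstance(genome, GenomeSequence):
        provenance["genome_path"] = str(genome)
        provenance["genome_sha256"] = _sha256_file(genome)
        genome = load_genome(genome)
    if not isinstance(annotation, list):
        provenance["gff3_path"] = str(annotation)
        provenance["gff3_sha256"] = _sha256_file(annotation)
        annotation = load_annotation(annotation, genome)
    genes = {g.gene_id: g for g in annotation}

    logger.info("build: region map (promoter length %d)", config.promoter_length)
    region_map = build_region_map(
        annotation, genome, promoter_length=config.promoter_length
    )
    tables = load_cfd_tables(config.cfd_mismatch_path, config.cfd_pam_path)
    rs2_model = load_rs2_model(config.rs2_weights_path)

    logger.info("build: scanning PAM sites")
    sites = scan_pam_sites(genome, region_map, config.pam_classes)
    guides = select_on_targets(sites, rs2_model.score, region_map, genome)
    index = build_seed_index(sites, config.policy)

    logger.info("build: tiered off-target search for %d guides", len(guides))
    hits: dict[str, list[OffTargetHit]] = {}
    for guide in guides:
        gh = find_offtargets(guide, index, config.policy)
        _score_hits(gh, guide.site.protospacer, tables)
        hits[guide.guide_id] = gh
    logger.info(
        "build: %d hits total", sum(len(v) for v in hits.values())
    )
    return GuideDatabase(
        genome=genome, genes=genes, region_map=region_map, sites=sites,
        index=index, guides=guides, hits=hits, config=config,
        tables=tables, rs2_model=rs2_model, provenance=provenance,
    )


def _make_report(
    db: GuideDatabase,
    guide: OnTargetGuide,
    partners: list[str] | None,
) -> GuideReport:
    hits = db.hits[guide.guide_id]
    summary, cfd_hmlgs = aggregate_region_cfd(
        hits,
        homoeolog_partners=partners,
        region_map=db.region_map if partners is not None else None,
    )
    if partners is not None:
        overall = overall_score_homoeolog(guide.rs2, summary, cfd_hmlgs)
    else:
        overall = overall_score_default(guide.rs2, summary)
    gene = db.genes.get(guide.gene_id)
    in_all, frac = isoform_coverage(guide, gene) if gene else (False, 0.0)
    by_k: dict[int, int] = {}
    for h in hits:
        if not h.self_hit:
            by_k[h.k] = by_k.get(h.k, 0) + 1
    return GuideReport(
        guide=guide, summary=summary, cfd_hmlgs=cfd_hmlgs, overall=overall,
        in_all_isoforms=in_all, isoform_fraction=frac, n_offtargets_by_k=by_k,
    )


def query_gene(
    db: GuideDatabase,
    gene_id: str,
    mode: str = "default",
    homoeologs: HomoeologGroups | None = None,
) -> list[GuideReport]:
    """Ranked reports for every guide targeting one gene.

    In homoeolog mode, hits falling in the gene's group partners'
    coding/promoter regions are rewarded rather than penalized.
    """
    if gene_id not in db.genes:
        raise UnknownGeneError(gene_id)
    if mode not in ("default", "homoeolog"):
        raise UsageError(f"unknown mode {mode!r}")
    partners: list[str] | None = None
    if mode == "homoeolog":
        if homoeologs is None:
            raise UsageError("homoeolog mode requires a homoeolog-group table")
        partners = homoeologs.partners(gene_id)
    reports = [
        _make_report(db, g, partners) for g in db.guides_of_gene(gene_id)
    ]
    return rank_guides(reports, top=db.config.top)


def _extract_sequence_guides(seq: str) -> list[tuple[str, str, int, str | None]]:
    """Canonical-PAM guides from a pasted sequence, both strands.

    Returns (protospacer, strand, offset, context30-or-None); offset is
    the footprint start within the pasted sequence's forward strand.
    """
    out = []
    L = len(seq)
    for f in range(0, L - FOOTPRINT + 1):
        fp = seq[f : f + FOOTPRINT]
        if "N" not in fp and fp[21:23] == "GG":
            ctx = None
            if f >= 4 and f + FOOTPRINT + 3 <= L:
                w = seq[f - 4 : f + FOOTPRINT + 3]
                ctx = w if "N" not in w else None
            out.append((fp[:PROTOSPACER_LEN], "+", f, ctx))
        if "N" not in fp and fp[0:2] == "CC":
            rc = revcomp(fp)
            ctx = None
            if f >= 3 and f + FOOTPRINT + 4 <= L:
                w = seq[f - 3 : f + FOOTPRINT + 4]
                ctx = revcomp(w) if "N" not in w else None
            out.append((rc[:PROTOSPACER_LEN], "-", f, ctx))
    return out


def query_sequence(
    seq: str,
    db: GuideDatabase,
    homoeolog: bool = False,
) -> list[GuideReport]:
    """On-the-fly mode: design guides for an arbitrary pasted sequence.

    Guides are extracted from the pasted sequence (canonical NGG only),
    off-targets are searched against the database genome under the same
    tiered caps, and the default overall score is applied.  Targeting a
    homoeolog set is not possible in this mode.  The first exact k=0
    genomic match of a guide (by contig, start, strand) is flagged as
    its presumptive on-target site and excluded from the maxima.
    """
    if homoeolog:
        raise UsageError(
            "targeting a set of homoeologs is not possible in sequence mode"
        )
    seq = normalize(seq)
    if len(seq) < FOOTPRINT:
        raise InputError(
            f"sequence must be at least {FOOTPRINT} nt (got {len(seq)})"
        )
    reports: list[GuideReport] = []
    for proto, strand, offset, ctx in _extract_sequence_guides(seq):
        hits = find_offtargets(proto, db.index, db.config.policy)
        exact = sorted(
            (h for h in hits if h.k == 0 and h.site.protospacer == proto),
            key=lambda h: h.site.key,
        )
        if exact:
            exact[0].self_hit = True
        _score_hits(hits, proto, db.tables)
        if ctx is not None:
            rs2 = db.rs2_model.score(ctx, False)
            no_context = False
        else:
            rs2, no_context = 0.0, True
        pseudo_site = PamSite(
            contig_id="query", strand=strand, protospacer_start=offset,
            footprint_start=offset, protospacer=proto,
            pam=seq[offset + 20 : offset + 23] if strand == "+"
            else revcomp(seq[offset : offset + 3]),
            pam_class="NGG", region="coding",
        )
        guide = OnTargetGuide(
            site=pseudo_site, gene_id="query", rs2=rs2,
            context30=ctx, no_context=no_context,
        )
        summary, _ = aggregate_region_cfd(hits)
        overall = overall_score_default(rs2, summary)
        by_k: dict[int, int] = {}
        for h in hits:
            if not h.self_hit:
                by_k[h.k] = by_k.get(h.k, 0) + 1
        rep = GuideReport(
            guide=guide, summary=summary, cfd_hmlgs=None, overall=overall,
            n_offtargets_by_k=by_k,
        )
        rep.hits = hits  # type: ignore[attr-defined] — kept for inspection
        reports.append(rep)
    return rank_guides(reports, top=db.config.top)


# ---------------------------------------------------------------------------
# persistence


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def guides_to_tsv(db: GuideDatabase) -> str:
    lines = ["guide_id\tgene_id\tcontig\tstrand\tprotospacer_start\t"
             "footprint_start\tprotospacer\tpam\tregion\trs2\tno_context"]
    for g in db.guides:
        s = g.site
        lines.append(
            f"{g.guide_id}\t{g.gene_id}\t{s.contig_id}\t{s.strand}\t"
            f"{s.protospacer_start}\t{s.footprint_start}\t{s.protospacer}\t"
            f"{s.pam}\t{s.region}\t{g.rs2:.6f}\t{int(g.no_context)}"
        )
    return "\n".join(lines) + "\n"


def save_database(db: GuideDatabase, out_dir: str | Path) -> None:
    """Write guides.tsv, offtargets.tsv, regions.bed and manifest.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    guides_tsv = guides_to_tsv(db)
    all_hits = [h for g in db.guides for h in db.hits[g.guide_id]]
    hits_tsv = hits_to_tsv(all_hits)
    regions_bed = db.region_map.to_bed()
    (out / "guides.tsv").write_text(guides_tsv)
    (out / "offtargets.tsv").write_text(hits_tsv)
    (out / "regions.bed").write_text(regions_bed)
    manifest = {
        "format": "polyguide-db/1",
        "provenance": db.provenance,
        "config": db.config.to_dict(),
        "checksums": {
            "guides.tsv": _sha256_text(guides_tsv),
            "offtargets.tsv": _sha256_text(hits_tsv),
            "regions.bed": _sha256_text(regions_bed),
        },
        "counts": {
            "contigs": len(db.genome.contigs),
            "genes": len(db.genes),
            "pam_sites": len(db.sites),
            "guides": len(db.guides),
            "offtarget_hits": len(all_hits),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def load_database(db_dir: str | Path) -> GuideDatabase:
    """Rebuild a database from the inputs recorded in its manifest.

    The build is deterministic, so re-running it reproduces the stored
    database exactly; the manifest checksums are verified to prove it.
    """
    db_dir = Path(db_dir)
    manifest = json.loads((db_dir / "manifest.json").read_text())
    prov = manifest["provenance"]
    cfg = manifest["config"]
    caps = {
        tuple(k.split(":")): v for k, v in cfg["caps"].items()
    }
    config = BuildConfig(
        promoter_length=cfg["promoter_length"],
        pam_classes=tuple(cfg["pam_classes"]),
        policy=KCapPolicy(
            caps=caps,
            early_stop_threshold=cfg["early_stop_threshold"],
            early_stop_enabled=cfg["early_stop_enabled"],
        ),
        cfd_mismatch_path=cfg["cfd_mismatch_path"],
        cfd_pam_path=cfg["cfd_pam_path"],
        rs2_weights_path=cfg["rs2_weights_path"],
        top=cfg["top"],
    )
    db = build_database(prov["genome_path"], prov["gff3_path"], config)
    got = _sha256_text(guides_to_tsv(db))
    want = manifest["checksums"]["guides.tsv"]
    if got != want:
        raise InputError(
            f"database at {db_dir} does not match its manifest "
            f"(guides.tsv checksum {got[:12]} != {want[:12]})"
        )
    return db


def export_sites_bed(db: GuideDatabase) -> str:
    return sites_to_bed(db.sites)


def gene_report_tsv(
    db: GuideDatabase,
    gene_id: str,
    mode: str = "default",
    homoeologs: HomoeologGroups | None = None,
) -> str:
    reports = query_gene(db, gene_id, mode=mode, homoeologs=homoeologs)
    return reports_to_tsv(reports, max_k=db.config.policy.max_cap)
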