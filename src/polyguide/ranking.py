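"""Per-guide aggregation and overall-score ranking.

The key off-target summary per guide is the worst (maximum) CFD score
in each of the four genomic regions.  The default overall score trades
on-target activity against region-weighted worst off-targets:

    overall = 0.5*rs2 + 1 - 0.5*(0.7*max(cfd_coding, cfd_promoter)
                                 + 0.2*cfd_other_genic
                                 + 0.1*cfd_intergenic)        in [0.5, 1.5]

In homoeolog mode, hits inside homoeologue coding/promoter regions are
diverted out of the penalty maxima and rewarded instead:

    overall = 0.33*rs2 + (1 - 0.33*(...same weighted term...))
              + 0.34*mean(cfd_hmlgs)                          in [0.67, 1.67]

where cfd_hmlgs holds the best CFD per non-target homoeologue,
zero-filled for homoeologues without any detected hit, so the reward is
largest for guides predicted to cut every copy.  The overall score is a
heuristic ranking aid, not an empirically fitted quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ContractError
from .genome import GeneModel, RegionMap
from .offtarget import OffTargetHit
from .pam import FOOTPRINT, OnTargetGuide


@dataclass(frozen=True)
class HomoeologGroups:
    """gene_id → group_id mapping (a gene belongs to at most one group)."""

    group_of: dict[str, str]

    @property
    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid, grp in self.group_of.items():
            out.setdefault(grp, []).append(gid)
        return {g: sorted(m) for g, m in out.items()}

    def partners(self, gene_id: str) -> list[str]:
        """Other genes in gene_id's group (empty if ungrouped)."""
        grp = self.group_of.get(gene_id)
        if grp is None:
            return []
        return [g for g in self.members[grp] if g != gene_id]


def load_homoeolog_groups(text: str) -> HomoeologGroups:
    """Parse a two-column TSV (gene_id, group_id); leading '#' lines ignored."""
    group_of: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gid, grp = line.split("\t")[:2]
        if gid == "gene_id":
            continue
        if gid in group_of and group_of[gid] != grp:
            raise ContractError(f"gene {gid} listed in two homoeolog groups")
        group_of[gid] = grp
    return HomoeologGroups(group_of)


@dataclass(frozen=True)
class RegionCfdSummary:
    cfd_coding: float = 0.0
    cfd_promoter: float = 0.0
    cfd_other_genic: float = 0.0
    cfd_intergenic: float = 0.0


def aggregate_region_cfd(
    hits: list[OffTargetHit],
    homoeolog_partners: list[str] | None = None,
    region_map: RegionMap | None = None,
) -> tuple[RegionCfdSummary, list[float] | None]:
    """Per-region maximum CFD over a guide's non-self hits.

    In homoeolog mode (partners given), a hit whose site lies inside a
    partner gene's coding or promoter interval is diverted: it feeds the
    per-partner best-CFD list (zero-filled for partners without hits)
    and is excluded from the four regional maxima.
    """
    maxima = {"coding": 0.0, "promoter": 0.0, "other_genic": 0.0,
              "intergenic": 0.0}
    hmlg_best: dict[str, float] | None = None
    if homoeolog_partners is not None:
        if region_map is None:
            raise ContractError("homoeolog mode requires a region map")
        hmlg_best = {g: 0.0 for g in homoeolog_partners}

    for hit in hits:
        if hit.self_hit:
            continue
        cfd = hit.cfd if hit.cfd is not None else 0.0
        if hmlg_best is not None:
            owners = {
                gid for gid, _kind in region_map.owner_genes(
                    hit.site.contig_id, hit.site.protospacer_start
                )
                if gid in hmlg_best
            }
            if owners:
                for gid in owners:
                    hmlg_best[gid] = max(hmlg_best[gid], cfd)
                continue
        maxima[hit.site.region] = max(maxima[hit.site.region], cfd)

    summary = RegionCfdSummary(
        cfd_coding=maxima["coding"],
        cfd_promoter=maxima["promoter"],
        cfd_other_genic=maxima["other_genic"],
        cfd_intergenic=maxima["intergenic"],
    )
    cfd_hmlgs = (
        [hmlg_best[g] for g in sorted(hmlg_best)] if hmlg_best is not None else None
    )
    return summary, cfd_hmlgs


def _check_unit(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ContractError(f"{name} = {value} outside [0,1]")


def _weighted_cfd(s: RegionCfdSummary) -> float:
    for name in ("cfd_coding", "cfd_promoter", "cfd_other_genic",
                 "cfd_intergenic"):
        _check_unit(name, getattr(s, name))
    return (0.7 * max(s.cfd_coding, s.cfd_promoter)
            + 0.2 * s.cfd_other_genic
            + 0.1 * s.cfd_intergenic)


def overall_score_default(rs2: float, s: RegionCfdSummary) -> float:
    """0.5*rs2 + 1 - 0.5*(weighted worst-CFD term); range [0.5, 1.5]."""
    _check_unit("rs2", rs2)
    return 0.5 * rs2 + 1.0 - 0.5 * _weighted_cfd(s)


def overall_score_homoeolog(
    rs2: float, s: RegionCfdSummary, cfd_hmlgs: list[float]
) -> float:
    """0.33*rs2 + (1 - 0.33*(weighted term)) + 0.34*mean(cfd_hmlgs);
    range [0.67, 1.67]."""
    _check_unit("rs2", rs2)
    if not cfd_hmlgs:
        raise ContractError("homoeolog mode requires a non-empty cfd_hmlgs")
    for v in cfd_hmlgs:
        _check_unit("cfd_hmlgs element", v)
    mean_h = sum(cfd_hmlgs) / len(cfd_hmlgs)
    return 0.33 * rs2 + (1.0 - 0.33 * _weighted_cfd(s)) + 0.34 * mean_h


def isoform_coverage(
    guide: OnTargetGuide, gene: GeneModel
) -> tuple[bool, float]:
    """Fraction of the gene's isoforms whose exon union contains the full
    23-nt footprint; promoter guides cover no isoform by definition."""
    if guide.site.region != "coding" or not gene.isoforms:
        return False, 0.0
    f = guide.site.footprint_start
    covered = sum(
        any(s <= f and f + FOOTPRINT <= e for s, e in iso.exons)
        for iso in gene.isoforms
    )
    frac = covered / len(gene.isoforms)
    return frac == 1.0, frac


@dataclass
class GuideReport:
    """Ranked per-guide record for one gene query."""

    guide: OnTargetGuide
    summary: RegionCfdSummary
    cfd_hmlgs: list[float] | None
    overall: float
    rank: int = 0
    top: bool = False
    in_all_isoforms: bool = False
    isoform_fraction: float = 0.0
    n_offtargets_by_k: dict[int, int] = field(default_factory=dict)


def rank_guides(
    reports: list[GuideReport], top: int = 10
) -> list[GuideReport]:
    """Sort by overall desc, then rs2 desc, then (contig, start, strand);
    assign 1-based ranks and flag the first ``top`` for default display."""
    ordered = sorted(
        reports,
        key=lambda r: (
            -r.overall,
            -r.guide.rs2,
            r.guide.site.contig_id,
            r.guide.site.protospacer_start,
            r.guide.site.strand,
        ),
    )
    for i, rep in enumerate(ordered, start=1):
        rep.rank = i
        rep.top = i <= top
    return ordered


def reports_to_tsv(reports: list[GuideReport], max_k: int = 6) -> str:
    """gRNA table: one row per ranked guide, scores to 4 decimals."""
    kcols = "\t".join(f"n_offtargets_k{k}" for k in range(max_k + 1))
    lines = [
        "gene_id\tguide_id\tcontig\tstart\tend\tstrand\tprotospacer\tpam\t"
        "region\trs2\tcfd_coding\tcfd_promoter\tcfd_other_genic\t"
        f"cfd_intergenic\tcfd_hmlg_mean\t{kcols}\toverall\trank\t"
        "in_all_isoforms\tisoform_fraction"
    ]
    for r in reports:
        s = r.guide.site
        hm = (sum(r.cfd_hmlgs) / len(r.cfd_hmlgs)) if r.cfd_hmlgs else 0.0
        kvals = "\t".join(
            str(r.n_offtargets_by_k.get(k, 0)) for k in range(max_k + 1)
        )
        lines.append(
            f"{r.guide.gene_id}\t{r.guide.guide_id}\t{s.contig_id}\t"
            f"{s.footprint_start}\t{s.footprint_start + FOOTPRINT}\t{s.strand}\t"
            f"{s.protospacer}\t{s.pam}\t{s.region}\t{r.guide.rs2:.4f}\t"
            f"{r.summary.cfd_coding:.4f}\t{r.summary.cfd_promoter:.4f}\t"
            f"{r.summary.cfd_other_genic:.4f}\t{r.summary.cfd_intergenic:.4f}\t"
            f"{hm:.4f}\t{kvals}\t{r.overall:.4f}\t{r.rank}\t"
            f"{int(r.in_all_isoforms)}\t{r.isoform_fraction:.4f}"
        )
    return "\n".join(lines) + "\n"
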