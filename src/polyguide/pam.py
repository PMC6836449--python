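"""PAM-site enumeration and on-target guide selection.

Scans every genomic 3-mer window on both strands for the canonical NGG
PAM and the non-canonical NAG/NCG/NGA classes, keeping only windows with
a full 20-nt protospacer immediately 5' on the same strand and no N in
the 23-nt footprint.  Canonical NGG sites in coding or promoter regions
form the on-target guide set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .genome import GenomeSequence, RegionMap

logger = logging.getLogger(__name__)

#: PAM class → required (2nd, 3rd) base pair.  The four patterns are
#: pairwise disjoint, so class assignment is unambiguous; NGG is checked
#: first regardless.
PAM_CLASSES: dict[str, str] = {"NGG": "GG", "NAG": "AG", "NCG": "CG", "NGA": "GA"}

PROTOSPACER_LEN = 20
PAM_LEN = 3
FOOTPRINT = PROTOSPACER_LEN + PAM_LEN  # 23


@dataclass(frozen=True, slots=True)
class PamSite:
    """One protospacer+PAM occurrence.

    ``protospacer_start`` is the forward-strand coordinate of the
    protospacer's 5'-most base (= footprint_start on '+', footprint_start
    + 22 on '-'); region classification uses this single base.
    ``footprint_start`` is the left end of the 23-nt forward-strand
    footprint, i.e. the BED start.
    """

    contig_id: str
    strand: str
    protospacer_start: int
    footprint_start: int
    protospacer: str
    pam: str
    pam_class: str
    region: str

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.contig_id, self.strand, self.protospacer_start)


def _runs_without_n(is_n: np.ndarray, width: int) -> np.ndarray:
    """Boolean array over window starts: True if window [i, i+width) is N-free."""
    if is_n.shape[0] < width:
        return np.zeros(0, dtype=bool)
    csum = np.concatenate(([0], np.cumsum(is_n.astype(np.int32))))
    return (csum[width:] - csum[:-width]) == 0


def scan_pam_sites(
    genome: GenomeSequence,
    region_map: RegionMap,
    pam_classes: Sequence[str] = ("NGG", "NAG", "NCG", "NGA"),
) -> list[PamSite]:
    """Enumerate every PamSite of the requested classes on both strands.

    Emission order is deterministic: per contig in genome order, '+'
    strand sites by ascending footprint, then '-' strand sites.  Windows
    containing N are skipped and counted in the log.
    """
    for cls in pam_classes:
        if cls not in PAM_CLASSES:
            raise ValueError(f"unknown PAM class {cls!r}")
    # NGG first for clarity; the patterns are disjoint so order is cosmetic.
    ordered = [c for c in PAM_CLASSES if c in pam_classes]

    sites: list[PamSite] = []
    n_skipped = 0
    for cid, seq in genome.contigs.items():
        L = len(seq)
        if L < FOOTPRINT:
            continue
        arr = genome.encoded(cid)
        labels = region_map.labels[cid]
        nfree = _runs_without_n(arr == 4, FOOTPRINT)  # indexed by footprint start

        fwd: list[tuple[int, str]] = []  # (footprint_start, pam_class)
        rev: list[tuple[int, str]] = []
        b1 = arr[:-1]
        b2 = arr[1:]
        code = {b: i for i, b in enumerate("ACGT")}
        for cls in ordered:
            x, y = PAM_CLASSES[cls]
            # forward: PAM suffix at positions (p+1, p+2); footprint start f = p-20
            hit = np.nonzero((b1 == code[x]) & (b2 == code[y]))[0]
            p = hit - 1  # PAM start
            f = p - PROTOSPACER_LEN
            ok = (f >= 0) & (p + PAM_LEN <= L)
            for fs in f[ok]:
                if nfree[fs]:
                    fwd.append((int(fs), cls))
                else:
                    n_skipped += 1
            # reverse: forward 3-mer at footprint start is revcomp(PAM);
            # its first two bases are complement(y), complement(x).
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            rx, ry = comp[y], comp[x]
            hit = np.nonzero((b1 == code[rx]) & (b2 == code[ry]))[0]
            f = hit  # footprint start
            ok = f + FOOTPRINT <= L
            for fs in f[ok]:
                if nfree[fs]:
                    rev.append((int(fs), cls))
                else:
                    n_skipped += 1

        for strand, found in (("+", sorted(fwd)), ("-", sorted(rev))):
            for fs, cls in found:
                if strand == "+":
                    proto = seq[fs : fs + PROTOSPACER_LEN]
                    pam = seq[fs + PROTOSPACER_LEN : fs + FOOTPRINT]
                    pstart = fs
                else:
                    pam = revcomp(seq[fs : fs + PAM_LEN])
                    proto = revcomp(seq[fs + PAM_LEN : fs + FOOTPRINT])
                    pstart = fs + FOOTPRINT - 1
                sites.append(
                    PamSite(
                        contig_id=cid,
                        strand=strand,
                        protospacer_start=pstart,
                        footprint_start=fs,
                        protospacer=proto,
                        pam=pam,
                        pam_class=cls,
                        region=region_map.classify(cid, pstart),
                    )
                )
    if n_skipped:
        logger.info("scan: skipped %d N-containing windows", n_skipped)
    logger.info("scan: %d PAM sites", len(sites))
    return sites


def extract_context(site: PamSite, genome: GenomeSequence) -> str | None:
    """30-nt context on the PAM strand: 4 nt + protospacer + PAM + 3 nt.

    Returns None when the window runs off the contig or contains N.
    """
    seq = genome.contigs[site.contig_id]
    f = site.footprint_start
    if site.strand == "+":
        s, e = f - 4, f + FOOTPRINT + 3
        if s < 0 or e > len(seq):
            return None
        ctx = seq[s:e]
    else:
        s, e = f - 3, f + FOOTPRINT + 4
        if s < 0 or e > len(seq):
            return None
        ctx = revcomp(seq[s:e])
    if "N" in ctx:
        return None
    return ctx


@dataclass(slots=True)
class OnTargetGuide:
    """A canonical coding/promoter PamSite adopted as a designable guide."""

    site: PamSite
    gene_id: str
    rs2: float = 0.0
    context30: str | None = None
    no_context: bool = False

    @property
    def guide_id(self) -> str:
        s = self.site
        return f"{self.gene_id}|{s.contig_id}:{s.protospacer_start}{s.strand}"


def select_on_targets(
    sites: Iterable[PamSite],
    scorer: Callable[[str, bool], float],
    region_map: RegionMap,
    genome: GenomeSequence,
) -> list[OnTargetGuide]:
    """Keep NGG sites in coding/promoter regions and score them.

    A site covered by the coding/promoter intervals of several genes
    yields one guide per owning gene.  Sites whose 30-nt context is
    unavailable get rs2 = 0 and the no_context flag.
    """
    guides: list[OnTargetGuide] = []
    for site in sites:
        if site.pam_class != "NGG" or site.region not in ("coding", "promoter"):
            continue
        owners = {
            gid for gid, _kind in
            region_map.owner_genes(site.contig_id, site.protospacer_start)
        }
        ctx = extract_context(site, genome)
        if ctx is None:
            rs2, flag = 0.0, True
        else:
            rs2, flag = scorer(ctx, site.region == "coding"), False
        for gid in sorted(owners):
            guides.append(
                OnTargetGuide(
                    site=site, gene_id=gid, rs2=rs2,
                    context30=ctx, no_context=flag,
                )
            )
    logger.info("select: %d on-target guides", len(guides))
    return guides


def sites_to_tsv(sites: Iterable[PamSite]) -> str:
    """One row per PamSite (tab-separated, with header)."""
    lines = ["contig\tstrand\tprotospacer_start\tfootprint_start\t"
             "protospacer\tpam\tpam_class\tregion"]
    for s in sites:
        lines.append(
            f"{s.contig_id}\t{s.strand}\t{s.protospacer_start}\t"
            f"{s.footprint_start}\t{s.protospacer}\t{s.pam}\t"
            f"{s.pam_class}\t{s.region}"
        )
    return "\n".join(lines) + "\n"


def sites_to_bed(sites: Iterable[PamSite]) -> str:
    """BED6: footprint interval, name = pam_class, score 0, strand."""
    lines = [
        f"{s.contig_id}\t{s.footprint_start}\t{s.footprint_start + FOOTPRINT}\t"
        f"{s.pam_class}\t0\t{s.strand}"
        for s in sites
    ]
    return "\n".join(lines) + "\n"
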