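"""Complete tiered-k off-target enumeration.

Alignment heuristics (e.g. Bowtie2) may miss high-mismatch hits and so
underestimate off-target risk; this module instead guarantees complete
retrieval within each dataset's Hamming-distance cap using pigeonhole
seed partitioning: a 20-mer within k mismatches of the guide must match
it exactly on at least one of k+1 disjoint fragments, so exact fragment
lookup followed by full Hamming verification can miss nothing.

The genome's PAM sites are partitioned into eight datasets — {canonical,
non-canonical} PAM class x {coding, promoter, other_genic, intergenic}
region — each searched to its own cap (deepest for canonical sites in
exons/promoters, shallowest intergenic), with an early-stop rule:
once at least ``early_stop_threshold`` cumulative matches are found up
to some k, levels k+1.. are not searched in that dataset.  Levels are
atomic: a level is either fully reported or not at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode
from .errors import ContractError

from .pam import OnTargetGuide, PamSite, PROTOSPACER_LEN

logger = logging.getLogger(__name__)

REGION_GROUPS = {
    "coding": "exon_promoter",
    "promoter": "exon_promoter",
    "other_genic": "intron_utr",
    "intergenic": "intergenic",
}

DEFAULT_CAPS = {
    ("canonical", "exon_promoter"): 6,
    ("canonical", "intron_utr"): 4,
    ("canonical", "intergenic"): 3,
    ("non_canonical", "exon_promoter"): 4,
    ("non_canonical", "intron_utr"): 3,
    ("non_canonical", "intergenic"): 2,
}

DEFAULT_EARLY_STOP = 20

#: deterministic dataset iteration order
DATASET_KEYS = [
    (grp, region)
    for grp in ("canonical", "non_canonical")
    for region in ("coding", "promoter", "other_genic", "intergenic")
]


def pam_group(pam_class: str) -> str:
    return "canonical" if pam_class == "NGG" else "non_canonical"


@dataclass(frozen=True)
class KCapPolicy:
    """Region- and PAM-class-tiered mismatch caps plus the early-stop rule."""

    caps: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_CAPS)
    )
    early_stop_threshold: int = DEFAULT_EARLY_STOP
    early_stop_enabled: bool = True

    def __post_init__(self) -> None:
        if self.early_stop_threshold < 1:
            raise ContractError("early_stop_threshold must be >= 1")

    def cap(self, pam_class: str, region: str) -> int:
        return self.caps[(pam_group(pam_class), REGION_GROUPS[region])]

    @property
    def max_cap(self) -> int:
        return max(self.caps.values())


def k_cap(policy: KCapPolicy, pam_class: str, region: str) -> int:
    """Maximum mismatch level searched for a site's dataset."""
    return policy.cap(pam_class, region)


def hamming20(a: str, b: str) -> int:
    """Mismatch count between two 20-nt protospacers."""
    if len(a) != PROTOSPACER_LEN or len(b) != PROTOSPACER_LEN:
        raise ContractError("hamming20 requires two 20-nt strings")
    return sum(x != y for x, y in zip(a, b))


def _fragment_bounds(n_pieces: int) -> list[tuple[int, int]]:
    """Split [0, 20) into n_pieces near-equal contiguous fragments."""
    cuts = np.linspace(0, PROTOSPACER_LEN, n_pieces + 1).astype(int)
    return [(int(cuts[i]), int(cuts[i + 1])) for i in range(n_pieces)]


class _Dataset:
    """Sites of one (pam_group, region) dataset plus lazy fragment indexes."""

    def __init__(self) -> None:
        self.sites: list[PamSite] = []
        self._protos: np.ndarray | None = None
        self._frag: dict[int, dict[tuple[int, str], np.ndarray]] = {}

    def add(self, site: PamSite) -> None:
        self.sites.append(site)

    @property
    def protos(self) -> np.ndarray:
        if self._protos is None:
            if self.sites:
                self._protos = np.stack(
                    [encode(s.protospacer) for s in self.sites]
                )
            else:
                self._protos = np.zeros((0, PROTOSPACER_LEN), dtype=np.uint8)
        return self._protos

    def _index_for(self, n_pieces: int) -> dict[tuple[int, str], np.ndarray]:
        idx = self._frag.get(n_pieces)
        if idx is None:
            bounds = _fragment_bounds(n_pieces)
            raw: dict[tuple[int, str], list[int]] = {}
            for i, site in enumerate(self.sites):
                for j, (s, e) in enumerate(bounds):
                    raw.setdefault((j, site.protospacer[s:e]), []).append(i)
            idx = {k: np.asarray(v, dtype=np.int64) for k, v in raw.items()}
            self._frag[n_pieces] = idx
        return idx

    def query(self, guide20: str, k: int) -> list[tuple[int, int]]:
        """All (site_index, hamming) with hamming <= k; complete by pigeonhole."""
        if not self.sites:
            return []
        n_pieces = k + 1
        idx = self._index_for(n_pieces)
        bounds = _fragment_bounds(n_pieces)
        cands: list[np.ndarray] = []
        for j, (s, e) in enumerate(bounds):
            arr = idx.get((j, guide20[s:e]))
            if arr is not None:
                cands.append(arr)
        if not cands:
            return []
        cand = np.unique(np.concatenate(cands))
        g = encode(guide20)
        mism = (self.protos[cand] != g).sum(axis=1)
        keep = mism <= k
        return [(int(i), int(m)) for i, m in zip(cand[keep], mism[keep])]


class SeedIndex:
    """Eight per-dataset exact-fragment indexes supporting k-mismatch retrieval."""

    def __init__(self) -> None:
        self.datasets: dict[tuple[str, str], _Dataset] = {
            key: _Dataset() for key in DATASET_KEYS
        }

    def add(self, site: PamSite) -> None:
        self.datasets[(pam_group(site.pam_class), site.region)].add(site)

    def query(
        self, dataset_key: tuple[str, str], guide20: str, k: int
    ) -> list[tuple[PamSite, int]]:
        ds = self.datasets[dataset_key]
        return [(ds.sites[i], m) for i, m in ds.query(guide20, k)]


def build_seed_index(sites, policy: KCapPolicy | None = None) -> SeedIndex:
    """Partition scanned sites into the eight datasets and index them."""
    index = SeedIndex()
    for site in sites:
        index.add(site)
    for key in DATASET_KEYS:
        logger.debug("index: %s -> %d sites", key, len(index.datasets[key].sites))
    return index


@dataclass(slots=True)
class OffTargetHit:
    """A (guide, genomic site) pairing within the dataset's mismatch cap."""

    guide_id: str
    site: PamSite
    k: int
    self_hit: bool = False
    cfd: float | None = None


def find_offtargets(
    guide: OnTargetGuide | str,
    index: SeedIndex,
    policy: KCapPolicy,
    guide_site_key: tuple[str, str, int] | None = None,
) -> list[OffTargetHit]:
    """All off-target hits of a guide across the eight datasets.

    Within each dataset, hits accumulate level-by-level k = 0, 1, ...;
    after completing a level, if the cumulative count reaches the
    early-stop threshold no deeper level is reported for that dataset
    (levels are atomic).  The guide's own genomic site is returned
    flagged as self_hit and counts toward the threshold; exclusion from
    score aggregation happens downstream.

    ``guide`` may be a bare 20-mer (pasted-sequence mode); then
    ``guide_site_key`` optionally marks which genomic site is self.
    """
    if isinstance(guide, OnTargetGuide):
        guide20 = guide.site.protospacer
        gid = guide.guide_id
        self_key = guide.site.key
    else:
        guide20 = guide
        gid = guide20
        self_key = guide_site_key
    if len(guide20) != PROTOSPACER_LEN or any(c not in "ACGT" for c in guide20):
        raise ContractError(f"invalid protospacer {guide20!r}")

    hits: list[OffTargetHit] = []
    for key in DATASET_KEYS:
        grp, region = key
        cap = policy.caps[(grp, REGION_GROUPS[region])]
        found = index.query(key, guide20, cap)
        by_level: dict[int, list[PamSite]] = {}
        for site, m in found:
            by_level.setdefault(m, []).append(site)
        cum = 0
        for k in range(cap + 1):
            level = by_level.get(k, [])
            level.sort(key=lambda s: s.key)
            for site in level:
                hits.append(
                    OffTargetHit(
                        guide_id=gid,
                        site=site,
                        k=k,
                        self_hit=(site.key == self_key),
                    )
                )
            cum += len(level)
            if policy.early_stop_enabled and cum >= policy.early_stop_threshold:
                break
    return hits


def hits_to_tsv(hits) -> str:
    """Off-target dump: one row per hit."""
    lines = ["guide_id\tcontig\tstrand\tstart\tpam\tpam_class\tregion\t"
             "k\tcfd\tself_hit"]
    for h in hits:
        s = h.site
        cfd = "" if h.cfd is None else f"{h.cfd:.4f}"
        lines.append(
            f"{h.guide_id}\t{s.contig_id}\t{s.strand}\t{s.protospacer_start}\t"
            f"{s.pam}\t{s.pam_class}\t{s.region}\t{h.k}\t{cfd}\t"
            f"{int(h.self_hit)}"
        )
    return "\n".join(lines) + "\n"
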