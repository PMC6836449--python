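"""Independent oracles used by the tests.

These deliberately avoid the library's seed-index/scan code paths:
the off-target oracle is a direct sliding-window Hamming scan over the
raw genome on both strands, and the region oracle paints labels with
plain Python loops straight from the gene models.
"""

from __future__ import annotations

import numpy as np

from polyguide._seq import encode, revcomp
from polyguide.genome import GeneModel, GenomeSequence, promoter_interval
from polyguide.offtarget import REGION_GROUPS, KCapPolicy, pam_group

PAM_SUFFIX = {"NGG": "GG", "NAG": "AG", "NCG": "CG", "NGA": "GA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_CODE = {b: i for i, b in enumerate("ACGT")}


def naive_site_scan(genome: GenomeSequence) -> set[tuple[str, str, int, str]]:
    """Pure-Python double-loop PAM scan: (contig, strand, footprint, class)."""
    out = set()
    for cid, seq in genome.contigs.items():
        L = len(seq)
        for f in range(0, L - 23 + 1):
            win = seq[f : f + 23]
            if "N" in win:
                continue
            for cls, suf in PAM_SUFFIX.items():
                if win[21:23] == suf:
                    out.add((cid, "+", f, cls))
                if win[0] == _COMP[suf[1]] and win[1] == _COMP[suf[0]]:
                    out.add((cid, "-", f, cls))
    return out


class WindowOracle:
    """Vectorised brute-force Hamming scan over every 23-nt genomic window.

    Precomputes, per contig, the PAM-class index sets on both strands so
    that many guides can be checked cheaply; completely independent of
    the pigeonhole seed index.
    """

    def __init__(self, genome: GenomeSequence, region_map) -> None:
        self.per_contig = []
        for cid, seq in genome.contigs.items():
            arr = encode(seq)
            L = arr.shape[0]
            if L < 23:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, 23)
            nfree = ~(win == 4).any(axis=1)
            fwd, rev = {}, {}
            for cls, suf in PAM_SUFFIX.items():
                x, y = suf
                fsel = (win[:, 21] == _CODE[x]) & (win[:, 22] == _CODE[y]) & nfree
                rsel = (
                    (win[:, 0] == _CODE[_COMP[y]])
                    & (win[:, 1] == _CODE[_COMP[x]])
                    & nfree
                )
                fwd[cls] = np.nonzero(fsel)[0]
                rev[cls] = np.nonzero(rsel)[0]
            regions = np.array(
                [region_map.classify(cid, p) for p in range(L)], dtype=object
            )
            self.per_contig.append((cid, win, fwd, rev, regions))

    def hits(
        self, guide20: str, policy: KCapPolicy
    ) -> dict[tuple[str, str], set[tuple[str, str, int, int]]]:
        """dataset -> {(contig, strand, protospacer_start, k)} within caps."""
        g = encode(guide20)
        grc = encode(revcomp(guide20))
        out: dict[tuple[str, str], set] = {}
        for cid, win, fwd, rev, regions in self.per_contig:
            for cls in PAM_SUFFIX:
                grp = pam_group(cls)
                idx = fwd[cls]
                if idx.size:
                    mism = (win[idx, :20] != g).sum(axis=1)
                    for f, k in zip(idx, mism):
                        region = regions[f]
                        if k <= policy.caps[(grp, REGION_GROUPS[region])]:
                            out.setdefault((grp, region), set()).add(
                                (cid, "+", int(f), int(k))
                            )
                idx = rev[cls]
                if idx.size:
                    mism = (win[idx, 3:23] != grc).sum(axis=1)
                    for f, k in zip(idx, mism):
                        region = regions[f + 22]
                        if k <= policy.caps[(grp, REGION_GROUPS[region])]:
                            out.setdefault((grp, region), set()).add(
                                (cid, "-", int(f) + 22, int(k))
                            )
        return out


def paint_regions_by_hand(
    genes: list[GeneModel], genome: GenomeSequence, promoter_length: int
) -> dict[str, list[str]]:
    """Label every position with nested Python loops (no numpy painting)."""
    out = {cid: ["intergenic"] * genome.length(cid) for cid in genome.contigs}
    order = {"intergenic": 0, "other_genic": 1, "promoter": 2, "coding": 3}

    def put(cid, s, e, label):
        arr = out[cid]
        for p in range(max(0, s), min(len(arr), e)):
            if order[label] > order[arr[p]]:
                arr[p] = label

    for g in genes:
        put(g.contig_id, g.span[0], g.span[1], "other_genic")
    for g in genes:
        prom = promoter_interval(g, genome.length(g.contig_id), promoter_length)
        if prom:
            put(g.contig_id, prom[0], prom[1], "promoter")
    for g in genes:
        for s, e in g.cds_union():
            put(g.contig_id, s, e, "coding")
    return out


def hits_as_keys(hits, include_self: bool = True):
    """find_offtargets output -> dataset -> {(contig, strand, start, k)}."""
    out: dict[tuple[str, str], set] = {}
    for h in hits:
        if not include_self and h.self_hit:
            continue
        key = (pam_group(h.site.pam_class), h.site.region)
        out.setdefault(key, set()).add(
            (h.site.contig_id, h.site.strand, h.site.protospacer_start, h.k)
        )
    return out


def replay_early_stop(disabled_keys: dict, policy: KCapPolicy) -> dict:
    """Apply the cumulative-20 level rule to a full (no-early-stop) hit
    set, independently of the implementation's control flow."""
    out = {}
    for ds, keys in disabled_keys.items():
        cap = policy.caps[(ds[0], REGION_GROUPS[ds[1]])]
        by_k: dict[int, set] = {}
        for item in keys:
            by_k.setdefault(item[3], set()).add(item)
        kept = set()
        cum = 0
        for k in range(cap + 1):
            level = by_k.get(k, set())
            kept |= level
            cum += len(level)
            if cum >= policy.early_stop_threshold:
                break
        out[ds] = kept
    return out
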