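"""Generate the packaged synthetic score tables.

The shipped CFD penalty/PAM tables and rs2 weight file are deterministic
synthetic stand-ins with the qualitative shape of empirically derived
CRISPR scoring tables: mismatch penalties fall toward the PAM-proximal
end of the protospacer and depend on the mismatch identity (purine
transitions and rG:dT-wobble-like pairs are better tolerated); the
canonical GG PAM suffix has factor 1.0 with non-canonical suffixes far
lower; rs2 weights are small seeded values around a 0.45 intercept so
typical contexts score mid-range.  Re-running this script reproduces
the files byte-for-byte.

Usage: python scripts/make_score_tables.py  (writes src/polyguide/data/)
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "src" / "polyguide" / "data"

BASES = "ACGT"

# relative tolerance of each guide->target mismatch identity; wobble-like
# pairs (guide G vs target A, guide T vs target C, etc.) are more tolerated
MISMATCH_TOLERANCE = {
    ("A", "C"): 0.55, ("A", "G"): 0.70, ("A", "T"): 0.45,
    ("C", "A"): 0.60, ("C", "G"): 0.50, ("C", "T"): 0.75,
    ("G", "A"): 0.85, ("G", "C"): 0.45, ("G", "T"): 0.90,
    ("T", "A"): 0.50, ("T", "C"): 0.80, ("T", "G"): 0.65,
}

PAM_FACTORS = {
    "GG": 1.0, "AG": 0.26, "CG": 0.11, "GA": 0.07,
    "TG": 0.04, "GT": 0.02, "GC": 0.02, "AA": 0.0, "AC": 0.0,
    "AT": 0.0, "CA": 0.01, "CC": 0.0, "CT": 0.0, "TA": 0.0,
    "TC": 0.0, "TT": 0.0,
}

HEADER = (
    "# SYNTHETIC stand-in score table generated deterministically by\n"
    "# scripts/make_score_tables.py; not empirically fitted values.\n"
    "# Guide bases use the DNA alphabet (T for rU).\n"
)


def write_cfd_mismatch() -> None:
    rng = np.random.default_rng(431001)
    lines = [HEADER + "position\tguide_base\ttarget_base\tscore"]
    for pos in range(1, 21):
        # penalties shrink toward the PAM-proximal end (position 20)
        profile = 1.0 - 0.8 * ((pos - 1) / 19.0) ** 1.3
        for g in BASES:
            for t in BASES:
                if g == t:
                    continue
                jitter = rng.uniform(-0.03, 0.03)
                v = MISMATCH_TOLERANCE[(g, t)] * profile + jitter
                v = min(1.0, max(0.02, round(v, 4)))
                lines.append(f"{pos}\t{g}\t{t}\t{v}")
    (OUT / "cfd_mismatch_scores.synthetic.tsv").write_text("\n".join(lines) + "\n")


def write_cfd_pam() -> None:
    lines = [HEADER + "pam_suffix\tscore"]
    for suf in sorted(PAM_FACTORS):
        lines.append(f"{suf}\t{PAM_FACTORS[suf]}")
    (OUT / "cfd_pam_scores.synthetic.tsv").write_text("\n".join(lines) + "\n")


def write_rs2_weights() -> None:
    rng = np.random.default_rng(431002)
    lines = [HEADER + "feature\tweight"]
    lines.append("intercept\t0.45")
    for i in range(30):
        for b in BASES:
            lines.append(f"nt{i:02d}_{b}\t{rng.normal(0, 0.012):.6f}")
    for i in range(29):
        for b1 in BASES:
            for b2 in BASES:
                lines.append(f"dn{i:02d}_{b1}{b2}\t{rng.normal(0, 0.005):.6f}")
    lines.append("gc_low\t-0.012000")
    lines.append("gc_high\t-0.010000")
    lines.append("tm_seg1\t0.080000")
    lines.append("tm_seg2\t0.050000")
    lines.append("tm_seg3\t0.070000")
    for b1 in BASES:
        for b2 in BASES:
            lines.append(f"nggx_{b1}{b2}\t{rng.normal(0, 0.02):.6f}")
    lines.append("in_coding\t0.060000")
    (OUT / "rs2_weights.synthetic.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    write_cfd_mismatch()
    write_cfd_pam()
    write_rs2_weights()
    print(f"wrote score tables to {OUT}")
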