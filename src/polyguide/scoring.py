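"""Table-driven CFD off-target and rs2-style on-target scoring.

CFD (cutting frequency determination) multiplies a position- and
identity-specific penalty for every guide:target mismatch along the
20-nt protospacer, times a factor for the PAM's last two bases (GG = 1).
The on-target score is a deterministic linear model over sequence
features of the 30-nt context window (4 nt + protospacer + PAM + 3 nt):
position-specific mono- and dinucleotides, protospacer GC content,
melting-temperature proxies of three protospacer segments, the
PAM-flanking "NGGX" dinucleotide, and an in-coding-region indicator.
Scores are clamped to [0, 1].

Both scorers are backed by packaged TSV tables; the shipped tables are
deterministic synthetic stand-ins (see their headers) and can be
overridden by path.  Guide bases use the DNA alphabet throughout (T for
rU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .errors import ContractError, TableIntegrityError
from .pam import PROTOSPACER_LEN

_BASES = "ACGT"

CFD_MISMATCH_FILE = "cfd_mismatch_scores.synthetic.tsv"
CFD_PAM_FILE = "cfd_pam_scores.synthetic.tsv"
RS2_WEIGHTS_FILE = "rs2_weights.synthetic.tsv"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("polyguide").joinpath("data", name)))


def _read_tsv(path: Path) -> list[list[str]]:
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@dataclass(frozen=True)
class CfdTables:
    """Mismatch penalties keyed (position 1..20 5'->3', guide, target) and
    PAM factors keyed by the PAM's 2nd+3rd bases."""

    mismatch_penalty: dict[tuple[int, str, str], float]
    pam_factor: dict[str, float]

    def __post_init__(self) -> None:
        expected = {
            (p, g, t)
            for p in range(1, PROTOSPACER_LEN + 1)
            for g in _BASES
            for t in _BASES
            if g != t
        }
        missing = expected - set(self.mismatch_penalty)
        if missing:
            raise TableIntegrityError(
                f"CFD mismatch table missing {len(missing)} entries, "
                f"e.g. {sorted(missing)[0]}"
            )
        for key, v in self.mismatch_penalty.items():
            if not 0.0 <= v <= 1.0:
                raise TableIntegrityError(f"penalty {key} = {v} outside [0,1]")
        for suf, v in self.pam_factor.items():
            if not 0.0 <= v <= 1.0:
                raise TableIntegrityError(f"PAM factor {suf} = {v} outside [0,1]")
        if self.pam_factor.get("GG") != 1.0:
            raise TableIntegrityError("PAM factor for GG must be 1.0")


def load_cfd_tables(
    mismatch_path: str | Path | None = None,
    pam_path: str | Path | None = None,
) -> CfdTables:
    """Load CFD tables from TSV (packaged defaults unless paths given)."""
    mpath = Path(mismatch_path) if mismatch_path else _data_path(CFD_MISMATCH_FILE)
    ppath = Path(pam_path) if pam_path else _data_path(CFD_PAM_FILE)
    mism: dict[tuple[int, str, str], float] = {}
    for row in _read_tsv(mpath):
        if row[0] == "position":
            continue
        pos, g, t, v = int(row[0]), row[1], row[2], float(row[3])
        mism[(pos, g, t)] = v
    pam: dict[str, float] = {}
    for row in _read_tsv(ppath):
        if row[0] == "pam_suffix":
            continue
        pam[row[0]] = float(row[1])
    return CfdTables(mismatch_penalty=mism, pam_factor=pam)


def cfd_score(
    guide20: str, target20: str, target_pam: str, tables: CfdTables
) -> float:
    """PAM factor times the product of per-mismatch penalties (empty product = 1)."""
    if len(guide20) != PROTOSPACER_LEN or len(target20) != PROTOSPACER_LEN:
        raise ContractError("cfd_score requires 20-nt guide and target")
    if any(c not in _BASES for c in guide20 + target20):
        raise ContractError("cfd_score sequences must be over ACGT")
    if len(target_pam) != 3 or any(c not in _BASES for c in target_pam):
        raise ContractError(f"invalid PAM {target_pam!r}")
    suffix = target_pam[1:]
    try:
        score = tables.pam_factor[suffix]
    except KeyError:
        raise TableIntegrityError(f"no PAM factor for suffix {suffix!r}") from None
    for i, (g, t) in enumerate(zip(guide20, target20), start=1):
        if g != t:
            try:
                score *= tables.mismatch_penalty[(i, g, t)]
            except KeyError:
                raise TableIntegrityError(
                    f"no mismatch penalty for position {i} {g}->{t}"
                ) from None
    return score


# ---------------------------------------------------------------------------
# rs2-style on-target scoring


def _tm_proxy(seq: str) -> float:
    """Wallace-rule melting-temperature proxy, scaled to [0.5, 1]:
    (2*AT + 4*GC) / (4 * len)."""
    gc = sum(c in "GC" for c in seq)
    at = len(seq) - gc
    return (2 * at + 4 * gc) / (4 * len(seq))


def _feature_value(name: str, ctx: str, in_coding: bool) -> float:
    """Value of one named feature on a 30-nt context.

    Recognised names: nt{i:02d}_{B} (i 0..29), dn{i:02d}_{BB} (i 0..28),
    gc_count, gc_low, gc_high, tm_seg1..tm_seg3, nggx_{BB}, in_coding.
    Unknown names raise TableIntegrityError (schema mismatch).
    """
    proto = ctx[4:24]
    if name.startswith("nt") and len(name) == 6 and name[5] in _BASES:
        i = int(name[2:4])
        if 0 <= i <= 29:
            return 1.0 if ctx[i] == name[5] else 0.0
    elif name.startswith("dn") and len(name) == 7:
        i = int(name[2:4])
        if 0 <= i <= 28 and name[5] in _BASES and name[6] in _BASES:
            return 1.0 if ctx[i : i + 2] == name[5:7] else 0.0
    elif name == "gc_count":
        return float(sum(c in "GC" for c in proto))
    elif name == "gc_low":
        gc = sum(c in "GC" for c in proto)
        return float(max(0, 10 - gc))
    elif name == "gc_high":
        gc = sum(c in "GC" for c in proto)
        return float(max(0, gc - 10))
    elif name == "tm_seg1":  # first 5 protospacer bases
        return _tm_proxy(proto[0:5])
    elif name == "tm_seg2":  # middle 8
        return _tm_proxy(proto[5:13])
    elif name == "tm_seg3":  # 5 bases toward the PAM
        return _tm_proxy(proto[13:18])
    elif name.startswith("nggx_") and len(name) == 7:
        # PAM 'N' base (ctx[24]) and the base just 3' of the PAM (ctx[27])
        if name[5] in _BASES and name[6] in _BASES:
            return 1.0 if (ctx[24] == name[5] and ctx[27] == name[6]) else 0.0
    elif name == "in_coding":
        return 1.0 if in_coding else 0.0
    raise TableIntegrityError(f"unknown rs2 feature name {name!r}")


@dataclass(frozen=True)
class Rs2Model:
    """Deterministic linear on-target scorer: clamp(intercept + w·x, 0, 1)."""

    weights: dict[str, float]
    intercept: float = 0.0

    def score(self, context30: str, in_coding: bool) -> float:
        return rs2_score(context30, in_coding, self)


def load_rs2_model(path: str | Path | None = None) -> Rs2Model:
    wpath = Path(path) if path else _data_path(RS2_WEIGHTS_FILE)
    weights: dict[str, float] = {}
    intercept = 0.0
    for row in _read_tsv(wpath):
        if row[0] == "feature":
            continue
        if row[0] == "intercept":
            intercept = float(row[1])
        else:
            weights[row[0]] = float(row[1])
    return Rs2Model(weights=weights, intercept=intercept)


def _check_context(context30: str) -> None:
    if len(context30) != 30:
        raise ContractError("rs2 context must be 30 nt")
    if any(c not in _BASES for c in context30):
        raise ContractError("rs2 context must be over ACGT")


def featurize_rs2(
    context30: str, in_coding: bool, schema
) -> dict[str, float]:
    """Sparse feature vector (nonzero entries only) for the given schema
    (an iterable of feature names, e.g. ``model.weights``)."""
    _check_context(context30)
    out = {}
    for name in schema:
        v = _feature_value(name, context30, in_coding)
        if v != 0.0:
            out[name] = v
    return out


def rs2_score(context30: str, in_coding: bool, model: Rs2Model) -> float:
    """clamp(intercept + sum of weight * feature, 0, 1); deterministic."""
    _check_context(context30)
    total = model.intercept
    for name, w in model.weights.items():
        if w != 0.0:
            total += w * _feature_value(name, context30, in_coding)
    if math.isnan(total):
        raise TableIntegrityError("rs2 score is NaN; corrupt weights")
    return min(1.0, max(0.0, total))
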