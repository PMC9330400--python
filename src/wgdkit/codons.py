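"""Codon tables and NG86 synonymous/nonsynonymous counting.

Site and difference counting follow the Nei-Gojobori (1986) conventions as
implemented in the standard toolchain: mutations to stop codons count as
nonsynonymous, per-codon site counts are normalized so S + N = 3, and codon
pairs differing at 2-3 positions average synonymous/nonsynonymous difference
counts over all mutational pathways with equal weight (pathway steps through
stop codons count as nonsynonymous).  Everything is precomputed into numpy
tables at import so that scoring thousands of gene pairs is vectorized.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

BASES = "TCAG"
STANDARD_TABLE = {}
_aa = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(BASES, BASES, BASES)):
    STANDARD_TABLE[_b1 + _b2 + _b3] = _aa[_i]

STOP_CODONS = frozenset(c for c, a in STANDARD_TABLE.items() if a == "*")
SENSE_CODONS = sorted(c for c in STANDARD_TABLE if c not in STOP_CODONS)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)  # 61


def _neighbors(codon: str):
    for pos in range(3):
        for b in "ACGT":
            if b != codon[pos]:
                yield codon[:pos] + b + codon[pos + 1 :]


def _syn_site_counts():
    """Fractional synonymous sites per codon (stop neighbors nonsynonymous).

    With all 9 single-nucleotide neighbors counted, the normalization that
    makes S + N = 3 reduces to S = (# synonymous neighbors) / 3.
    """
    s = np.zeros(N_SENSE)
    for i, codon in enumerate(SENSE_CODONS):
        aa = STANDARD_TABLE[codon]
        syn = sum(
            1
            for nb in _neighbors(codon)
            if nb not in STOP_CODONS and STANDARD_TABLE[nb] == aa
        )
        s[i] = syn / 3.0
    return s


S_SITES = _syn_site_counts()
N_SITES = 3.0 - S_SITES


def _step_sn(c1: str, c2: str, weight: float):
    """(syn, nonsyn) weight of one mutational step.

    A step that preserves the encoded symbol is synonymous; this includes
    the degenerate stop-to-stop step inside a multi-hit pathway, matching
    the field's standard NG86 pathway accounting."""
    a1 = STANDARD_TABLE.get(c1) if c1 not in STOP_CODONS else None
    a2 = STANDARD_TABLE.get(c2) if c2 not in STOP_CODONS else None
    if a1 == a2:
        return weight, 0.0
    return 0.0, weight


def _pair_diffs(c1: str, c2: str):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    sd = nd = 0.0
    if len(diff) == 1:
        s, n = _step_sn(c1, c2, 1.0)
        sd += s
        nd += n
    elif len(diff) == 2:
        for i in diff:
            mid = c1[:i] + c2[i] + c1[i + 1 :]
            for a, b in ((c1, mid), (mid, c2)):
                s, n = _step_sn(a, b, 0.5)
                sd += s
                nd += n
    elif len(diff) == 3:
        for p in itertools.permutations(range(3)):
            t1 = c1[: p[0]] + c2[p[0]] + c1[p[0] + 1 :]
            t2 = t1[: p[1]] + c2[p[1]] + t1[p[1] + 1 :]
            for a, b in ((c1, t1), (t1, t2), (t2, c2)):
                s, n = _step_sn(a, b, 0.5 / 3)
                sd += s
                nd += n
    return sd, nd


def _diff_tables():
    sd = np.zeros((N_SENSE, N_SENSE))
    nd = np.zeros((N_SENSE, N_SENSE))
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i < j:
                s, n = _pair_diffs(c1, c2)
                sd[i, j] = sd[j, i] = s
                nd[i, j] = nd[j, i] = n
    return sd, nd


SD_TABLE, ND_TABLE = _diff_tables()

# single-nucleotide mutational neighborhoods among sense codons
SYN_NEIGHBORS: list[np.ndarray] = []
NONSYN_NEIGHBORS: list[np.ndarray] = []
for _codon in SENSE_CODONS:
    _aa0 = STANDARD_TABLE[_codon]
    _syn, _non = [], []
    for _nb in _neighbors(_codon):
        if _nb in STOP_CODONS:
            continue
        (_syn if STANDARD_TABLE[_nb] == _aa0 else _non).append(CODON_INDEX[_nb])
    SYN_NEIGHBORS.append(np.array(_syn, dtype=np.int16))
    NONSYN_NEIGHBORS.append(np.array(_non, dtype=np.int16))


def encode_cds(seq: str) -> np.ndarray:
    """Translate an in-frame CDS string to an array of sense-codon indices."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError("CDS length is not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    try:
        return np.array([CODON_INDEX[c] for c in codons], dtype=np.int16)
    except KeyError as exc:
        bad = exc.args[0]
        kind = "stop codon" if bad in STOP_CODONS else "unrecognized codon"
        raise ValueError(f"{kind} {bad!r} in CDS") from None


def decode_cds(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)


@dataclass(frozen=True)
class KaKs:
    """NG86 estimates for one sequence pair; NaN marks JC saturation."""

    ka: float
    ks: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float

    @property
    def saturated(self) -> bool:
        return math.isnan(self.ks)


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_ks(cds_a, cds_b) -> KaKs:
    """NG86 Ka/Ks with Jukes-Cantor multiple-hit correction per site class.

    Accepts raw CDS strings or pre-encoded codon-index arrays of equal
    length.  Ks (or Ka) is NaN when the corrected-log argument is
    non-positive, i.e. the proportion of differences reaches 3/4
    (saturation).
    """
    a = encode_cds(cds_a) if isinstance(cds_a, str) else np.asarray(cds_a)
    b = encode_cds(cds_b) if isinstance(cds_b, str) else np.asarray(cds_b)
    if a.shape != b.shape:
        raise ValueError("sequences differ in codon length")
    if a.size == 0:
        raise ValueError("empty sequences")
    s_sites = 0.5 * (S_SITES[a].sum() + S_SITES[b].sum())
    n_sites = 0.5 * (N_SITES[a].sum() + N_SITES[b].sum())
    sd = float(SD_TABLE[a, b].sum())
    nd = float(ND_TABLE[a, b].sum())
    ks = _jc(sd / s_sites) if s_sites > 0 else math.nan
    ka = _jc(nd / n_sites) if n_sites > 0 else math.nan
    return KaKs(ka=ka, ks=ks, s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)
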