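"""Pairwise synonymous substitution rates (Ks).

Site and difference counting follows the Nei–Gojobori (1986) pathway method:
per-codon synonymous site fractions, pathway-averaged difference counts for
multi-substitution codons, and a Jukes–Cantor correction
ks = -(3/4)·ln(1 - (4/3)·pS).  Mutations to stop codons are excluded from
site counting and pathways through stop codons are excluded from difference
averaging (with a fall-back to all pathways when every route is blocked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Optional

from .seqio import (
    CODON_TABLE,
    CodonAlignment,
    STOP_CODONS,
    align_proteins_global,
    codon_alignment,
    is_unambiguous,
    translate,
)

STATUS_OK = "ok"
STATUS_SATURATED = "saturated"
STATUS_INSUFFICIENT = "insufficient_overlap"

_NAN = float("nan")


@dataclass(frozen=True)
class KsResult:
    S: float  # synonymous sites, pair-averaged over compared codons
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences, pathway-averaged
    Nd: float  # nonsynonymous differences
    pS: float  # Sd / S
    ks: float  # -(3/4) ln(1 - (4/3) pS); NaN unless status == ok
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


@lru_cache(maxsize=None)
def ng86_sites(codon: str, exclude_stop_mutations: bool = True) -> tuple[float, float]:
    """(S, N) site counts for one codon.

    Each position contributes the fraction of its single-nucleotide changes
    that are synonymous; changes creating stop codons are dropped from both
    numerator and denominator when ``exclude_stop_mutations``.
    """
    codon = codon.upper()
    if not is_unambiguous(codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = CODON_TABLE[codon]
    S = 0.0
    for pos in range(3):
        syn = other = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS and exclude_stop_mutations:
                continue
            if CODON_TABLE[mut] == aa:
                syn += 1
            else:
                other += 1
        if syn + other:
            S += syn / (syn + other)
    return S, 3.0 - S


@lru_cache(maxsize=None)
def ng86_differences(
    codon_a: str, codon_b: str, exclude_stop_paths: bool = True
) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) between two sense codons.

    All orderings of the differing positions are enumerated; orderings whose
    intermediate codons are stops are skipped (every step of a blocked route
    would pass through a nonsense codon).  If all routes are blocked the
    average falls back to every ordering, with stop-involving steps counted
    as nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if not is_unambiguous(c):
            raise ValueError(f"invalid codon {c!r}")
        if c in STOP_CODONS:
            raise ValueError(f"stop codon {c} not comparable")
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0
        hits_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS or cur in STOP_CODONS:
                nd += 1
                hits_stop = hits_stop or nxt in STOP_CODONS
            elif CODON_TABLE[cur] == CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if hits_stop else valid).append((sd, nd))
    pool = valid if (valid and exclude_stop_paths) else valid + blocked
    Sd = sum(p[0] for p in pool) / len(pool)
    Nd = sum(p[1] for p in pool) / len(pool)
    return Sd, Nd


def _comparable(ca: Optional[str], cb: Optional[str]) -> bool:
    return (
        ca is not None
        and cb is not None
        and is_unambiguous(ca)
        and is_unambiguous(cb)
        and ca not in STOP_CODONS
        and cb not in STOP_CODONS
    )


def jukes_cantor(pS: float) -> float:
    """-(3/4)·ln(1 - (4/3)·pS); requires pS < 3/4."""
    if pS >= 0.75:
        raise ValueError(f"pS={pS} saturated")
    return -0.75 * math.log1p(-(4.0 / 3.0) * pS)


def ks_pair(codon_aln: CodonAlignment, min_overlap_bp: int = 50) -> KsResult:
    """Ks for one codon alignment.

    Gap columns, ambiguous codons, and stop codons are skipped.  Status is
    ``insufficient_overlap`` when fewer than ``min_overlap_bp`` aligned bases
    are available, ``saturated`` when pS reaches the Jukes–Cantor pole.
    """
    if codon_aln.overlap_bp < min_overlap_bp:
        return KsResult(_NAN, _NAN, _NAN, _NAN, _NAN, _NAN, STATUS_INSUFFICIENT)
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in codon_aln.pairs:
        if not _comparable(ca, cb):
            continue
        sa, na = ng86_sites(ca)
        sb, nb = ng86_sites(cb)
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        sd, nd = ng86_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_codons += 1
    if 3 * n_codons < min_overlap_bp:
        return KsResult(S, N, Sd, Nd, _NAN, _NAN, STATUS_INSUFFICIENT)
    if S <= 0.0:
        if Sd > 0.0:
            return KsResult(S, N, Sd, Nd, _NAN, _NAN, STATUS_SATURATED)
        return KsResult(S, N, Sd, Nd, 0.0, 0.0, STATUS_OK)
    pS = Sd / S
    if pS >= 0.75:
        return KsResult(S, N, Sd, Nd, pS, _NAN, STATUS_SATURATED)
    return KsResult(S, N, Sd, Nd, pS, jukes_cantor(pS), STATUS_OK)


def ks_equal_length(cds_a: str, cds_b: str, min_overlap_bp: int = 50) -> KsResult:
    """Ks for two unaligned CDS of identical length (positional pairing)."""
    if len(cds_a) != len(cds_b):
        raise ValueError("sequences differ in length; align them first")
    pairs = tuple(
        (cds_a[i : i + 3], cds_b[i : i + 3]) for i in range(0, len(cds_a) - 2, 3)
    )
    return ks_pair(CodonAlignment(pairs=pairs), min_overlap_bp=min_overlap_bp)


def ks_between(
    cds_a: str, cds_b: str, min_overlap_bp: int = 50, **align_kwargs
) -> KsResult:
    """Align the translations, back-translate to codons, compute Ks."""
    p_a = translate(cds_a)
    p_b = translate(cds_b)
    aln = align_proteins_global(p_a, p_b, **align_kwargs)
    return ks_pair(codon_alignment(aln, cds_a, cds_b), min_overlap_bp=min_overlap_bp)


def write_ks_table(rows, path) -> None:
    """TSV of pairwise Ks results: (taxon, id_a, id_b, KsResult) tuples."""
    with open(path, "w") as fh:
        fh.write("taxon\tid_a\tid_b\tS\tN\tSd\tNd\tpS\tks\tstatus\n")
        for taxon, id_a, id_b, r in rows:
            fh.write(
                f"{taxon}\t{id_a}\t{id_b}\t{r.S:.4f}\t{r.N:.4f}\t{r.Sd:.4f}\t"
                f"{r.Nd:.4f}\t{r.pS:.6f}\t{r.ks:.6f}\t{r.status}\n"
            )
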