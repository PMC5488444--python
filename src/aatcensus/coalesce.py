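"""Collapse candidate transcripts into putative representative loci.

De novo mode: isoforms sharing an assembler component collapse first; the
remaining component representatives are compared all-against-all and joined
when the pairwise synonymous rate is below threshold or when their aligned
overlap is shorter than the overlap cutoff (fragments of one gene).  Joins
are transitive: loci are connected components of the pair graph.

Genome-guided mode: each transcript's best-scoring scaffold interval is
taken and intervals sharing scaffold and strand that overlap or lie within
a configurable gap are merged into one locus.  Transcripts without a
passing mapping fall back to the de novo rules.

Every locus keeps the member with the longest ORF as its representative
(ties go to the lexicographically smaller id), and every merge is logged
with its reason.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from . import ks as ksmod
from .classify import Candidate
from .seqio import align_proteins_global, codon_alignment

logger = logging.getLogger(__name__)

REASON_COMPONENT = "shared_component"
REASON_KS = "ks_below_threshold"
REASON_OVERLAP = "short_overlap"
REASON_LOCATION = "shared_location"
REASON_NONE = "none"


@dataclass(frozen=True)
class CoalesceConfig:
    ks_threshold: float = 0.25
    overlap_bp: int = 50
    merge_gap_bp: int = 5000
    map_evalue: float = 1e-3


@dataclass(frozen=True)
class MappingHit:
    """One transcript-to-scaffold alignment (1-based inclusive coordinates)."""

    transcript_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PairDecision:
    collapse: bool
    reason: str
    ks: Optional[ksmod.KsResult]


@dataclass(frozen=True)
class MergeLog:
    id_a: str
    id_b: str
    reason: str
    ks: Optional[float] = None


@dataclass
class Locus:
    locus_id: str
    members: tuple
    representative_id: str


@dataclass
class LocusSet:
    taxon: str
    family: str
    loci: list
    decisions: list = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.loci)


def _rep(candidates: Sequence[Candidate]) -> Candidate:
    return min(candidates, key=lambda c: (-len(c.orf.protein), c.id))


def collapse_by_component(
    candidates: Sequence[Candidate],
) -> list[list[Candidate]]:
    """Group same-taxon candidates by component id; groups sorted by rep id."""
    groups: dict[tuple, list[Candidate]] = {}
    for c in candidates:
        if not c.transcript.component_id:
            raise ValueError(f"{c.id}: missing component id in de novo mode")
        groups.setdefault((c.transcript.taxon, c.transcript.component_id), []).append(c)
    out = [sorted(g, key=lambda c: c.id) for g in groups.values()]
    out.sort(key=lambda g: _rep(g).id)
    return out


def pair_decision(
    rep_a: Candidate, rep_b: Candidate, cfg: CoalesceConfig = CoalesceConfig()
) -> PairDecision:
    """Decide whether two component representatives belong to one locus."""
    aln = align_proteins_global(rep_a.orf.protein, rep_b.orf.protein)
    caln = codon_alignment(aln, rep_a.orf.cds, rep_b.orf.cds)
    if caln.overlap_bp < cfg.overlap_bp:
        return PairDecision(True, REASON_OVERLAP, None)
    result = ksmod.ks_pair(caln, min_overlap_bp=cfg.overlap_bp)
    if result.status == ksmod.STATUS_INSUFFICIENT:
        return PairDecision(True, REASON_OVERLAP, result)
    if result.ok and result.ks < cfg.ks_threshold:
        return PairDecision(True, REASON_KS, result)
    return PairDecision(False, REASON_NONE, result)


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {i: i for i in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic: smaller id becomes the root
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def _check_inputs(candidates: Sequence[Candidate]) -> tuple[str, str]:
    taxa = {c.transcript.taxon for c in candidates}
    fams = {c.family for c in candidates}
    if len(taxa) != 1 or len(fams) != 1:
        raise ValueError(
            f"coalescing expects one taxon and one family, got taxa={sorted(taxa)} "
            f"families={sorted(fams)}"
        )
    return taxa.pop(), fams.pop()


def _build_loci(
    taxon: str,
    family: str,
    clusters: Sequence[Sequence[Candidate]],
    decisions: list[MergeLog],
) -> LocusSet:
    loci = []
    for members in sorted(clusters, key=lambda ms: _rep(ms).id):
        rep = _rep(members)
        loci.append(
            Locus(
                locus_id="",
                members=tuple(sorted(c.id for c in members)),
                representative_id=rep.id,
            )
        )
    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"{taxon}|{family}|L{i:03d}"
    ls = LocusSet(taxon=taxon, family=family, loci=loci, decisions=decisions)
    _assert_partition(ls, clusters)
    return ls


def _assert_partition(ls: LocusSet, clusters) -> None:
    all_ids = sorted(c.id for ms in clusters for c in ms)
    in_loci = sorted(m for locus in ls.loci for m in locus.members)
    if all_ids != in_loci:
        raise AssertionError("loci do not partition the candidate set")


def coalesce_denovo(
    candidates: Sequence[Candidate], cfg: CoalesceConfig = CoalesceConfig()
) -> LocusSet:
    """Component collapse, then transitive Ks/overlap joining of representatives."""
    if not candidates:
        raise ValueError("no candidates to coalesce")
    taxon, family = _check_inputs(candidates)
    groups = collapse_by_component(candidates)
    decisions: list[MergeLog] = []
    for g in groups:
        rep = _rep(g)
        for c in g:
            if c.id != rep.id:
                decisions.append(MergeLog(rep.id, c.id, REASON_COMPONENT))
    reps = [_rep(g) for g in groups]
    uf = _UnionFind(r.id for r in reps)
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            a, b = sorted((reps[i], reps[j]), key=lambda c: c.id)
            dec = pair_decision(a, b, cfg)
            if dec.collapse:
                uf.union(a.id, b.id)
                decisions.append(
                    MergeLog(a.id, b.id, dec.reason,
                             dec.ks.ks if dec.ks is not None else None)
                )
    clusters: dict[str, list[Candidate]] = {}
    for g, r in zip(groups, reps):
        clusters.setdefault(uf.find(r.id), []).extend(g)
    return _build_loci(taxon, family, list(clusters.values()), decisions)


# ---------------------------------------------------------------------------
# Genome-guided mode


def parse_mapping_hits(path) -> list[MappingHit]:
    """BLAST tabular (12 columns); strand derived from sstart/send order."""
    hits = []
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) == 1:
                row = row[0].split()
            if len(row) != 12:
                raise ValueError(
                    f"{path}: row {lineno}: expected 12 mapping columns, got {len(row)}"
                )
            try:
                sstart, send = int(row[8]), int(row[9])
                hits.append(
                    MappingHit(
                        transcript_id=row[0],
                        scaffold=row[1],
                        strand="+" if sstart <= send else "-",
                        start=min(sstart, send),
                        end=max(sstart, send),
                        evalue=float(row[10]),
                        bitscore=float(row[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def coalesce_genome_guided(
    candidates: Sequence[Candidate],
    mapping_hits: Sequence[MappingHit],
    cfg: CoalesceConfig = CoalesceConfig(),
) -> LocusSet:
    """Merge candidates whose best genome intervals share a location.

    Candidates with no mapping passing ``cfg.map_evalue`` are coalesced with
    the de novo rules among themselves and their loci appended (logged).
    """
    if not candidates:
        raise ValueError("no candidates to coalesce")
    taxon, family = _check_inputs(candidates)
    ids = {c.id for c in candidates}
    best: dict[str, MappingHit] = {}
    for h in mapping_hits:
        if h.transcript_id not in ids or h.evalue >= cfg.map_evalue:
            continue
        cur = best.get(h.transcript_id)
        key = lambda m: (-m.bitscore, m.evalue, m.scaffold, m.start)
        if cur is None or key(h) < key(cur):
            best[h.transcript_id] = h
    mapped = [c for c in candidates if c.id in best]
    unmapped = [c for c in candidates if c.id not in best]

    decisions: list[MergeLog] = []
    clusters: list[list[Candidate]] = []
    by_loc: dict[tuple, list[Candidate]] = {}
    for c in mapped:
        h = best[c.id]
        by_loc.setdefault((h.scaffold, h.strand), []).append(c)
    for (scaffold, strand), group in sorted(by_loc.items()):
        group.sort(key=lambda c: (best[c.id].start, best[c.id].end, c.id))
        current: list[Candidate] = []
        current_end = None
        for c in group:
            h = best[c.id]
            if current and h.start <= current_end + 1 + cfg.merge_gap_bp:
                decisions.append(MergeLog(_rep(current).id, c.id, REASON_LOCATION))
                current.append(c)
                current_end = max(current_end, h.end)
            else:
                if current:
                    clusters.append(current)
                current = [c]
                current_end = h.end
        if current:
            clusters.append(current)

    if unmapped:
        logger.warning(
            "%s/%s: %d candidate(s) without a passing genome mapping; "
            "falling back to de novo rules: %s",
            taxon, family, len(unmapped), ",".join(sorted(c.id for c in unmapped)),
        )
        fallback = coalesce_denovo(unmapped, cfg)
        decisions.extend(fallback.decisions)
        id_map = {c.id: c for c in unmapped}
        for locus in fallback.loci:
            clusters.append([id_map[m] for m in locus.members])
    return _build_loci(taxon, family, clusters, decisions)


def write_locus_table(locus_sets: Iterable[LocusSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tfamily\tlocus_id\trepresentative_id\tmembers\n")
        for ls in locus_sets:
            for locus in ls.loci:
                fh.write(
                    f"{ls.taxon}\t{ls.family}\t{locus.locus_id}\t"
                    f"{locus.representative_id}\t{','.join(locus.members)}\n"
                )


def write_decision_log(locus_sets: Iterable[LocusSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tfamily\tid_a\tid_b\treason\tks\n")
        for ls in locus_sets:
            for d in ls.decisions:
                ks_txt = "" if d.ks is None else f"{d.ks:.6f}"
                fh.write(f"{ls.taxon}\t{ls.family}\t{d.id_a}\t{d.id_b}\t{d.reason}\t{ks_txt}\n")
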