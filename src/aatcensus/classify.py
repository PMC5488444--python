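"""Candidate transporter selection from domain- and homology-hit tables.

A transcript becomes a candidate when (i) it carries a qualifying family
domain hit (APC or AAAP accession, e-value below threshold), (ii) its best
homology hit — minimum e-value, ties broken by maximum bitscore then
subject id — is an APC/AAAP member from the required taxon group, and
(iii) it encodes an ORF of at least the configured length.  The taxon-group
check is what removes plant contaminants and other look-alike transporter
families without re-querying any external database.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .seqio import ORFRecord, Transcript, longest_orf

logger = logging.getLogger(__name__)

FAMILY_APC = "APC"
FAMILY_AAAP = "AAAP"

#: Pfam accessions of the two counted transporter families.
DEFAULT_FAMILY_ACCESSIONS = {"PF03024": FAMILY_APC, "PF01490": FAMILY_AAAP}

BLAST_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore subject_family subject_taxon_group"
).split()


@dataclass(frozen=True)
class DomainHit:
    transcript_id: str
    domain_accession: str
    evalue: float
    score: float

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"{self.transcript_id}: e-value must be > 0")


@dataclass(frozen=True)
class BlastHit:
    transcript_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float
    subject_family: str
    subject_taxon_group: str

    def __post_init__(self) -> None:
        if self.evalue <= 0:
            raise ValueError(f"{self.transcript_id}: e-value must be > 0")
        if self.bitscore < 0:
            raise ValueError(f"{self.transcript_id}: negative bitscore")


@dataclass(frozen=True)
class Candidate:
    transcript: Transcript
    family: str
    orf: ORFRecord

    @property
    def id(self) -> str:
        return self.transcript.id


@dataclass(frozen=True)
class ClassifyConfig:
    domain_evalue: float = 1e-3
    blast_evalue: float = 1e-3
    required_group: str = "hemiptera"
    family_accessions: dict = field(
        default_factory=lambda: dict(DEFAULT_FAMILY_ACCESSIONS)
    )
    min_orf_aa: int = 50
    on_missing_transcript: str = "warn"  # or "error"


def _read_rows(path, n_cols: int, what: str):
    with open(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            # tolerate space-delimited tables too
            if len(row) == 1:
                row = row[0].split()
            if len(row) != n_cols:
                raise ValueError(
                    f"{path}: row {lineno}: expected {n_cols} {what} columns, "
                    f"got {len(row)}"
                )
            yield lineno, row


def parse_domain_hits(path) -> list[DomainHit]:
    """Parse a 4-column domain-hit TSV (transcript, accession, evalue, score)."""
    hits = []
    for lineno, row in _read_rows(path, 4, "domain-hit"):
        try:
            hits.append(DomainHit(row[0], row[1], float(row[2]), float(row[3])))
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def parse_blast_hits(path) -> list[BlastHit]:
    """Parse BLAST tabular rows with two trailing annotation columns.

    Columns: the 12 standard tabular fields plus subject_family and
    subject_taxon_group.  Rows are kept in input order (ties preserved).
    """
    hits = []
    for lineno, row in _read_rows(path, len(BLAST_COLUMNS), "homology-hit"):
        try:
            hits.append(
                BlastHit(
                    transcript_id=row[0],
                    subject_id=row[1],
                    pct_identity=float(row[2]),
                    aln_len=int(row[3]),
                    evalue=float(row[10]),
                    bitscore=float(row[11]),
                    subject_family=row[12],
                    subject_taxon_group=row[13],
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {lineno}: {exc}") from exc
    return hits


def best_blast_hit(hits: Sequence[BlastHit]) -> Optional[BlastHit]:
    """Deterministic best hit: min e-value, then max bitscore, then subject id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def select_candidates(
    transcripts: Iterable[Transcript],
    domain_hits: Iterable[DomainHit],
    blast_hits: Iterable[BlastHit],
    cfg: ClassifyConfig = ClassifyConfig(),
) -> list[Candidate]:
    """Apply the domain filter, the best-hit verification, and the ORF check.

    Output order is sorted by (taxon, id), so the result is invariant under
    permutation of the inputs.
    """
    by_id = {t.id: t for t in transcripts}

    def _known(tid: str, table: str) -> bool:
        if tid in by_id:
            return True
        if cfg.on_missing_transcript == "error":
            raise KeyError(f"{table} hit references unknown transcript {tid!r}")
        logger.warning("%s hit references unknown transcript %r; skipped", table, tid)
        return False

    domain_by_tx: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        if _known(h.transcript_id, "domain"):
            domain_by_tx.setdefault(h.transcript_id, []).append(h)
    blast_by_tx: dict[str, list[BlastHit]] = {}
    for h in blast_hits:
        if _known(h.transcript_id, "homology"):
            blast_by_tx.setdefault(h.transcript_id, []).append(h)

    candidates = []
    for tid in sorted(by_id, key=lambda i: (by_id[i].taxon, i)):
        fam_hits = [
            h
            for h in domain_by_tx.get(tid, [])
            if h.domain_accession in cfg.family_accessions
            and h.evalue < cfg.domain_evalue
        ]
        if not fam_hits:
            continue
        best_dom = min(fam_hits, key=lambda h: (h.evalue, -h.score, h.domain_accession))
        best = best_blast_hit(blast_by_tx.get(tid, []))
        if best is None:
            logger.info("%s: qualifying domain hit but no homology rows; rejected", tid)
            continue
        if not (
            best.evalue < cfg.blast_evalue
            and best.subject_family in (FAMILY_APC, FAMILY_AAAP)
            and best.subject_taxon_group == cfg.required_group
        ):
            continue
        orf = longest_orf(by_id[tid].seq, min_aa=cfg.min_orf_aa)
        if orf is None:
            logger.info("%s: passes hit filters but no ORF >= %d aa; rejected",
                        tid, cfg.min_orf_aa)
            continue
        orf = ORFRecord(
            transcript_id=tid,
            frame=orf.frame,
            start_nt=orf.start_nt,
            end_nt=orf.end_nt,
            cds=orf.cds,
            protein=orf.protein,
        )
        candidates.append(
            Candidate(
                transcript=by_id[tid],
                family=cfg.family_accessions[best_dom.domain_accession],
                orf=orf,
            )
        )
    return candidates


def write_candidates(candidates: Iterable[Candidate], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "transcript_id\ttaxon\tcomponent_id\tfamily\tframe\t"
            "orf_start\torf_end\tcds\tprotein\n"
        )
        for c in candidates:
            o = c.orf
            fh.write(
                f"{c.id}\t{c.transcript.taxon}\t{c.transcript.component_id}\t"
                f"{c.family}\t{o.frame:+d}\t{o.start_nt}\t{o.end_nt}\t"
                f"{o.cds}\t{o.protein}\n"
            )


def read_candidates(path) -> list[Candidate]:
    """Read a table written by :func:`write_candidates`."""
    candidates = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            orf = ORFRecord(
                transcript_id=row["transcript_id"],
                frame=int(row["frame"]),
                start_nt=int(row["orf_start"]),
                end_nt=int(row["orf_end"]),
                cds=row["cds"],
                protein=row["protein"],
            )
            # the stored CDS is all downstream stages need; keep it as the seq
            tx = Transcript(
                id=row["transcript_id"],
                taxon=row["taxon"],
                component_id=row["component_id"],
                seq=row["cds"],
            )
            candidates.append(Candidate(transcript=tx, family=row["family"], orf=orf))
    return candidates
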