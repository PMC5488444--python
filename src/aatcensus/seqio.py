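"""Sequence I/O, ORF finding, translation, and pairwise codon alignments.

Transcripts are plain nucleotide sequences tagged with a taxon and an
assembler component id (the gene-level grouping assemblers attach to
isoforms).  ORFs are ATG-initiated, stop-terminated (or sequence-end
terminated) spans searched over all six frames.  Protein alignments are
pairwise affine-gap alignments used only to back-translate into codon
alignments for the synonymous-rate calculator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

# Standard genetic code, codons enumerated T,C,A,G by position.
_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE: dict[str, str] = {
    b1 + b2 + b3: _AA[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
STOP_CODONS = frozenset(c for c, a in CODON_TABLE.items() if a == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FRAMES = (1, 2, 3, -1, -2, -3)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_unambiguous(codon: str) -> bool:
    return len(codon) == 3 and all(b in "ACGT" for b in codon)


@dataclass(frozen=True)
class Transcript:
    """One assembled transcript: unique id, taxon, assembler component id."""

    id: str
    taxon: str
    component_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"{self.id}: empty sequence")


@dataclass(frozen=True)
class ORFRecord:
    """An ORF located on one of the six frames of a transcript.

    ``start_nt``/``end_nt`` are 0-based half-open coordinates on the frame's
    source strand (the transcript itself for +1..+3, its reverse complement
    for -1..-3).  ``cds`` excludes the terminal stop codon, so
    ``translate(cds) == protein`` and ``end_nt - start_nt == len(cds)``.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    cds: str
    protein: str


def translate(cds: str, ambiguous: str = "error") -> str:
    """Translate a CDS with the standard code.

    The terminal stop codon, if present, is dropped.  An internal stop or a
    length not divisible by 3 raises ``ValueError``.  ``ambiguous`` controls
    codons containing non-ACGT characters: ``"error"`` raises, ``"X"`` emits
    an X residue.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper().replace("U", "T")
    aas = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if not is_unambiguous(codon):
            if ambiguous == "X":
                aas.append("X")
                continue
            raise ValueError(f"ambiguous codon {codon!r} at codon {i}")
        aa = CODON_TABLE[codon]
        if aa == "*":
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i}")
        aas.append(aa)
    return "".join(aas)


def longest_orf(
    seq: str, min_aa: int = 50, allow_ambiguous: bool = False
) -> Optional[ORFRecord]:
    """Longest ATG-initiated ORF over all six frames, or None.

    Stops may terminate an ORF, or the sequence end may (open 3' end, as in
    truncated transcripts).  Ambiguous bases inside a candidate span
    disqualify it unless ``allow_ambiguous`` (then translated as X).
    Ties break toward forward frames, lower frame index, smaller start.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper().replace("U", "T")
    best: Optional[ORFRecord] = None
    for frame in FRAMES:
        source = seq if frame > 0 else reverse_complement(seq)
        off = abs(frame) - 1
        n_codons = (len(source) - off) // 3
        codons = [source[off + 3 * i : off + 3 * i + 3] for i in range(n_codons)]
        # segment = maximal run of codons between stops (stops excluded)
        seg_start = 0
        for idx in range(n_codons + 1):
            at_stop = idx < n_codons and is_unambiguous(codons[idx]) and CODON_TABLE[
                codons[idx]
            ] == "*"
            if idx < n_codons and not at_stop:
                continue
            seg = range(seg_start, idx)
            has_stop = idx < n_codons
            cand = _best_in_segment(
                codons, seg, has_stop, off, frame, min_aa, allow_ambiguous
            )
            if cand is not None and (best is None or len(cand.protein) > len(best.protein)):
                best = cand
            seg_start = idx + 1
    return best


def _best_in_segment(codons, seg, has_stop, off, frame, min_aa, allow_ambiguous):
    """Longest valid ATG-initiated ORF within a stop-free codon segment."""
    seg = list(seg)
    if not seg:
        return None
    if allow_ambiguous:
        min_start = seg[0]
    else:
        last_ambig = max((i for i in seg if not is_unambiguous(codons[i])), default=None)
        min_start = seg[0] if last_ambig is None else last_ambig + 1
    atg = next((i for i in seg if i >= min_start and codons[i] == "ATG"), None)
    if atg is None:
        return None
    end_codon = seg[-1] + 1  # exclusive, before the stop
    protein = "".join(
        CODON_TABLE[codons[i]] if is_unambiguous(codons[i]) else "X"
        for i in range(atg, end_codon)
    )
    if len(protein) < min_aa:
        return None
    cds = "".join(codons[atg:end_codon])
    return ORFRecord(
        transcript_id="",
        frame=frame,
        start_nt=off + 3 * atg,
        end_nt=off + 3 * end_codon,
        cds=cds,
        protein=protein,
    )


# ---------------------------------------------------------------------------
# FASTA

_HEADER_KV = re.compile(r"(\w+)=(\S+)")


def read_fasta(
    path,
    taxon: Optional[str] = None,
    component_key: str = "comp",
    taxon_key: str = "taxon",
    require_component: bool = True,
) -> list[Transcript]:
    """Read transcripts from FASTA with ``id key=value ...`` headers.

    ``taxon`` overrides any per-record taxon tag.  Sequences are upper-cased
    and U is mapped to T.  Duplicate ids raise.
    """
    _check_fasta_shape(path)
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(_HEADER_KV.findall(rec.description))
        tx_taxon = taxon if taxon is not None else tags.get(taxon_key, "")
        comp = tags.get(component_key, "")
        if require_component and not comp:
            raise ValueError(
                f"{path}: record {rec.id!r} lacks the {component_key}= header tag"
            )
        if not tx_taxon:
            raise ValueError(
                f"{path}: record {rec.id!r} lacks a taxon (no {taxon_key}= tag and "
                "no explicit taxon given)"
            )
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate transcript id {rec.id!r}")
        seen.add(rec.id)
        transcripts.append(
            Transcript(
                id=rec.id,
                taxon=tx_taxon,
                component_id=comp,
                seq=str(rec.seq).upper().replace("U", "T"),
            )
        )
    return transcripts


def _check_fasta_shape(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno}: expected FASTA header, got "
                        f"{line.strip()[:40]!r}"
                    )
                return


def write_fasta(transcripts: Iterable[Transcript], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id} taxon={t.taxon} comp={t.component_id}\n")
            for i in range(0, len(t.seq), width):
                fh.write(t.seq[i : i + width] + "\n")


def write_orf_table(orfs: Iterable[ORFRecord], path) -> None:
    """TSV of ORFs; coordinates exported 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("transcript_id\tframe\tstart\tend\taa_len\n")
        for o in orfs:
            fh.write(
                f"{o.transcript_id}\t{o.frame:+d}\t{o.start_nt + 1}\t{o.end_nt}\t"
                f"{len(o.protein)}\n"
            )


# ---------------------------------------------------------------------------
# Pairwise protein alignment and codon back-translation


@dataclass(frozen=True)
class ProteinAlignment:
    a: str  # gapped sequence
    b: str
    score: float


@lru_cache(maxsize=8)
def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float,
                  penalize_ends: bool) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # a gap of length L costs gap_open + gap_extend * L
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if not penalize_ends:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython attribute names
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def align_proteins_global(
    p_a: str,
    p_b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    penalize_ends: bool = False,
) -> ProteinAlignment:
    """Global affine-gap protein alignment, deterministic traceback.

    End gaps are free by default so that a fragment aligns inside a
    full-length partner and two non-overlapping fragments align with
    (near-)zero overlap — the overlap semantics the collapse rules need.
    """
    if not p_a or not p_b:
        raise ValueError("cannot align empty protein")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend, penalize_ends)
    aln = aligner.align(p_a, p_b)[0]
    return ProteinAlignment(a=str(aln[0]), b=str(aln[1]), score=aln.score)


@dataclass(frozen=True)
class CodonAlignment:
    """Codon-level pairing induced by a protein alignment.

    ``pairs`` holds (codon_a, codon_b) with None for a gap.  ``overlap_bp``
    counts both-present columns times 3.
    """

    pairs: tuple
    overlap_bp: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "overlap_bp",
            3 * sum(1 for a, b in self.pairs if a is not None and b is not None),
        )


def _strip_terminal_stop(cds: str, n_aa: int) -> str:
    if len(cds) == 3 * n_aa + 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    if len(cds) != 3 * n_aa:
        raise ValueError(
            f"CDS length {len(cds)} inconsistent with protein length {n_aa}"
        )
    return cds


def codon_alignment(aln: ProteinAlignment, cds_a: str, cds_b: str) -> CodonAlignment:
    """Map an aligned protein pair back onto its source codons."""
    if len(aln.a) != len(aln.b):
        raise ValueError("gapped alignment strings differ in length")
    ungapped_a = aln.a.replace("-", "")
    ungapped_b = aln.b.replace("-", "")
    cds_a = _strip_terminal_stop(cds_a.upper(), len(ungapped_a))
    cds_b = _strip_terminal_stop(cds_b.upper(), len(ungapped_b))
    pairs = []
    i = j = 0
    for ra, rb in zip(aln.a, aln.b):
        ca = cb = None
        if ra != "-":
            ca = cds_a[3 * i : 3 * i + 3]
            i += 1
        if rb != "-":
            cb = cds_b[3 * j : 3 * j + 3]
            j += 1
        pairs.append((ca, cb))
    return CodonAlignment(pairs=tuple(pairs))
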