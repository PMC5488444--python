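"""Synthetic inputs for the whole pipeline, with truth tables.

Everything the analysis consumes can be generated here from an explicit
config and seed: a pure-birth species tree, life-history labels, true
per-family locus counts (Brownian motion on the tree plus a life-history
shift), per-taxon transcript sets with isoform/fragment/paralog structure,
matching mock domain- and homology-hit tables, optional genome mapping
tables, and a per-transcript truth table for recovery testing.

Paralog divergence is achieved by iteratively applying random substitutions
and re-measuring Ks with the package's own calculator until a target is
reached, so the generator and the estimator agree by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import ks as ksmod
from .classify import BLAST_COLUMNS, BlastHit, DomainHit
from .coalesce import MappingHit
from .phylo import brownian_vcv, parse_newick
from .seqio import SENSE_CODONS, STOP_CODONS, Transcript, longest_orf, write_fasta

logger = logging.getLogger(__name__)

ROLE_REPRESENTATIVE = "paralog-representative"
ROLE_ISOFORM = "isoform"
ROLE_FRAGMENT = "fragment"
ROLE_CONTAMINANT = "contaminant"
ROLE_BACKGROUND = "background"

_ACC_BY_FAMILY = {"APC": "PF03024", "AAAP": "PF01490"}


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_taxa: int = 8
    birth_rate: float = 1.0
    sigma2: float = 1.0
    delta: float = 7.0
    baseline: dict = field(default_factory=lambda: {"APC": 10.0, "AAAP": 14.0})
    free_living_fraction: float = 0.4
    isoforms_per_locus: tuple = (1, 3)
    fragment_prob: float = 0.25
    split_locus_prob: float = 0.05
    paralog_ks: tuple = (0.5, 0.7)
    omega: float = 0.15  # acceptance prob. for nonsynonymous substitutions
    isoform_max_subs: int = 2
    contaminant_fraction: float = 0.1
    background_n: int = 20
    cds_len_range: tuple = (360, 900)
    utr_len_range: tuple = (30, 120)
    label_noise: float = 0.0
    genome_mode: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_taxa < 3:
            raise ValueError("need at least 3 taxa")
        for name in ("free_living_fraction", "fragment_prob", "split_locus_prob",
                     "contaminant_fraction", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.birth_rate <= 0 or self.sigma2 < 0:
            raise ValueError("rates must be positive")


@dataclass
class TaxonBundle:
    taxon: str
    transcripts: list
    domain_hits: list
    blast_hits: list
    mapping_hits: list
    truth: list  # dicts: transcript_id, taxon, family, true_locus, role


@dataclass
class SimBundle:
    config: SimConfig
    newick: str
    tree: dendropy.Tree
    life_history: dict
    true_counts: pd.DataFrame  # taxon, family, count
    taxa: list
    transcripts: list
    domain_hits: list
    blast_hits: list
    mapping_hits: list
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Tree, life history, counts


def simulate_tree(n_taxa: int, birth_rate: float, seed) -> dendropy.Tree:
    """Ultrametric pure-birth tree with tips T01..Tnn, deterministic per seed."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = _as_rng(seed)
    next_id = [0]

    def leaf():
        next_id[0] += 1
        return {"children": [], "birth": None, "label": None}

    root = {"children": [leaf(), leaf()], "birth": 0.0, "label": None}
    active = list(root["children"])
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node["birth"] = t
        node["children"] = [leaf(), leaf()]
        active.extend(node["children"])
    t_end = t + rng.exponential(1.0 / (birth_rate * len(active)))
    labels = iter(f"T{i + 1:02d}" for i in range(n_taxa))
    for node in active:
        node["birth"] = t_end
        node["label"] = next(labels)

    def newick(node, parent_birth):
        bl = node["birth"] - parent_birth
        if node["children"]:
            inner = ",".join(newick(c, node["birth"]) for c in node["children"])
            return f"({inner}):{bl:.10f}"
        return f"{node['label']}:{bl:.10f}"

    text = "(" + ",".join(newick(c, 0.0) for c in root["children"]) + "):0.0;"
    return parse_newick(text)


def simulate_life_history(
    taxa: Sequence[str], free_living_fraction: float, seed
) -> dict[str, str]:
    """Random assignment with at least one taxon per group."""
    rng = _as_rng(seed)
    n = len(taxa)
    n_free = int(np.clip(round(free_living_fraction * n), 1, n - 1))
    free = set(rng.choice(n, size=n_free, replace=False).tolist())
    return {t: ("free_living" if i in free else "galling") for i, t in enumerate(taxa)}


def simulate_counts(
    tree: dendropy.Tree,
    life_history: dict,
    sigma2: float,
    delta: float,
    baseline: dict,
    seed,
) -> pd.DataFrame:
    """Latent = baseline + Brownian(σ²·C) + δ·1[free-living]; count = max(1, round)."""
    rng = _as_rng(seed)
    taxa = sorted(life_history)
    C = brownian_vcv(tree, taxa)
    L = np.linalg.cholesky(C + 1e-12 * np.eye(len(taxa))) if sigma2 > 0 else None
    ind = np.array([1.0 if life_history[t] == "free_living" else 0.0 for t in taxa])
    rows = []
    for family in sorted(baseline):
        latent = np.full(len(taxa), float(baseline[family])) + delta * ind
        if L is not None:
            latent = latent + np.sqrt(sigma2) * (L @ rng.standard_normal(len(taxa)))
        counts = np.maximum(1, np.rint(latent).astype(int))
        rows.extend(
            {"taxon": t, "family": family, "count": int(c)}
            for t, c in zip(taxa, counts)
        )
    return pd.DataFrame(rows, columns=["taxon", "family", "count"])


# ---------------------------------------------------------------------------
# Sequences


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _random_codons(n: int, rng) -> list[str]:
    return [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n)]


def _random_nt(n: int, rng) -> str:
    return "".join("ACGT"[i] for i in rng.integers(4, size=n))


def random_cds(n_codons: int, rng, internal_atg_at: Optional[int] = None) -> str:
    """ATG + random sense codons + stop; optionally plant an internal ATG."""
    body = _random_codons(n_codons - 2, rng)
    if internal_atg_at is not None:
        body[internal_atg_at - 1] = "ATG"
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
    return "ATG" + "".join(body) + stop


def _apply_subs(
    cds: str, n_subs: int, rng, protected: frozenset, omega: float = 1.0
) -> str:
    """Random substitutions that never create a stop or touch protected codons.

    ``omega`` is the acceptance probability for nonsynonymous proposals —
    values well below 1 mimic purifying selection, keeping the encoded
    protein alignable at high synonymous divergence.
    """
    from .seqio import CODON_TABLE

    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    done = 0
    while done < n_subs:
        ci = int(rng.integers(1, len(codons) - 1))
        if ci in protected:
            continue
        pos = int(rng.integers(3))
        base = "ACGT"[int(rng.integers(4))]
        codon = codons[ci]
        if base == codon[pos]:
            continue
        mut = codon[:pos] + base + codon[pos + 1 :]
        if mut in STOP_CODONS:
            continue
        if CODON_TABLE[mut] != CODON_TABLE[codon] and rng.random() > omega:
            continue
        codons[ci] = mut
        done += 1
    return "".join(codons)


def mutate_to_ks(
    cds: str,
    target: float,
    rng,
    tol: float = 0.10,
    protected: frozenset = frozenset(),
    omega: float = 1.0,
    max_iter: Optional[int] = None,
) -> tuple[str, float]:
    """Substitute until the measured Ks against the source reaches target±tol.

    Measures with the package's own calculator on the positional codon
    pairing (sequences stay equal-length).  Raises if the target is not
    reached within ``max_iter`` substitutions.
    """
    if max_iter is None:
        max_iter = 60 * len(cds) // 3
    current = cds
    lo, hi = target * (1 - tol), target * (1 + tol)
    stride = max(1, len(cds) // 120)
    applied = 0
    realized = 0.0
    while applied < max_iter:
        r = ksmod.ks_equal_length(cds, current)
        realized = r.ks if r.ok else float("inf")
        if realized >= lo:
            break
        gap_small = r.ok and realized >= target * (1 - 3 * tol)
        step = 1 if gap_small else stride
        current = _apply_subs(current, step, rng, protected, omega=omega)
        applied += step
    if not (lo <= realized):
        raise RuntimeError(
            f"could not reach Ks target {target:.3f} after {applied} substitutions"
        )
    if realized > hi:
        raise RuntimeError(
            f"overshot Ks target {target:.3f} (realized {realized:.3f})"
        )
    return current, realized


def _wrap_with_utrs(
    coding: str,
    expected_orf_cds: str,
    cfg: SimConfig,
    rng,
    lead5: bool = True,
    tail3: bool = True,
    min_aa: int = 50,
) -> str:
    """Attach random UTRs, verifying the planted CDS stays the longest ORF.

    Random flanks occasionally create a longer competing ORF (often an
    open-ended reverse-strand one); those draws are rejected so the truth
    table stays consistent with what the ORF finder will report.
    """
    for _ in range(40):
        utr5 = _random_nt(int(rng.integers(*cfg.utr_len_range)), rng) if lead5 else ""
        utr3 = _random_nt(int(rng.integers(*cfg.utr_len_range)), rng) if tail3 else ""
        seq = utr5 + coding + utr3
        orf = longest_orf(seq, min_aa=min_aa)
        if orf is not None and orf.frame > 0 and orf.cds == expected_orf_cds:
            return seq
    raise RuntimeError("could not embed CDS without a competing ORF")


# ---------------------------------------------------------------------------
# Per-taxon transcriptome with mock hit tables


def _aat_blast_rows(tid: str, family: str, aa_len: int, rng) -> list[BlastHit]:
    best = BlastHit(
        transcript_id=tid,
        subject_id=f"hemi_{family}_{int(rng.integers(1, 50)):03d}",
        pct_identity=float(np.round(70 + 25 * rng.random(), 2)),
        aln_len=aa_len,
        evalue=10.0 ** -float(rng.uniform(60, 120)),
        bitscore=float(np.round(300 + 400 * rng.random(), 1)),
        subject_family=family,
        subject_taxon_group="hemiptera",
    )
    decoy = BlastHit(
        transcript_id=tid,
        subject_id=f"other_tx_{int(rng.integers(1, 50)):03d}",
        pct_identity=float(np.round(30 + 20 * rng.random(), 2)),
        aln_len=aa_len // 2,
        evalue=10.0 ** -float(rng.uniform(3, 10)),
        bitscore=float(np.round(40 + 60 * rng.random(), 1)),
        subject_family="OTHER",
        subject_taxon_group="other",
    )
    return [best, decoy]


def simulate_transcriptome(
    taxon: str, true_counts: dict, cfg: SimConfig, seed
) -> TaxonBundle:
    """Transcripts plus consistent mock hit tables for one taxon.

    For each true locus: one full-length representative, optional extra
    isoforms (few substitutions) and truncated fragments sharing its
    component id — or, with ``split_locus_prob``, a pair of fragments in two
    separate components overlapping by only 30 bp (an assembler-split
    locus).  Distinct loci are diverged to Ks targets drawn from
    ``paralog_ks``.  Contaminants carry plant best hits; background
    transcripts carry no domain hits.
    """
    rng = _as_rng(seed)
    bundle = TaxonBundle(taxon, [], [], [], [], [])
    comp_counter = [0]
    scaffold_cursor: dict[str, int] = {}

    def new_component() -> str:
        comp_counter[0] += 1
        return f"c{comp_counter[0]}"

    def add_transcript(tid, comp, seq, family, locus, role):
        bundle.transcripts.append(
            Transcript(id=tid, taxon=taxon, component_id=comp, seq=seq)
        )
        bundle.truth.append(
            {
                "transcript_id": tid,
                "taxon": taxon,
                "family": family,
                "true_locus": locus,
                "role": role,
            }
        )

    def add_aat_hits(tid, family, aa_len):
        noisy = cfg.label_noise > 0 and rng.random() < cfg.label_noise
        bundle.domain_hits.append(
            DomainHit(
                transcript_id=tid,
                domain_accession=_ACC_BY_FAMILY[family],
                evalue=0.01 if noisy else 10.0 ** -float(rng.uniform(8, 40)),
                score=float(np.round(50 + 400 * rng.random(), 1)),
            )
        )
        bundle.blast_hits.extend(_aat_blast_rows(tid, family, aa_len, rng))

    n_loci_total = 0
    for family in sorted(true_counts):
        k = int(true_counts[family])
        if k < 1:
            raise ValueError(f"{taxon}/{family}: true count must be >= 1")
        n_loci_total += k
        n_codons = int(rng.integers(cfg.cds_len_range[0] // 3,
                                    cfg.cds_len_range[1] // 3 + 1))
        # plant an internal ATG usable as a 3' fragment start; both halves of
        # a split locus must clear the 50-aa ORF minimum
        mid_lo = max(55, n_codons * 2 // 5)
        mid_hi = min(n_codons - 57, n_codons * 3 // 5)
        if mid_hi < mid_lo:
            raise ValueError(
                f"cds_len_range too short for split loci (got {3 * n_codons} nt)"
            )
        mid = int(rng.integers(mid_lo, mid_hi + 1))
        base = random_cds(n_codons, rng, internal_atg_at=mid)
        protected = frozenset({0, mid, n_codons - 1})
        loci_cds = [base]
        for _ in range(1, k):
            target = float(rng.uniform(*cfg.paralog_ks))
            mutated, _realized = mutate_to_ks(
                base, target, rng, protected=protected, omega=cfg.omega
            )
            loci_cds.append(mutated)
        for li, cds in enumerate(loci_cds, start=1):
            locus_id = f"{taxon}|{family}|true{li:03d}"
            if cfg.split_locus_prob > 0 and rng.random() < cfg.split_locus_prob:
                # assembler-split locus: 5' and 3' fragments, 30 bp overlap,
                # in two different components
                cut = 3 * mid
                frag5 = _wrap_with_utrs(cds[: cut + 30], cds[: cut + 30],
                                        cfg, rng, tail3=False)
                frag3 = _wrap_with_utrs(cds[cut:], cds[cut:-3],
                                        cfg, rng, lead5=False)
                for part, seq in (("a", frag5), ("b", frag3)):
                    tid = f"{taxon}_{family}_{li:03d}{part}"
                    add_transcript(tid, new_component(), seq, family, locus_id,
                                   ROLE_FRAGMENT)
                    add_aat_hits(tid, family, len(seq) // 3)
                self_hits = [(f"{taxon}_{family}_{li:03d}a", 1, cut + 30),
                             (f"{taxon}_{family}_{li:03d}b", cut + 1, len(cds))]
            else:
                comp = new_component()
                n_iso = int(rng.integers(cfg.isoforms_per_locus[0],
                                         cfg.isoforms_per_locus[1] + 1))
                self_hits = []
                for j in range(n_iso):
                    tid = f"{taxon}_{family}_{li:03d}i{j + 1}"
                    if j == 0:
                        seq = _wrap_with_utrs(cds, cds[:-3], cfg, rng)
                        role = ROLE_REPRESENTATIVE
                        span = (1, len(cds))
                    else:
                        var = _apply_subs(
                            cds, int(rng.integers(0, cfg.isoform_max_subs + 1)),
                            rng, protected, omega=cfg.omega)
                        if rng.random() < cfg.fragment_prob:
                            # 3'-truncated fragment, at least 60 codons
                            keep = int(rng.integers(60, max(61, len(cds) // 3 - 10)))
                            seq = _wrap_with_utrs(var[: 3 * keep], var[: 3 * keep],
                                                  cfg, rng, tail3=False)
                            role = ROLE_FRAGMENT
                            span = (1, 3 * keep)
                        else:
                            seq = _wrap_with_utrs(var, var[:-3], cfg, rng)
                            role = ROLE_ISOFORM
                            span = (1, len(cds))
                    add_transcript(tid, comp, seq, family, locus_id, role)
                    add_aat_hits(tid, family, len(seq) // 3)
                    self_hits.append((tid, *span))
            if cfg.genome_mode:
                scaffold = f"scf_{taxon}_{family}"
                offset = scaffold_cursor.get(scaffold, 10_000)
                strand = "+" if rng.random() < 0.5 else "-"
                for tid, lo, hi in self_hits:
                    bundle.mapping_hits.append(
                        MappingHit(
                            transcript_id=tid,
                            scaffold=scaffold,
                            strand=strand,
                            start=offset + lo,
                            end=offset + hi,
                            evalue=1e-60,
                            bitscore=float(hi - lo + 1),
                        )
                    )
                # distinct loci stay well beyond the merge gap
                scaffold_cursor[scaffold] = offset + len(cds) + 50_000

    n_cont = int(round(cfg.contaminant_fraction * n_loci_total))
    for ci in range(1, n_cont + 1):
        tid = f"{taxon}_cont{ci:03d}"
        n_codons = int(rng.integers(100, 300))
        seq = random_cds(n_codons, rng)
        family = ("APC", "AAAP")[int(rng.integers(2))]
        add_transcript(tid, new_component(), seq, family, "", ROLE_CONTAMINANT)
        bundle.domain_hits.append(
            DomainHit(tid, _ACC_BY_FAMILY[family],
                      10.0 ** -float(rng.uniform(5, 20)), 120.0)
        )
        bundle.blast_hits.append(
            BlastHit(
                transcript_id=tid,
                subject_id=f"plant_{family}_{ci:03d}",
                pct_identity=85.0,
                aln_len=n_codons,
                evalue=10.0 ** -float(rng.uniform(80, 150)),
                bitscore=900.0,
                subject_family=family,
                subject_taxon_group="plant",
            )
        )
        bundle.blast_hits.append(
            BlastHit(
                transcript_id=tid,
                subject_id=f"hemi_{family}_999",
                pct_identity=40.0,
                aln_len=n_codons // 2,
                evalue=10.0 ** -float(rng.uniform(5, 15)),
                bitscore=90.0,
                subject_family=family,
                subject_taxon_group="hemiptera",
            )
        )
    for bi in range(1, cfg.background_n + 1):
        tid = f"{taxon}_bg{bi:03d}"
        seq = _random_nt(int(rng.integers(300, 1200)), rng)
        add_transcript(tid, new_component(), seq, "", "", ROLE_BACKGROUND)
        if rng.random() < 0.5:
            bundle.blast_hits.append(
                BlastHit(
                    transcript_id=tid,
                    subject_id=f"misc_{bi:03d}",
                    pct_identity=50.0,
                    aln_len=80,
                    evalue=1e-5,
                    bitscore=60.0,
                    subject_family="OTHER",
                    subject_taxon_group="hemiptera",
                )
            )
    return bundle


def simulate_bundle(cfg: SimConfig) -> SimBundle:
    """Full multi-taxon input set: tree, labels, counts, transcripts, tables."""
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_lh, s_counts, s_tx = ss.spawn(4)
    tree = simulate_tree(cfg.n_taxa, cfg.birth_rate, _as_rng(s_tree))
    taxa = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    life_history = simulate_life_history(taxa, cfg.free_living_fraction, _as_rng(s_lh))
    true_counts = simulate_counts(
        tree, life_history, cfg.sigma2, cfg.delta, cfg.baseline, _as_rng(s_counts)
    )
    bundle = SimBundle(
        config=cfg,
        newick=tree.as_string(schema="newick").strip(),
        tree=tree,
        life_history=life_history,
        true_counts=true_counts,
        taxa=taxa,
        transcripts=[],
        domain_hits=[],
        blast_hits=[],
        mapping_hits=[],
        truth=None,
    )
    truth_rows = []
    for taxon, child in zip(taxa, s_tx.spawn(len(taxa))):
        per_family = {
            r["family"]: r["count"]
            for _, r in true_counts[true_counts["taxon"] == taxon].iterrows()
        }
        tb = simulate_transcriptome(taxon, per_family, cfg, _as_rng(child))
        bundle.transcripts.extend(tb.transcripts)
        bundle.domain_hits.extend(tb.domain_hits)
        bundle.blast_hits.extend(tb.blast_hits)
        bundle.mapping_hits.extend(tb.mapping_hits)
        truth_rows.extend(tb.truth)
    bundle.truth = pd.DataFrame(
        truth_rows, columns=["transcript_id", "taxon", "family", "true_locus", "role"]
    )
    return bundle


# ---------------------------------------------------------------------------
# Writing bundles to disk


def _write_domain_hits(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("#transcript_id\tdomain_accession\tevalue\tscore\n")
        for h in hits:
            fh.write(f"{h.transcript_id}\t{h.domain_accession}\t{h.evalue:.3e}\t{h.score:.1f}\n")


def _write_blast_hits(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BLAST_COLUMNS) + "\n")
        for h in hits:
            qend = 3 * h.aln_len
            fh.write(
                f"{h.transcript_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t"
                f"{h.aln_len}\t0\t0\t1\t{qend}\t1\t{h.aln_len}\t"
                f"{h.evalue:.3e}\t{h.bitscore:.1f}\t{h.subject_family}\t"
                f"{h.subject_taxon_group}\n"
            )


def _write_mapping_hits(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = (h.start, h.end) if h.strand == "+" else (h.end, h.start)
            qlen = h.end - h.start + 1
            fh.write(
                f"{h.transcript_id}\t{h.scaffold}\t98.00\t{qlen}\t0\t0\t1\t{qlen}\t"
                f"{sstart}\t{send}\t{h.evalue:.3e}\t{h.bitscore:.1f}\n"
            )


def write_bundle(bundle: SimBundle, outdir, force: bool = False) -> dict:
    """Write every artifact plus a manifest with config and checksums."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists and is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.transcripts, outdir / "transcripts.fasta")
    _write_domain_hits(bundle.domain_hits, outdir / "domain_hits.tsv")
    _write_blast_hits(bundle.blast_hits, outdir / "blast_hits.tsv")
    files = ["transcripts.fasta", "domain_hits.tsv", "blast_hits.tsv"]
    if bundle.mapping_hits:
        _write_mapping_hits(bundle.mapping_hits, outdir / "mapping_hits.tsv")
        files.append("mapping_hits.tsv")
    (outdir / "tree.nwk").write_text(bundle.newick + "\n")
    with open(outdir / "life_history.tsv", "w") as fh:
        fh.write("taxon\tlife_history\n")
        for taxon in bundle.taxa:
            fh.write(f"{taxon}\t{bundle.life_history[taxon]}\n")
    bundle.true_counts.to_csv(outdir / "true_counts.tsv", sep="\t", index=False)
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    files += ["tree.nwk", "life_history.tsv", "true_counts.tsv", "truth.tsv"]
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "checksums": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
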