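"""Transcript-to-locus collapsing, de novo and genome-guided."""

import itertools
import random

import numpy as np
import pytest

from aatcensus import coalesce as coal
from aatcensus import simulate as sim
from aatcensus.classify import Candidate
from aatcensus.seqio import ORFRecord, Transcript, translate


def _cand(tid, cds, comp, taxon="T1", family="APC"):
    protein = translate(cds)
    return Candidate(
        transcript=Transcript(id=tid, taxon=taxon, component_id=comp, seq=cds),
        family=family,
        orf=ORFRecord(transcript_id=tid, frame=1, start_nt=0, end_nt=len(cds),
                      cds=cds, protein=protein),
    )


@pytest.fixture(scope="module")
def family_cds():
    """Three locus CDSs: A and B near-identical, C deeply diverged."""
    rng = np.random.default_rng(101)
    base = sim.random_cds(160, rng)[:-3]  # drop stop; ORF-style cds
    near, _ = sim.mutate_to_ks(base, 0.10, rng, omega=0.2)
    far, _ = sim.mutate_to_ks(base, 0.60, rng, omega=0.2)
    return base, near, far


# ---------------------------------------------------------------------------
# component collapse


def test_collapse_by_component_groups_isoforms(family_cds):
    base, near, _ = family_cds
    cands = [
        _cand("iso1", base, "c7"),
        _cand("iso2", base[:300], "c7"),
        _cand("iso3", near, "c7"),
    ]
    groups = coal.collapse_by_component(cands)
    assert len(groups) == 1
    assert coal._rep(groups[0]).id in ("iso1", "iso3")
    assert len(coal._rep(groups[0]).orf.protein) == len(base) // 3


def test_collapse_by_component_distinct(family_cds):
    base, *_ = family_cds
    cands = [_cand(f"t{i}", base, f"c{i}") for i in range(4)]
    assert len(coal.collapse_by_component(cands)) == 4


def test_collapse_by_component_tie_lexicographic(family_cds):
    base, *_ = family_cds
    cands = [_cand("zz", base, "c1"), _cand("aa", base, "c1")]
    assert coal._rep(coal.collapse_by_component(cands)[0]).id == "aa"


# ---------------------------------------------------------------------------
# pair decisions


def test_pair_decision_low_ks_collapses(family_cds):
    base, near, _ = family_cds
    d = coal.pair_decision(_cand("a", base, "c1"), _cand("b", near, "c2"))
    assert d.collapse and d.reason == coal.REASON_KS
    assert d.ks.ks < 0.25


def test_pair_decision_high_ks_keeps(family_cds):
    base, _, far = family_cds
    d = coal.pair_decision(_cand("a", base, "c1"), _cand("b", far, "c2"))
    assert not d.collapse
    assert d.ks.ks > 0.25


def test_pair_decision_short_overlap_collapses(family_cds):
    base, *_ = family_cds
    # two fragments sharing only 30 bp (10 codons)
    cut = 210
    frag5 = base[: cut + 30]
    frag3 = base[cut:]
    # frag3 must start with ATG to be an ORF-like cds in this synthetic setup
    frag3 = "ATG" + frag3[3:]
    d = coal.pair_decision(_cand("a", frag5, "c1"), _cand("b", frag3, "c2"))
    assert d.collapse and d.reason == coal.REASON_OVERLAP


def test_pair_decision_threshold_config(family_cds):
    base, near, _ = family_cds
    strict = coal.CoalesceConfig(ks_threshold=0.01)
    d = coal.pair_decision(_cand("a", base, "c1"), _cand("b", near, "c2"), strict)
    assert not d.collapse


# ---------------------------------------------------------------------------
# de novo coalescing


def test_coalesce_transitive_closure(family_cds):
    """collapse(A,B) and collapse(B,C) must union all three."""
    rng = np.random.default_rng(5)
    a = sim.random_cds(150, rng)[:-3]
    b, _ = sim.mutate_to_ks(a, 0.18, rng, omega=0.2)
    c, _ = sim.mutate_to_ks(b, 0.18, rng, omega=0.2)
    cands = [_cand("A", a, "c1"), _cand("B", b, "c2"), _cand("C", c, "c3")]
    dAB = coal.pair_decision(cands[0], cands[1])
    dBC = coal.pair_decision(cands[1], cands[2])
    assert dAB.collapse and dBC.collapse
    ls = coal.coalesce_denovo(cands)
    # oracle: union-find over the explicit pair matrix
    uf = {x: x for x in "ABC"}

    def find(x):
        while uf[x] != x:
            x = uf[x]
        return x

    for x, y in itertools.combinations(range(3), 2):
        if coal.pair_decision(cands[x], cands[y]).collapse:
            uf[find("ABC"[y])] = find("ABC"[x])
    n_oracle = len({find(x) for x in "ABC"})
    assert ls.count == n_oracle
    if dAB.collapse and dBC.collapse:
        assert ls.count == 1
        assert ls.loci[0].members == ("A", "B", "C")


def test_coalesce_no_pairs_identity(family_cds):
    base, _, far = family_cds
    rng = np.random.default_rng(17)
    far2, _ = sim.mutate_to_ks(far, 0.55, rng, omega=0.2)
    cands = [_cand("A", base, "c1"), _cand("B", far, "c2"), _cand("C", far2, "c3")]
    ls = coal.coalesce_denovo(cands)
    assert ls.count == len(cands)


def test_coalesce_two_loci_three_isoforms_each(family_cds):
    base, near, far = family_cds
    cands = []
    for i, cds in enumerate((base, near, base[:300])):
        cands.append(_cand(f"l1_{i}", cds, "c1"))
    rng = np.random.default_rng(23)
    far_iso, _ = sim.mutate_to_ks(far, 0.05, rng, omega=0.2)
    for i, cds in enumerate((far, far_iso, far[:330])):
        cands.append(_cand(f"l2_{i}", cds, "c2"))
    ls = coal.coalesce_denovo(cands)
    assert ls.count == 2


def test_coalesce_partition_and_representative(family_cds):
    base, near, far = family_cds
    cands = [
        _cand("a1", base, "c1"),
        _cand("a2", near, "c2"),
        _cand("b1", far, "c3"),
    ]
    ls = coal.coalesce_denovo(cands)
    members = sorted(m for locus in ls.loci for m in locus.members)
    assert members == ["a1", "a2", "b1"]
    by_id = {c.id: c for c in cands}
    for locus in ls.loci:
        rep_len = len(by_id[locus.representative_id].orf.protein)
        assert rep_len == max(len(by_id[m].orf.protein) for m in locus.members)


def test_coalesce_order_invariance(family_cds):
    base, near, far = family_cds
    cands = [
        _cand("a1", base, "c1"),
        _cand("a2", near, "c2"),
        _cand("b1", far, "c3"),
        _cand("b2", far[:330], "c3"),
    ]
    baseline = coal.coalesce_denovo(cands)
    rng = random.Random(3)
    for _ in range(4):
        rng.shuffle(cands)
        again = coal.coalesce_denovo(cands)
        assert [(l.locus_id, l.members, l.representative_id) for l in again.loci] == [
            (l.locus_id, l.members, l.representative_id) for l in baseline.loci
        ]


def test_coalesce_monotone_in_ks_threshold(family_cds):
    base, near, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", near, "c2"), _cand("c", far, "c3")]
    counts = []
    for thr in (0.01, 0.25, 0.7, 2.0):
        ls = coal.coalesce_denovo(cands, coal.CoalesceConfig(ks_threshold=thr))
        counts.append(ls.count)
    assert counts == sorted(counts, reverse=True)


def test_coalesce_mixed_taxa_rejected(family_cds):
    base, *_ = family_cds
    cands = [_cand("a", base, "c1", taxon="T1"), _cand("b", base, "c2", taxon="T2")]
    with pytest.raises(ValueError, match="one taxon"):
        coal.coalesce_denovo(cands)


def test_coalesce_recovery_small():
    """Generator truth is recovered on 20 fresh single-taxon replicates."""
    hits = 0
    for seed in range(20):
        cfg = sim.SimConfig(seed=seed + 1000, n_taxa=3, background_n=0,
                            contaminant_fraction=0.0,
                            baseline={"APC": 3.0}, delta=1.0, sigma2=0.3)
        bundle = sim.simulate_bundle(cfg)
        from aatcensus.classify import select_candidates

        cands = select_candidates(bundle.transcripts, bundle.domain_hits,
                                  bundle.blast_hits)
        taxon = bundle.taxa[0]
        sub = [c for c in cands if c.transcript.taxon == taxon]
        ls = coal.coalesce_denovo(sub)
        truth = bundle.true_counts
        want = truth[(truth.taxon == taxon) & (truth.family == "APC")]["count"].item()
        hits += ls.count == want
    assert hits >= 19


# ---------------------------------------------------------------------------
# genome-guided


def _map(tid, scaffold="scf1", strand="+", start=1000, end=2000):
    return coal.MappingHit(transcript_id=tid, scaffold=scaffold, strand=strand,
                           start=start, end=end, evalue=1e-50, bitscore=500.0)


def test_genome_overlapping_intervals_merge(family_cds):
    base, _, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", far, "c2")]
    hits = [_map("a", start=1000, end=2000), _map("b", start=1500, end=2500)]
    ls = coal.coalesce_genome_guided(cands, hits)
    assert ls.count == 1
    assert any(d.reason == coal.REASON_LOCATION for d in ls.decisions)


def test_genome_different_scaffolds_stay(family_cds):
    base, near, _ = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", near, "c2")]
    hits = [_map("a"), _map("b", scaffold="scf2")]
    assert coal.coalesce_genome_guided(cands, hits).count == 2


def test_genome_gap_within_merge_distance(family_cds):
    base, _, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", far, "c2")]
    hits = [_map("a", start=1000, end=1500), _map("b", start=2000, end=2600)]
    assert coal.coalesce_genome_guided(cands, hits).count == 1
    tight = coal.CoalesceConfig(merge_gap_bp=100)
    assert coal.coalesce_genome_guided(cands, hits, tight).count == 2


def test_genome_strand_separates(family_cds):
    base, _, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", far, "c2")]
    hits = [_map("a"), _map("b", strand="-")]
    assert coal.coalesce_genome_guided(cands, hits).count == 2


def test_genome_unmapped_fall_back_to_denovo(family_cds):
    base, near, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", near, "c2"), _cand("c", far, "c3")]
    hits = [_map("c")]
    ls = coal.coalesce_genome_guided(cands, hits)
    # a+b merge by Ks; c alone on the genome
    assert ls.count == 2


def test_genome_best_interval_by_bitscore(family_cds):
    base, _, far = family_cds
    cands = [_cand("a", base, "c1"), _cand("b", far, "c2")]
    hits = [
        _map("a", start=1000, end=2000),
        coal.MappingHit("a", "scf9", "+", 1, 500, 1e-10, 50.0),  # weaker
        _map("b", start=1500, end=2500),
    ]
    assert coal.coalesce_genome_guided(cands, hits).count == 1


def test_mapping_hit_parse(tmp_path):
    p = tmp_path / "m.tsv"
    p.write_text(
        "t1\tscf1\t98\t500\t0\t0\t1\t500\t2000\t1501\t1e-50\t400\n"
        "t2\tscf1\t98\t500\t0\t0\t1\t500\t3000\t3499\t1e-50\t400\n"
    )
    hits = coal.parse_mapping_hits(p)
    assert hits[0].strand == "-" and hits[0].start == 1501 and hits[0].end == 2000
    assert hits[1].strand == "+"


def test_write_locus_table(tmp_path, family_cds):
    base, near, _ = family_cds
    ls = coal.coalesce_denovo([_cand("a", base, "c1"), _cand("b", near, "c2")])
    out = tmp_path / "loci.tsv"
    coal.write_locus_table([ls], out)
    text = out.read_text()
    assert "T1|APC|L001" in text
    coal.write_decision_log([ls], tmp_path / "dec.tsv")
    assert "ks_below_threshold" in (tmp_path / "dec.tsv").read_text()
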