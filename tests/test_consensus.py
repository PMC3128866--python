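"""Consensus transcriptome: redundancy collapse, grouping, consensus,
extension, fragment joining, singletons, stats, conflict assessment."""

import numpy as np
import pytest
from Bio.Seq import Seq

from floratx.consensus import (
    OrthologGroup,
    add_singletons,
    assess_against_reference,
    build_groups,
    collapse_redundant,
    consense,
    incorporate_extensions,
    join_fragments,
    transcriptome_stats,
)
from floratx.seqio import SeqRecord, revcomp
from floratx.simulate import SimulationConfig, emit_contigs, simulate_transcriptome


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mut(rng, s, n_mut):
    arr = list(s)
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    return "".join(arr)


class TestCollapse:
    def test_identical_pair_collapsed(self, rng):
        s = _random_seq(rng, 500)
        out = collapse_redundant([SeqRecord("a", s), SeqRecord("b", s)])
        assert len(out) == 1

    def test_partial_coverage_keeps_both(self, rng):
        # 200 bp contig matches a 500 bp contig over only 150 bp (75% of
        # shorter) at high identity: below the 95%-coverage condition
        core = _random_seq(rng, 150)
        long = _random_seq(rng, 200) + core + _random_seq(rng, 150)
        short = core + _random_seq(rng, 50)
        out = collapse_redundant([SeqRecord("long", long), SeqRecord("short", short)])
        assert len(out) == 2

    def test_short_contig_discarded(self, rng):
        out = collapse_redundant([SeqRecord("tiny", _random_seq(rng, 80))])
        assert out == []

    def test_longer_contig_retained(self, rng):
        s = _random_seq(rng, 400)
        longer = s + _random_seq(rng, 10)
        out = collapse_redundant([SeqRecord("a", s), SeqRecord("b", longer)])
        assert [c.id for c in out] == ["b"]

    def test_idempotent_and_order_independent(self, rng):
        s1 = _random_seq(rng, 400)
        s2 = _mut(rng, s1, 2)           # 99.5% identical -> collapses
        s3 = _random_seq(rng, 300)
        recs = [SeqRecord("a", s1), SeqRecord("b", s2), SeqRecord("c", s3)]
        once = collapse_redundant(recs)
        twice = collapse_redundant(once)
        assert {c.id for c in once} == {c.id for c in twice}
        shuffled = collapse_redundant(recs[::-1])
        assert {c.id for c in once} == {c.id for c in shuffled}

    def test_below_99_identity_not_collapsed(self, rng):
        s1 = _random_seq(rng, 400)
        s2 = _mut(rng, s1, 8)           # 98% identity
        out = collapse_redundant([SeqRecord("a", s1), SeqRecord("b", s2)])
        assert len(out) == 2


class TestBuildGroups:
    def test_four_identical_samples_one_group(self, rng):
        s = _random_seq(rng, 300)
        samples = {f"s{i}": [SeqRecord(f"s{i}_c0", s)] for i in range(4)}
        groups, leftovers = build_groups(samples)
        assert len(groups) == 1 and len(groups[0].members) == 4
        assert leftovers == []

    def test_low_identity_pair_not_grouped(self, rng):
        s = _random_seq(rng, 300)
        diverged = _mut(rng, s, 45)     # 85% identity
        samples = {"a": [SeqRecord("a_c0", s)], "b": [SeqRecord("b_c0", diverged)]}
        groups, leftovers = build_groups(samples)
        assert groups == []
        assert len(leftovers) == 2

    def test_single_sample_rejected(self, rng):
        with pytest.raises(ValueError):
            build_groups({"a": [SeqRecord("a_c0", _random_seq(rng, 300))]})

    def test_synthio_group_recovery(self):
        cfg = SimulationConfig(
            n_loci=100, seed=31, paralog_family_fraction=0.0,
            fragmentation_rate=0.0, allelic_duplicate_rate=0.0,
            junk_short_contig_rate=0.0,
        )
        truth = simulate_transcriptome(cfg)
        contigs = emit_contigs(truth, cfg)
        groups, _ = build_groups(contigs)
        correct = 0
        for grp in groups:
            loci = {truth.contig_map[r.id][1] for r in grp.members.values()}
            if len(loci) == 1:
                correct += 1
        assert len(groups) >= 0.90 * cfg.n_loci
        assert correct >= 0.95 * len(groups)


def _group(members, strands=None):
    m = {f"s{i}": rec for i, rec in enumerate(members)}
    st = strands or {rec.id: "+" for rec in members}
    return OrthologGroup("g0", m, st)


class TestConsense:
    def test_identical_members(self, rng):
        s = _random_seq(rng, 300)
        grp = _group([SeqRecord(f"c{i}", s) for i in range(3)])
        assert consense(grp).seq == s

    def test_overhang_retained(self, rng):
        s = _random_seq(rng, 400)
        short = s[:300]
        grp = _group([SeqRecord("long", s), SeqRecord("short", short)])
        cons = consense(grp)
        assert len(cons.seq) == 400
        assert cons.seq == s

    def test_majority_rule_column(self, rng):
        s = _random_seq(rng, 300)
        variant = _mut(rng, s, 1)
        grp = _group([SeqRecord("a", s), SeqRecord("b", s), SeqRecord("c", variant)])
        assert consense(grp).seq == s

    def test_minus_strand_member_oriented(self, rng):
        s = _random_seq(rng, 300)
        grp = _group(
            [SeqRecord("fwd", s), SeqRecord("rev", revcomp(s))],
            strands={"fwd": "+", "rev": "-"},
        )
        assert consense(grp).seq == s


class TestExtensions:
    def test_tail_extension_merged(self, rng):
        cons = SeqRecord("cons0", _random_seq(rng, 400))
        tail = _random_seq(rng, 100)
        leftover = SeqRecord("lo", cons.seq[-200:] + tail)
        out, remaining, log = incorporate_extensions([cons], [leftover])
        assert remaining == []
        assert log.merged == [("lo", "cons0")]
        assert out[0].seq == cons.seq + tail

    def test_internal_unalignable_gap_rejected(self, rng):
        base = _random_seq(rng, 400)
        cons = SeqRecord("cons0", base)
        # leftover matches two blocks of the consensus separated by a 30 bp
        # junk insert: contiguity fails
        leftover = SeqRecord(
            "lo", base[100:220] + _random_seq(rng, 30) + base[250:400] + _random_seq(rng, 80)
        )
        out, remaining, log = incorporate_extensions([cons], [leftover])
        assert [r.id for r in remaining] == ["lo"]
        assert out[0].seq == base

    def test_contained_leftover_not_merged(self, rng):
        cons = SeqRecord("cons0", _random_seq(rng, 400))
        leftover = SeqRecord("lo", cons.seq[100:300])
        out, remaining, _ = incorporate_extensions([cons], [leftover])
        assert [r.id for r in remaining] == ["lo"]
        assert out[0].seq == cons.seq

    def test_ambiguous_double_extension_skipped(self, rng):
        shared = _random_seq(rng, 200)
        c1 = SeqRecord("cons0", _random_seq(rng, 200) + shared)
        c2 = SeqRecord("cons1", _random_seq(rng, 210) + shared)
        leftover = SeqRecord("lo", shared + _random_seq(rng, 100))
        out, remaining, log = incorporate_extensions([c1, c2], [leftover])
        assert log.ambiguous == ["lo"]
        assert [r.id for r in remaining] == ["lo"]


class TestJoinFragments:
    def _guide_and_fragments(self, rng, gap_codons):
        nt = _random_seq(rng, 630)
        prot = str(Seq(nt).translate()).replace("*", "X")
        guide = SeqRecord("guide0", prot)
        frag1 = nt[: 100 * 3]                       # guide residues [0, 100)
        start2 = (100 + gap_codons) * 3
        frag2 = nt[start2 : start2 + 90 * 3]        # residues [100+gap, 190+gap)
        return guide, SeqRecord("f1", frag1), SeqRecord("f2", frag2)

    def test_gap_joined_with_n_spacer(self, rng):
        guide, f1, f2 = self._guide_and_fragments(rng, gap_codons=19)
        out, log = join_fragments([f1, f2], [guide])
        assert log.joined == [("f1", "f2")]
        joined = next(r for r in out if "+" in r.id)
        assert joined.seq == f1.seq + "N" * 57 + f2.seq

    def test_large_overlap_not_joined(self, rng):
        guide, f1, _ = self._guide_and_fragments(rng, 0)
        nt = _random_seq(rng, 630)
        # second fragment overlaps guide residues 59..., overlap 41 > 15
        f2 = SeqRecord("f2", f1.seq[59 * 3 :] + _random_seq(rng, 150))
        out, log = join_fragments([f1, f2], [guide])
        assert log.joined == []

    def test_different_guides_untouched(self, rng):
        nt1, nt2 = _random_seq(rng, 600), _random_seq(rng, 600)
        g1 = SeqRecord("g1", str(Seq(nt1).translate()).replace("*", "X"))
        g2 = SeqRecord("g2", str(Seq(nt2).translate()).replace("*", "X"))
        f1, f2 = SeqRecord("f1", nt1[:300]), SeqRecord("f2", nt2[:300])
        out, log = join_fragments([f1, f2], [g1, g2])
        assert log.joined == [] and {r.id for r in out} == {"f1", "f2"}


class TestSingletons:
    def _guide_for(self, nt):
        sub = nt[: len(nt) - len(nt) % 3]
        return SeqRecord("g", str(Seq(sub).translate()).replace("*", "X"))

    def test_long_supported_leftover_included(self, rng):
        nt = _random_seq(rng, 1200)
        out = add_singletons([], [SeqRecord("lo", nt)], [self._guide_for(nt)])
        assert [r.id for r in out] == ["lo"]

    def test_short_leftover_excluded(self, rng):
        nt = _random_seq(rng, 800)
        out = add_singletons([], [SeqRecord("lo", nt)], [self._guide_for(nt)])
        assert out == []

    def test_unsupported_leftover_excluded(self, rng):
        nt = _random_seq(rng, 1200)
        other = self._guide_for(_random_seq(rng, 900))
        out = add_singletons([], [SeqRecord("lo", nt)], [other])
        assert out == []


class TestStats:
    @pytest.mark.parametrize(
        "lengths,n50",
        [([100], 100), ([2, 2, 2, 3, 3, 4], 3), ([500, 500], 500)],
    )
    def test_known_n50(self, lengths, n50, rng):
        recs = [SeqRecord(f"c{i}", "A" * L) for i, L in enumerate(lengths)]
        st = transcriptome_stats(recs)
        assert st.n50 == n50
        assert st.total_length == sum(lengths)
        assert st.mean_length == pytest.approx(np.mean(lengths))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            transcriptome_stats([])


class TestAssessment:
    def test_exact_assembly_no_conflicts(self, rng):
        truth = [SeqRecord(f"t{i}", _random_seq(rng, 600)) for i in range(5)]
        assembled = [SeqRecord(f"a{i}", t.seq) for i, t in enumerate(truth)]
        report = assess_against_reference(assembled, truth)
        assert report.n_conflicts == 0 and report.n_assessed == 5

    def test_chimera_flagged(self, rng):
        t1 = SeqRecord("t1", _random_seq(rng, 600))
        t2 = SeqRecord("t2", _random_seq(rng, 600))
        chimera = SeqRecord("chi", t1.seq[:300] + t2.seq[300:])
        report = assess_against_reference([chimera], [t1, t2])
        assert ("chi", "t1") in report.conflicts or ("chi", "t2") in report.conflicts

    def test_short_low_identity_flank_tolerated(self, rng):
        t = SeqRecord("t", _random_seq(rng, 500))
        # matches truth up to 40 bp before its end, then diverges: the
        # conflicting overlap is only 40 bp (< 50), so no conflict
        asm = SeqRecord("a", t.seq[:460] + _random_seq(rng, 40))
        report = assess_against_reference([asm], [t])
        assert report.n_conflicts == 0


class TestZeroDivergenceReconstruction:
    def test_groups_reconstruct_truth_exactly(self):
        cfg = SimulationConfig(
            n_loci=25, seed=13,
            interspecific_divergence=0.0, intraspecific_divergence=0.0,
            het_rate_outcrosser=0.0, het_rate_selfer=0.0,
            paralog_family_fraction=0.0, fragmentation_rate=0.0,
            allelic_duplicate_rate=0.0, junk_short_contig_rate=0.0,
        )
        truth = simulate_transcriptome(cfg)
        contigs = emit_contigs(truth, cfg)
        groups, leftovers = build_groups(contigs)
        assert len(groups) == cfg.n_loci and leftovers == []
        consensus_seqs = {consense(g).seq for g in groups}
        assert consensus_seqs == set(truth.ancestral.values())
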