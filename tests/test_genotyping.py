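"""Read mapping, the Bayesian site caller and the paralog SUSPECT flag."""

import numpy as np
import pytest

from floratx.genotyping import (
    GENOTYPE_PAIRS,
    LocusGenotype,
    PileupColumn,
    ReferenceIndex,
    _site_posteriors,
    call_site,
    flag_mapping_errors,
    genotype_locus,
    genotype_sample,
    map_read,
    map_reads,
    pileup,
    read_sam,
)
from floratx.pipeline import write_sam
from floratx.seqio import SeqRecord, revcomp


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mut(rng, s, n_mut):
    arr = list(s)
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    return "".join(arr)


def _oracle_posteriors(obs, het_prior=0.001):
    """Independent direct evaluation of the genotype model: explicit
    loops over the 10 diploid genotypes and every observation."""
    bases = "ACGT"
    genotypes = [(b, b) for b in bases] + [
        (bases[i], bases[j]) for i in range(4) for j in range(i + 1, 4)
    ]
    priors = []
    liks = []
    for x, y in genotypes:
        prior = (1 - het_prior) / 4 if x == y else het_prior / 6
        lik = 1.0
        for b, q in obs:
            eps = 10 ** (-q / 10)
            px = (1 - eps) if b == x else eps / 3
            py = (1 - eps) if b == y else eps / 3
            lik *= 0.5 * (px + py)
        priors.append(prior)
        liks.append(lik)
    post = [p * l for p, l in zip(priors, liks)]
    total = sum(post)
    return {g: p / total for g, p in zip(genotypes, post)}


class TestMapping:
    def test_error_free_read_maps_to_true_position(self, rng):
        ref = [SeqRecord("L0", _random_seq(rng, 500))]
        idx = ReferenceIndex(ref)
        read = SeqRecord("r", ref[0].seq[123 : 123 + 40], [30] * 40)
        a = map_read(read, idx)
        assert a.mapped and a.locus_id == "L0" and a.position == 123
        assert a.mismatch_count == 0 and a.strand == "+"

    def test_reverse_strand_read_mapped(self, rng):
        ref = [SeqRecord("L0", _random_seq(rng, 500))]
        idx = ReferenceIndex(ref)
        read = SeqRecord("r", revcomp(ref[0].seq[200:240]), [30] * 40)
        a = map_read(read, idx)
        assert a.mapped and a.position == 200 and a.strand == "-"
        assert a.seq == ref[0].seq[200:240]

    def test_identical_paralogs_give_ambiguous(self, rng):
        s = _random_seq(rng, 500)
        idx = ReferenceIndex([SeqRecord("L0", s), SeqRecord("L1", s)])
        read = SeqRecord("r", s[100:140], [30] * 40)
        a = map_read(read, idx)
        assert not a.mapped

    def test_diverged_paralog_read_mismaps_with_mismatches(self, rng):
        # only one family member in the reference: a read from the 97%
        # copy lands on the reference copy carrying its divergent bases
        s = _random_seq(rng, 500)
        arr = list(s)
        for pos in (105, 135):   # two divergent sites inside the read window
            arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
        paralog = "".join(arr)
        idx = ReferenceIndex([SeqRecord("L0", s)])
        read = SeqRecord("r", paralog[100:140], [30] * 40)
        a = map_read(read, idx)
        assert a.mapped and a.locus_id == "L0" and a.position == 100
        assert a.mismatch_count == 2

    def test_read_beyond_budget_unmapped(self, rng):
        s = _random_seq(rng, 500)
        idx = ReferenceIndex([SeqRecord("L0", s)])
        bad = _mut(rng, s[100:140], 8)
        a = map_read(SeqRecord("r", bad, [30] * 40), idx)
        assert not a.mapped


class TestPileup:
    def test_single_read_columns(self, rng):
        ref = [SeqRecord("L0", _random_seq(rng, 200))]
        read = SeqRecord("r", ref[0].seq[50:90], [30] * 40)
        alns = map_reads([read], ref)
        cols = pileup(alns, ref)["L0"]
        assert len(cols) == 40
        assert all(c.coverage == 1 for c in cols)
        assert cols[0].position == 50

    def test_overlapping_reads_stack(self, rng):
        ref = [SeqRecord("L0", _random_seq(rng, 200))]
        reads = [
            SeqRecord("r1", ref[0].seq[50:90], [30] * 40),
            SeqRecord("r2", ref[0].seq[60:100], [30] * 40),
        ]
        cols = pileup(map_reads(reads, ref), ref)["L0"]
        by_pos = {c.position: c for c in cols}
        assert by_pos[65].coverage == 2
        assert by_pos[55].coverage == 1


class TestCallSite:
    def _col(self, obs):
        counts = {b: 0 for b in "ACGT"}
        for b, _ in obs:
            counts[b] += 1
        return PileupColumn("L0", 0, counts, obs)

    def test_homozygote_called_confidently(self):
        obs = [("A", 20)] * 10
        call = call_site(self._col(obs))
        assert call.genotype == ("A", "A")
        assert call.consensus_quality > 13
        oracle = _oracle_posteriors(obs)
        assert oracle[("A", "A")] > 0.999

    def test_balanced_site_called_heterozygous(self):
        obs = [("A", 20)] * 5 + [("C", 20)] * 5
        call = call_site(self._col(obs))
        assert call.genotype == ("A", "C")

    def test_low_coverage_ambiguous(self):
        obs = [("A", 30)] * 4
        assert call_site(self._col(obs)).ambiguous
        obs5 = [("A", 30)] * 5
        assert call_site(self._col(obs5)).ambiguous  # coverage must exceed 5

    def test_posterior_matches_oracle(self, rng):
        for _ in range(20):
            obs = [
                (rng.choice(list("ACGT")), int(rng.integers(5, 40)))
                for _ in range(int(rng.integers(1, 15)))
            ]
            bases = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b, _ in obs])
            quals = np.array([q for _, q in obs], dtype=float)
            post = _site_posteriors(bases, quals, 0.001)
            oracle = _oracle_posteriors(obs)
            lut = "ACGT"
            for gi, (x, y) in enumerate(GENOTYPE_PAIRS):
                assert post[gi] == pytest.approx(oracle[(lut[x], lut[y])], abs=1e-9)

    def test_posterior_sums_to_one(self, rng):
        bases = rng.integers(0, 4, size=12)
        quals = rng.integers(5, 41, size=12).astype(float)
        post = _site_posteriors(bases, quals, 0.001)
        assert abs(post.sum() - 1.0) < 1e-9


class TestGenotypeLocus:
    def _cols(self, seq, cov, het_at=None):
        cols = []
        for i, b in enumerate(seq):
            if het_at is not None and i == het_at:
                obs = [("A", 30)] * (cov // 2) + [("C", 30)] * (cov - cov // 2)
            else:
                obs = [(b, 30)] * cov
            counts = {x: 0 for x in "ACGT"}
            for bb, _ in obs:
                counts[bb] += 1
            cols.append(PileupColumn("L0", i, counts, obs))
        return cols

    def test_homozygous_locus(self, rng):
        seq = _random_seq(rng, 50)
        lg = genotype_locus(self._cols(seq, 10), 50)
        assert lg.sequence == seq
        assert lg.het_site_count == 0 and lg.present

    def test_het_site_gets_iupac_code(self, rng):
        seq = _random_seq(rng, 50)
        lg = genotype_locus(self._cols(seq, 10, het_at=7), 50)
        assert lg.sequence[7] == "M"   # A/C
        assert lg.het_site_count == 1

    def test_low_mean_coverage_not_present(self, rng):
        seq = _random_seq(rng, 50)
        lg = genotype_locus(self._cols(seq, 3), 50)
        assert not lg.present

    def test_vectorised_caller_matches_per_site_calls(self, rng):
        ref = [SeqRecord("L0", _random_seq(rng, 300))]
        reads = []
        for i in range(120):
            start = int(rng.integers(0, 260))
            seq = ref[0].seq[start : start + 40]
            if rng.random() < 0.3:
                seq = _mut(rng, seq, 1)
            reads.append(SeqRecord(f"r{i}", seq, [25] * 40))
        alns = map_reads(reads, ref)
        by_locus = genotype_sample(alns, ref)
        cols = pileup(alns, ref)["L0"]
        expected = ["N"] * 300
        for col in cols:
            call = call_site(col)
            if call.genotype is not None:
                a, b = call.genotype
                from floratx.genotyping import IUPAC

                expected[col.position] = IUPAC[frozenset((a, b))]
        assert by_locus["L0"].sequence == "".join(expected)


class TestFlags:
    def _lg(self, lid, het, present=True):
        return LocusGenotype(lid, "A" * 10, 20.0 if present else 1.0, het, present)

    def test_het_in_two_selfers_suspect(self):
        gts = {
            "outcrosser": {"L0": self._lg("L0", 2)},
            "selfer1": {"L0": self._lg("L0", 1)},
            "selfer2": {"L0": self._lg("L0", 1)},
            "outgroup": {"L0": self._lg("L0", 0)},
        }
        flags = flag_mapping_errors(gts, ["selfer1", "selfer2", "outgroup"])
        assert flags["L0"] == "SUSPECT"

    def test_het_only_in_outcrosser_clean(self):
        gts = {
            "outcrosser": {"L0": self._lg("L0", 3)},
            "selfer1": {"L0": self._lg("L0", 0)},
            "selfer2": {"L0": self._lg("L0", 0)},
            "outgroup": {"L0": self._lg("L0", 0)},
        }
        flags = flag_mapping_errors(gts, ["selfer1", "selfer2", "outgroup"])
        assert flags["L0"] == "CLEAN"

    def test_present_in_one_selfer_untestable(self):
        gts = {
            "outcrosser": {"L0": self._lg("L0", 0)},
            "selfer1": {"L0": self._lg("L0", 0)},
            "selfer2": {"L0": self._lg("L0", 0, present=False)},
            "outgroup": {"L0": self._lg("L0", 0, present=False)},
        }
        flags = flag_mapping_errors(gts, ["selfer1", "selfer2", "outgroup"])
        assert flags["L0"] == "UNTESTABLE"

    def test_no_selfers_rejected(self):
        with pytest.raises(ValueError):
            flag_mapping_errors({}, [])


class TestSamRoundTrip:
    def test_write_read_sam(self, rng, tmp_path):
        ref = [SeqRecord("L0", _random_seq(rng, 300))]
        reads = [
            SeqRecord("r1/1", ref[0].seq[10:50], [30] * 40),
            SeqRecord("r1/2", revcomp(ref[0].seq[150:190]), [31] * 40),
        ]
        alns = map_reads(reads, ref)
        path = tmp_path / "x.sam"
        write_sam(alns, ref, path)
        back = read_sam(path)
        assert len(back) == 2
        for orig, rt in zip(alns, back):
            assert rt.locus_id == orig.locus_id
            assert rt.position == orig.position
            assert rt.strand == orig.strand
            assert rt.seq == orig.seq
            assert rt.quals == orig.quals
            assert rt.mismatch_count == orig.mismatch_count
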