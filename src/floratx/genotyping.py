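"""Read mapping, pileup and Bayesian diploid genotype calling.

Reads are mapped ungapped to the consensus transcriptome at their
minimal-mismatch position (both strands); reads with two equally good
placements are excluded as ambiguous.  Per covered site a diploid
genotype is called from base observations and their Phred qualities
under a simple Bayesian model: for error probability ε = 10^(−q/10),

    P(b | XX) = 1 − ε    if b = X, else ε/3
    P(b | XY) = ½ [P(b | XX) + P(b | YY)]

with a small heterozygote prior shared uniformly across the six
heterozygous genotypes.  The consensus quality Q is the Phred-scaled
probability that the called genotype is wrong; calls need coverage > 5
and Q > 13, otherwise the site is ambiguous.

Residual heterozygosity in multiple selfing genotypes is the paralog /
read-mis-mapping signal: loci heterozygous in ≥2 selfers are flagged
SUSPECT and excluded from downstream population-genetic analyses.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import SeqRecord, revcomp

BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
BASE_LUT = "ACGT"
# the 10 diploid genotypes: 4 homozygous then 6 heterozygous
GENOTYPE_PAIRS: list[tuple[int, int]] = [(i, i) for i in range(4)] + [
    (i, j) for i in range(4) for j in range(i + 1, 4)
]
IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
    frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K",
}


@dataclass
class AlignmentRecord:
    read_id: str
    locus_id: str
    position: int            # 0-based start on the locus
    strand: str
    mismatch_count: int
    mapped: bool
    length: int = 0
    seq: str = ""            # strand-adjusted (reference-forward) bases
    quals: list[int] | None = None


@dataclass
class PileupColumn:
    locus_id: str
    position: int
    base_counts: dict[str, int]
    base_quals: list[tuple[str, int]]   # (base, qual) per observation

    @property
    def coverage(self) -> int:
        return sum(self.base_counts.values())


@dataclass
class SiteCall:
    genotype: tuple[str, str] | None    # unordered base pair; None = AMBIGUOUS
    consensus_quality: float
    coverage: int

    @property
    def ambiguous(self) -> bool:
        return self.genotype is None

    @property
    def heterozygous(self) -> bool:
        return self.genotype is not None and self.genotype[0] != self.genotype[1]


@dataclass
class LocusGenotype:
    locus_id: str
    sequence: str            # called bases, IUPAC for het, N for ambiguous
    mean_coverage: float
    het_site_count: int
    present: bool


class ReferenceIndex:
    """k-mer index of the consensus transcriptome for ungapped mapping."""

    def __init__(self, reference: list[SeqRecord], k: int = 20):
        self.k = k
        self.loci = reference
        self.lengths = {r.id: len(r) for r in reference}
        self.seqs = {r.id: r.seq for r in reference}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for r in reference:
            s = r.seq
            for pos in range(len(s) - k + 1):
                self.index[s[pos : pos + k]].append((r.id, pos))


def map_read(
    read: SeqRecord, ref: ReferenceIndex, max_mismatch_frac: float = 0.05
) -> AlignmentRecord:
    """Place one read at its minimal-mismatch ungapped position.

    Budget is floor(max_mismatch_frac·len) + 1 mismatches.  Ties across
    distinct positions leave the read unmapped-ambiguous; multi-mapping
    therefore never contributes to pileups, and diverged paralog copies
    (the biologically relevant case) mis-map with mismatches instead.
    """
    L = len(read)
    k = ref.k
    budget = math.floor(max_mismatch_frac * L) + 1
    if L < k:
        return AlignmentRecord(read.id, "", -1, "+", 0, False)
    best: list[tuple[str, int, str]] = []
    best_mm = budget + 1
    for strand in "+-":
        seq = read.seq if strand == "+" else revcomp(read.seq)
        offsets = [0, L - k]
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for lid, pos in ref.index.get(seq[off : off + k], ()):
                candidates.add((lid, pos - off))
        if not candidates:  # fall back to every seed offset
            for off in range(1, L - k):
                for lid, pos in ref.index.get(seq[off : off + k], ()):
                    candidates.add((lid, pos - off))
        for lid, start in candidates:
            if start < 0 or start + L > ref.lengths[lid]:
                continue
            target = ref.seqs[lid][start : start + L]
            mm = sum(a != b for a, b in zip(seq, target))
            if mm < best_mm:
                best_mm = mm
                best = [(lid, start, strand)]
            elif mm == best_mm:
                best.append((lid, start, strand))
    if best_mm > budget or not best:
        return AlignmentRecord(read.id, "", -1, "+", 0, False)
    if len(set(best)) > 1:  # equally-best placements: ambiguous
        return AlignmentRecord(read.id, "", -1, "+", best_mm, False)
    lid, start, strand = best[0]
    seq = read.seq if strand == "+" else revcomp(read.seq)
    quals = read.quals if strand == "+" or read.quals is None else read.quals[::-1]
    return AlignmentRecord(read.id, lid, start, strand, best_mm, True, L, seq, quals)


def map_reads(
    reads: list[SeqRecord],
    reference: list[SeqRecord] | ReferenceIndex,
    max_mismatch_frac: float = 0.05,
) -> list[AlignmentRecord]:
    ref = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference)
    return [map_read(r, ref, max_mismatch_frac) for r in reads]


def read_sam(path: str | Path, default_qual: int = 30) -> list[AlignmentRecord]:
    """Ingest alignments from a SAM file (external aligner path).

    Only primary, mapped, ungapped-compatible records are kept; the NM
    tag supplies the mismatch count when present.
    """
    import pysam

    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            seq = rec.query_sequence or ""
            quals = (
                list(rec.query_qualities)
                if rec.query_qualities is not None
                else [default_qual] * len(seq)
            )
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            out.append(
                AlignmentRecord(
                    rec.query_name,
                    rec.reference_name or "",
                    rec.reference_start,
                    "-" if rec.is_reverse else "+",
                    int(nm),
                    True,
                    len(seq),
                    seq,
                    quals,
                )
            )
    return out


def pileup(
    alignments: list[AlignmentRecord], reference: list[SeqRecord]
) -> dict[str, list[PileupColumn]]:
    """Base/quality tallies per covered reference position, mapped reads only."""
    lengths = {r.id: len(r) for r in reference}
    obs: dict[str, dict[int, list[tuple[str, int]]]] = defaultdict(lambda: defaultdict(list))
    for a in alignments:
        if not a.mapped:
            continue
        quals = a.quals if a.quals is not None else [30] * len(a.seq)
        for i, (b, q) in enumerate(zip(a.seq, quals)):
            if b in BASE_CODE:
                obs[a.locus_id][a.position + i].append((b, q))
    out: dict[str, list[PileupColumn]] = {}
    for lid, cols in obs.items():
        lst = []
        for pos in sorted(cols):
            counts = {b: 0 for b in BASE_LUT}
            for b, _ in cols[pos]:
                counts[b] += 1
            lst.append(PileupColumn(lid, pos, counts, cols[pos]))
        out[lid] = lst
        _ = lengths  # lengths used by genotype_locus for denominators
    return out


def _genotype_log_priors(het_prior: float) -> np.ndarray:
    pri = np.empty(10)
    pri[:4] = (1.0 - het_prior) / 4.0
    pri[4:] = het_prior / 6.0
    return np.log(pri)


def _site_posteriors(
    bases: np.ndarray, quals: np.ndarray, het_prior: float
) -> np.ndarray:
    """Posterior over the 10 diploid genotypes for one column."""
    eps = 10.0 ** (-quals / 10.0)
    # p_hom[g, obs] = P(obs base | genotype gg)
    p_base = np.where(
        bases[None, :] == np.arange(4)[:, None], 1.0 - eps[None, :], eps[None, :] / 3.0
    )
    loglik = np.empty(10)
    for gi, (x, y) in enumerate(GENOTYPE_PAIRS):
        p = p_base[x] if x == y else 0.5 * (p_base[x] + p_base[y])
        loglik[gi] = np.sum(np.log(p))
    logpost = loglik + _genotype_log_priors(het_prior)
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def call_site(
    col: PileupColumn,
    het_prior: float = 0.001,
    min_coverage: int = 5,
    min_quality: float = 13.0,
) -> SiteCall:
    """Call one site; AMBIGUOUS unless coverage > 5 and Q > 13."""
    bases = np.array([BASE_CODE[b] for b, _ in col.base_quals], dtype=int)
    quals = np.array([q for _, q in col.base_quals], dtype=float)
    if len(bases) == 0:
        return SiteCall(None, 0.0, 0)
    post = _site_posteriors(bases, quals, het_prior)
    gi = int(np.argmax(post))
    q = -10.0 * math.log10(max(1.0 - post[gi], 1e-10))
    q = min(q, 99.0)
    cov = len(bases)
    if cov <= min_coverage or q <= min_quality:
        return SiteCall(None, q, cov)
    x, y = GENOTYPE_PAIRS[gi]
    return SiteCall((BASE_LUT[x], BASE_LUT[y]), q, cov)


def genotype_locus(
    columns: list[PileupColumn],
    locus_length: int,
    het_prior: float = 0.001,
    min_coverage: int = 5,
    min_quality: float = 13.0,
) -> LocusGenotype:
    """Assemble a locus sequence from site calls.

    The locus is `present` iff mean coverage over its full length
    exceeds the coverage threshold.  Heterozygous calls are written as
    IUPAC codes; ambiguous sites as N.
    """
    if not columns:
        return LocusGenotype("", "N" * locus_length, 0.0, 0, False)
    lid = columns[0].locus_id
    seq = ["N"] * locus_length
    total_cov = 0
    het = 0
    for col in columns:
        if not (0 <= col.position < locus_length):
            continue
        total_cov += col.coverage
        call = _call_column_fast(col, het_prior, min_coverage, min_quality)
        if call.genotype is None:
            continue
        a, b = call.genotype
        seq[col.position] = IUPAC[frozenset((a, b))]
        if a != b:
            het += 1
    mean_cov = total_cov / locus_length
    return LocusGenotype(lid, "".join(seq), mean_cov, het, mean_cov > min_coverage)


def _call_column_fast(col, het_prior, min_coverage, min_quality) -> SiteCall:
    # same model as call_site; kept separate so vectorised batching can
    # replace it without touching the public contract
    return call_site(col, het_prior, min_coverage, min_quality)


def genotype_sample(
    alignments: list[AlignmentRecord],
    reference: list[SeqRecord],
    het_prior: float = 0.001,
    min_coverage: int = 5,
    min_quality: float = 13.0,
) -> dict[str, LocusGenotype]:
    """Vectorised per-sample genotyping of every reference locus."""
    lengths = {r.id: len(r) for r in reference}
    per_locus: dict[str, list[tuple[np.ndarray, np.ndarray, np.ndarray]]] = defaultdict(list)
    for a in alignments:
        if not a.mapped:
            continue
        quals = np.asarray(a.quals if a.quals is not None else [30] * len(a.seq), dtype=float)
        codes = np.frombuffer(a.seq.encode(), dtype="S1")
        base_idx = np.full(len(a.seq), -1, dtype=int)
        for b, c in BASE_CODE.items():
            base_idx[codes == b.encode()] = c
        pos = np.arange(len(a.seq)) + a.position
        valid = base_idx >= 0
        per_locus[a.locus_id].append((pos[valid], base_idx[valid], quals[valid]))

    log_priors = _genotype_log_priors(het_prior)
    out: dict[str, LocusGenotype] = {}
    for r in reference:
        L = lengths[r.id]
        chunks = per_locus.get(r.id)
        if not chunks:
            out[r.id] = LocusGenotype(r.id, "N" * L, 0.0, 0, False)
            continue
        pos = np.concatenate([c[0] for c in chunks])
        base = np.concatenate([c[1] for c in chunks])
        qual = np.concatenate([c[2] for c in chunks])
        keep = (pos >= 0) & (pos < L)
        pos, base, qual = pos[keep], base[keep], qual[keep]
        eps = 10.0 ** (-qual / 10.0)
        # per-observation log-likelihood under each of the 10 genotypes,
        # summed into columns with bincount
        p_hom = np.empty((4, len(pos)))
        for x in range(4):
            p_hom[x] = np.where(base == x, 1.0 - eps, eps / 3.0)
        col_loglik = np.zeros((10, L))
        for gi, (x, y) in enumerate(GENOTYPE_PAIRS):
            p = p_hom[x] if x == y else 0.5 * (p_hom[x] + p_hom[y])
            col_loglik[gi] = np.bincount(pos, weights=np.log(p), minlength=L)
        cov = np.bincount(pos, minlength=L)
        logpost = col_loglik + log_priors[:, None]
        logpost -= logpost.max(axis=0, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=0, keepdims=True)
        gi_best = np.argmax(post, axis=0)
        p_best = post[gi_best, np.arange(L)]
        q = np.minimum(-10.0 * np.log10(np.maximum(1.0 - p_best, 1e-10)), 99.0)
        called = (cov > min_coverage) & (q > min_quality)
        seq = np.full(L, "N", dtype="<U1")
        het = 0
        for i in np.nonzero(called)[0]:
            x, y = GENOTYPE_PAIRS[gi_best[i]]
            seq[i] = IUPAC[frozenset((BASE_LUT[x], BASE_LUT[y]))]
            if x != y:
                het += 1
        mean_cov = float(cov.sum() / L)
        out[r.id] = LocusGenotype(r.id, "".join(seq), mean_cov, het, mean_cov > min_coverage)
    return out


def flag_mapping_errors(
    locus_genotypes: dict[str, dict[str, LocusGenotype]],
    selfer_labels: list[str],
) -> dict[str, str]:
    """Classify loci as CLEAN / SUSPECT / UNTESTABLE.

    ``locus_genotypes`` maps sample → locus → LocusGenotype.  A locus
    heterozygous in two or more selfing genotypes is SUSPECT (selfers
    should be near-homozygous, so shared heterozygosity marks read
    mis-mapping, typically from a collapsed paralog).  Loci present in
    at most one selfer are UNTESTABLE.
    """
    if not selfer_labels:
        raise ValueError("at least one selfer label required")
    all_loci = sorted({lid for gt in locus_genotypes.values() for lid in gt})
    out: dict[str, str] = {}
    for lid in all_loci:
        present_selfers = [
            s
            for s in selfer_labels
            if lid in locus_genotypes.get(s, {}) and locus_genotypes[s][lid].present
        ]
        if len(present_selfers) <= 1:
            out[lid] = "UNTESTABLE"
            continue
        n_het = sum(
            1 for s in present_selfers if locus_genotypes[s][lid].het_site_count >= 1
        )
        out[lid] = "SUSPECT" if n_het >= 2 else "CLEAN"
    return out


def write_vcf(
    genotypes: dict[str, LocusGenotype],
    reference: list[SeqRecord],
    sample: str,
    path: str | Path,
) -> None:
    """Export site calls that differ from the reference as a minimal VCF."""
    ref_by_id = {r.id: r for r in reference}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n")
        rev_iupac = {v: sorted(k) for k, v in IUPAC.items()}
        for lid in sorted(genotypes):
            lg = genotypes[lid]
            if lid not in ref_by_id:
                continue
            ref_seq = ref_by_id[lid].seq
            for i, code in enumerate(lg.sequence):
                if code == "N" or i >= len(ref_seq):
                    continue
                alleles = rev_iupac.get(code, [code])
                ref_b = ref_seq[i]
                alts = [a for a in alleles if a != ref_b]
                if not alts:
                    continue
                alt = ",".join(alts)
                if len(alleles) == 1:
                    gt = "1/1"
                else:
                    gt = "0/1" if ref_b in alleles else "1/2"
                fh.write(f"{lid}\t{i + 1}\t.\t{ref_b}\t{alt}\t.\tPASS\t.\tGT\t{gt}\n")
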