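"""Synthetic floral-transcriptome study generator.

Emulates the sampling design of a mating-system comparison: one
heterozygous outcrossing genotype, two independently derived,
near-homozygous selfing genotypes of the same species, and a diverged
selfing outgroup species.  From a simulated truth set (diploid
haplotypes per locus, paralog families, expression weights) it derives
the observables the analysis pipeline consumes: ~40 bp paired-end reads
with 3'-decaying qualities, assembler-like contig sets (fragmented
loci, >99%-identical allelic duplicates, short junk contigs), protein
guide sequences and a gene→GO map.

All randomness flows from ``SimulationConfig.seed``; a fixed seed gives
bit-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .seqio import SeqRecord, revcomp, write_fasta, write_fastq

BASES = np.frombuffer(b"ACGT", dtype="S1")
GENOTYPES = ("outcrosser", "selfer1", "selfer2", "outgroup")
SELFERS = ("selfer1", "selfer2", "outgroup")
INGROUP = ("outcrosser", "selfer1", "selfer2")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic comparison.

    Divergences are per-site substitution probabilities; het rates are
    the fraction of loci carrying at least one heterozygous site in a
    genotype of that mating system.
    """

    n_loci: int = 500
    locus_length_meanlog: float = 6.72   # lognormal; mean length ~ 900 bp
    locus_length_sdlog: float = 0.40
    min_locus_length: int = 200
    interspecific_divergence: float = 0.048
    intraspecific_divergence: float = 0.010
    het_rate_outcrosser: float = 0.20
    het_rate_selfer: float = 0.05
    het_sites_mean: float = 3.0          # mean het sites per heterozygous locus
    paralog_family_fraction: float = 0.05
    paralog_identity: float = 0.97
    expression_meanlog: float = 3.0      # lognormal log-FPKM-scale weights
    expression_sdlog: float = 1.2
    expression_noise_ingroup: float = 0.30
    expression_noise_outgroup: float = 0.80
    read_length: int = 40
    read_error_rate: float = 0.01
    mean_coverage: float = 20.0
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    fragmentation_rate: float = 0.05
    allelic_duplicate_rate: float = 0.05
    junk_short_contig_rate: float = 0.10
    selfer2_sister_to_outcrosser: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.het_rate_outcrosser,
            self.het_rate_selfer,
            self.paralog_family_fraction,
            self.fragmentation_rate,
            self.allelic_duplicate_rate,
            self.junk_short_contig_rate,
            self.read_error_rate,
        )
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("rates must lie in [0, 1]")
        if not (0.0 <= self.interspecific_divergence < 1.0) or not (
            0.0 <= self.intraspecific_divergence < 1.0
        ):
            raise ValueError("divergences must lie in [0, 1)")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if 1.0 - self.paralog_identity <= 2.0 * self.read_error_rate:
            warnings.warn(
                "paralog divergence is within the sequencing-error scale; "
                "paralog mis-mapping may be indistinguishable from noise",
                stacklevel=2,
            )


@dataclass
class TruthSet:
    """Ground truth: haplotypes, het sites, paralogy and expression."""

    config: SimulationConfig
    locus_ids: list[str]
    lengths: dict[str, int]
    ancestral: dict[str, str]
    # (genotype, locus) -> (hap1, hap2); hap1 is the emitted contig allele
    haplotypes: dict[tuple[str, str], tuple[str, str]]
    het_sites: dict[tuple[str, str], list[int]]
    paralog_families: dict[str, list[str]]   # family id -> member locus ids
    paralog_of: dict[str, str]               # duplicate locus -> primary locus
    expression: dict[tuple[str, str], float]
    contig_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    fragment_counts: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def genotypes(self) -> tuple[str, ...]:
        return GENOTYPES

    def het_locus_count(self, genotype: str) -> int:
        return sum(
            1 for (g, _), sites in self.het_sites.items() if g == genotype and sites
        )

    def pairwise_divergence(self, g1: str, g2: str) -> float:
        """Mean per-site hap1-vs-hap1 divergence across loci."""
        diffs = sites = 0
        for locus in self.locus_ids:
            a = self.haplotypes[(g1, locus)][0]
            b = self.haplotypes[(g2, locus)][0]
            diffs += sum(x != y for x, y in zip(a, b))
            sites += len(a)
        return diffs / sites

    def write(self, outdir: str | Path) -> None:
        """Serialize truth as FASTA + TSV so tests can join against it."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(
            [SeqRecord(lid, self.ancestral[lid]) for lid in self.locus_ids],
            outdir / "truth_ancestral.fasta",
        )
        for g in GENOTYPES:
            write_fasta(
                [
                    SeqRecord(f"{lid}", self.haplotypes[(g, lid)][0])
                    for lid in self.locus_ids
                ],
                outdir / f"truth_{g}_hap1.fasta",
            )
        with open(outdir / "truth_loci.tsv", "w") as fh:
            fh.write("locus\tgenotype\thet_sites\texpression_weight\tparalog_of\n")
            for lid in self.locus_ids:
                for g in GENOTYPES:
                    sites = ",".join(map(str, self.het_sites[(g, lid)])) or "-"
                    fh.write(
                        f"{lid}\t{g}\t{sites}\t"
                        f"{self.expression[(g, lid)]:.6g}\t"
                        f"{self.paralog_of.get(lid, '-')}\n"
                    )
        with open(outdir / "truth_contigs.tsv", "w") as fh:
            fh.write("contig\tgenotype\tlocus\n")
            for cid, (g, lid) in sorted(self.contig_map.items()):
                fh.write(f"{cid}\t{g}\t{lid}\n")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Jukes-Cantor-like substitution: each site flips to one of the
    three other bases with probability ``rate``; no indels."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    for i in idx:
        choices = BASES[BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_transcriptome(config: SimulationConfig) -> TruthSet:
    """Simulate the four-genotype truth set.

    The outgroup diverges from the ingroup ancestor at the interspecific
    rate; each ingroup genotype diverges at half the intraspecific rate
    so that realized *pairwise* ingroup divergence matches the
    intraspecific setting.  Heterozygous sites are injected per
    mating-system rate; paralog families are created by duplicating loci
    and mutating the copy down to ``paralog_identity``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_loci
    lengths_arr = np.maximum(
        config.min_locus_length,
        rng.lognormal(config.locus_length_meanlog, config.locus_length_sdlog, n).astype(int),
    )
    locus_ids = [f"L{i:05d}" for i in range(n)]
    ancestral = {lid: _random_seq(rng, int(L)) for lid, L in zip(locus_ids, lengths_arr)}

    # paralog duplication happens before speciation
    n_par = int(round(config.paralog_family_fraction * n))
    primaries = list(rng.choice(n, size=n_par, replace=False)) if n_par else []
    paralog_families: dict[str, list[str]] = {}
    paralog_of: dict[str, str] = {}
    for j, pi in enumerate(sorted(primaries)):
        primary = locus_ids[pi]
        dup = f"{primary}p"
        ancestral[dup] = _mutate(rng, ancestral[primary], 1.0 - config.paralog_identity)
        locus_ids.append(dup)
        paralog_families[f"fam{j:04d}"] = [primary, dup]
        paralog_of[dup] = primary
    lengths = {lid: len(s) for lid, s in ancestral.items()}

    intra = config.intraspecific_divergence
    inter = config.interspecific_divergence
    haplotypes: dict[tuple[str, str], tuple[str, str]] = {}
    het_sites: dict[tuple[str, str], list[int]] = {}
    for lid in locus_ids:
        anc = ancestral[lid]
        if config.selfer2_sister_to_outcrosser:
            node = _mutate(rng, anc, intra / 4)
            base = {
                "outcrosser": _mutate(rng, node, intra / 4),
                "selfer2": _mutate(rng, node, intra / 4),
                "selfer1": _mutate(rng, anc, intra / 2),
            }
        else:
            base = {g: _mutate(rng, anc, intra / 2) for g in INGROUP}
        base["outgroup"] = _mutate(rng, anc, inter)
        for g in GENOTYPES:
            rate = (
                config.het_rate_outcrosser if g == "outcrosser" else config.het_rate_selfer
            )
            hap1 = base[g]
            sites: list[int] = []
            if rng.random() < rate:
                k = 1 + rng.poisson(max(config.het_sites_mean - 1.0, 0.0))
                k = min(k, len(hap1))
                sites = sorted(rng.choice(len(hap1), size=k, replace=False).tolist())
            hap2 = hap1
            if sites:
                arr = np.frombuffer(hap1.encode(), dtype="S1").copy()
                for pos in sites:
                    choices = BASES[BASES != arr[pos]]
                    arr[pos] = rng.choice(choices)
                hap2 = arr.tobytes().decode()
            haplotypes[(g, lid)] = (hap1, hap2)
            het_sites[(g, lid)] = sites

    # expression: shared locus effect + per-genotype lognormal noise,
    # larger for the outgroup so ingroup pairs correlate more strongly
    expression: dict[tuple[str, str], float] = {}
    locus_mu = rng.normal(config.expression_meanlog, config.expression_sdlog, len(locus_ids))
    for mu, lid in zip(locus_mu, locus_ids):
        for g in GENOTYPES:
            s = (
                config.expression_noise_outgroup
                if g == "outgroup"
                else config.expression_noise_ingroup
            )
            expression[(g, lid)] = float(np.exp(mu + rng.normal(0.0, s)))

    return TruthSet(
        config=config,
        locus_ids=locus_ids,
        lengths=lengths,
        ancestral=ancestral,
        haplotypes=haplotypes,
        het_sites=het_sites,
        paralog_families=paralog_families,
        paralog_of=paralog_of,
        expression=expression,
    )


def _quality_profile(rng: np.random.Generator, length: int) -> np.ndarray:
    """Deterministic Q38→Q15 linear decay plus small integer noise."""
    base = np.round(np.linspace(38.0, 15.0, length)).astype(int)
    noise = rng.integers(-2, 3, size=length)
    return np.clip(base + noise, 2, 40)


def _nominal_profile_error(length: int) -> float:
    base = np.round(np.linspace(38.0, 15.0, length)).astype(int)
    return float(np.mean(10.0 ** (-base / 10.0)))


def simulate_reads(
    truth: TruthSet, config: SimulationConfig | None = None
) -> dict[str, tuple[list[SeqRecord], list[SeqRecord]]]:
    """Sample paired-end reads per genotype.

    Fragment counts per locus are Poisson with mean proportional to
    expression weight × length, scaled so realized coverage matches
    ``mean_coverage``.  Per-base errors are drawn consistent with the
    emitted decaying qualities, globally scaled to ``read_error_rate``.
    Realized fragment counts are recorded in ``truth.fragment_counts``.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.read_length
    scale = (
        config.read_error_rate / _nominal_profile_error(L)
        if config.read_error_rate > 0
        else 0.0
    )
    out: dict[str, tuple[list[SeqRecord], list[SeqRecord]]] = {}
    for g in GENOTYPES:
        weights = np.array(
            [truth.expression[(g, lid)] * truth.lengths[lid] for lid in truth.locus_ids]
        )
        total_bases = config.mean_coverage * sum(truth.lengths.values())
        total_frags = total_bases / (2.0 * L)
        lam = weights / weights.sum() * total_frags
        n_frags = rng.poisson(lam)
        reads1: list[SeqRecord] = []
        reads2: list[SeqRecord] = []
        for lid, nf in zip(truth.locus_ids, n_frags):
            truth.fragment_counts[(g, lid)] = int(nf)
            if nf == 0:
                continue
            hap_pair = truth.haplotypes[(g, lid)]
            locus_len = truth.lengths[lid]
            for j in range(nf):
                hap = hap_pair[int(rng.integers(2))]
                flen = int(
                    np.clip(
                        rng.normal(config.fragment_length_mean, config.fragment_length_sd),
                        L,
                        locus_len,
                    )
                )
                start = int(rng.integers(0, locus_len - flen + 1))
                frag = hap[start : start + flen]
                rid = f"{g}:{lid}:{j}"
                for mate, seq in ((1, frag[:L]), (2, revcomp(frag)[:L])):
                    quals = _quality_profile(rng, len(seq))
                    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
                    if scale > 0:
                        perr = np.minimum(scale * 10.0 ** (-quals / 10.0), 0.75)
                        hit = np.nonzero(rng.random(len(seq)) < perr)[0]
                        for i in hit:
                            arr[i] = rng.choice(BASES[BASES != arr[i]])
                    rec = SeqRecord(f"{rid}/{mate}", arr.tobytes().decode(), quals.tolist())
                    (reads1 if mate == 1 else reads2).append(rec)
        out[g] = (reads1, reads2)
    return out


def emit_contigs(
    truth: TruthSet, config: SimulationConfig | None = None
) -> dict[str, list[SeqRecord]]:
    """Emit assembler-like per-genotype contig sets.

    One contig per expressed locus (the hap1 allele), with a fraction of
    loci split into two overlapping fragments, a fraction emitting a
    second >99%-identical allelic duplicate (the hap2 allele), plus
    short junk contigs below 100 bp.  Contig→locus provenance is
    recorded in ``truth.contig_map``.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    out: dict[str, list[SeqRecord]] = {}
    for g in GENOTYPES:
        contigs: list[SeqRecord] = []
        idx = 0
        for lid in truth.locus_ids:
            if truth.expression[(g, lid)] <= 0:
                continue
            hap1, hap2 = truth.haplotypes[(g, lid)]
            if rng.random() < config.fragmentation_rate and len(hap1) >= 400:
                split = int(rng.integers(150, len(hap1) - 150))
                overlap = int(rng.integers(0, 51))
                pieces = [hap1[: split + overlap], hap1[split:]]
            else:
                pieces = [hap1]
            for piece in pieces:
                cid = f"{g}_c{idx:06d}"
                contigs.append(SeqRecord(cid, piece))
                truth.contig_map[cid] = (g, lid)
                idx += 1
            if rng.random() < config.allelic_duplicate_rate:
                cid = f"{g}_c{idx:06d}"
                contigs.append(SeqRecord(cid, hap2))
                truth.contig_map[cid] = (g, lid)
                idx += 1
        n_junk = rng.poisson(config.junk_short_contig_rate * config.n_loci)
        for _ in range(n_junk):
            cid = f"{g}_c{idx:06d}"
            contigs.append(SeqRecord(cid, _random_seq(rng, int(rng.integers(50, 100)))))
            truth.contig_map[cid] = (g, "junk")
            idx += 1
        out[g] = contigs
    return out


GO_ONTOLOGY = [f"GO:{7000001 + i:07d}" for i in range(25)]


def emit_annotations(
    truth: TruthSet, seed: int | None = None
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Translate each truth locus into a guide protein and assign GO terms.

    Guides translate the ancestral sequence in frame 0 (stops written as
    X so downstream protein alignment sees a plain residue alphabet);
    fragments of one locus necessarily share the locus guide.  Each
    locus draws 1-5 terms from a small fixed ontology.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([truth.config.seed if seed is None else seed, 3])
    )
    guides: list[SeqRecord] = []
    go_map: dict[str, list[str]] = {}
    for lid in truth.locus_ids:
        nt = truth.ancestral[lid]
        nt = nt[: len(nt) - len(nt) % 3]
        prot = str(Seq(nt).translate()).replace("*", "X")
        guides.append(SeqRecord(f"guide_{lid}", prot))
        k = int(rng.integers(1, 6))
        go_map[lid] = sorted(rng.choice(GO_ONTOLOGY, size=k, replace=False).tolist())
    return guides, go_map


def write_go_map(go_map: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            fh.write(f"{gene}\t{','.join(go_map[gene])}\n")


def read_go_map(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, terms = line.split("\t")
            out[gene] = terms.split(",")
    return out


def write_reads(
    reads: dict[str, tuple[list[SeqRecord], list[SeqRecord]]], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g, (r1, r2) in reads.items():
        write_fastq(r1, outdir / f"{g}_1.fastq")
        write_fastq(r2, outdir / f"{g}_2.fastq")


def write_contigs(contigs: dict[str, list[SeqRecord]], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for g, recs in contigs.items():
        write_fasta(recs, outdir / f"{g}_contigs.fasta")


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
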