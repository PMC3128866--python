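"""Conservative locus selection, pairwise divergence and Watterson's θ_W.

Downstream population genetics uses only a conservative locus set:
loci present in every sample and with zero heterozygous sites in every
selfing genotype — the loci for which paralogy/mis-mapping gives no
signal.  Pairwise SNPs are counted over sites that are unambiguous and
homozygous in both samples; Watterson's θ_W = S / (a_n · L) estimates
per-site polymorphism from S segregating sites among n sequences over
L shared sites, a_n = Σ_{i=1}^{n−1} 1/i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .genotyping import LocusGenotype

_HOMOZYGOUS = set("ACGT")


@dataclass
class ConservativeSet:
    locus_ids: list[str]
    total_length: int


@dataclass
class PairDivergence:
    snp_count: int
    site_count: int

    @property
    def divergence(self) -> float:
        return divergence(self.snp_count, self.site_count)


@dataclass
class WattersonResult:
    n: int
    segregating_sites: int
    a_n: float
    length: int
    theta_w: float


def conservative_set(
    locus_genotypes: dict[str, dict[str, LocusGenotype]],
    selfer_labels: list[str],
) -> ConservativeSet:
    """Loci present in all samples and homozygous in all selfers."""
    samples = sorted(locus_genotypes)
    common = None
    for s in samples:
        ids = {lid for lid, lg in locus_genotypes[s].items() if lg.present}
        common = ids if common is None else common & ids
    common = common or set()
    keep = [
        lid
        for lid in sorted(common)
        if all(locus_genotypes[s][lid].het_site_count == 0 for s in selfer_labels)
    ]
    total = sum(len(locus_genotypes[samples[0]][lid].sequence) for lid in keep)
    return ConservativeSet(keep, total)


def count_snps(
    genotypes_a: dict[str, LocusGenotype],
    genotypes_b: dict[str, LocusGenotype],
    cset: ConservativeSet,
) -> PairDivergence:
    """Fixed differences between two samples over the conservative set.

    Only sites where both calls are unambiguous homozygotes are
    compared (heterozygous sites are excluded rather than scored as
    half differences); differing calls count one SNP.
    """
    snps = sites = 0
    for lid in cset.locus_ids:
        a = genotypes_a[lid].sequence
        b = genotypes_b[lid].sequence
        for x, y in zip(a, b):
            if x in _HOMOZYGOUS and y in _HOMOZYGOUS:
                sites += 1
                if x != y:
                    snps += 1
    return PairDivergence(snps, sites)


def divergence(snp_count: int, site_count: int) -> float:
    """Per-site divergence: SNP count over compared sites."""
    if site_count <= 0:
        raise ValueError("site_count must be positive")
    return snp_count / site_count


def harmonic_number(n_minus_1: int) -> float:
    return sum(1.0 / i for i in range(1, n_minus_1 + 1))


def watterson_theta(
    sample_genotypes: list[dict[str, LocusGenotype]],
    cset: ConservativeSet,
) -> WattersonResult:
    """θ_W over columns unambiguous (homozygous call) in all n samples."""
    n = len(sample_genotypes)
    if n < 2:
        raise ValueError("need at least two samples")
    S = 0
    L = 0
    for lid in cset.locus_ids:
        seqs = [g[lid].sequence for g in sample_genotypes]
        for col in zip(*seqs):
            if all(b in _HOMOZYGOUS for b in col):
                L += 1
                if len(set(col)) > 1:
                    S += 1
    a_n = harmonic_number(n - 1)
    if L == 0:
        raise ValueError("no shared unambiguous sites")
    return WattersonResult(n, S, a_n, L, S / (a_n * L))


def theta_from_counts(S: int, n: int, L: int) -> float:
    """θ_W from summary counts (formula path)."""
    if n < 2 or L <= 0:
        raise ValueError("need n >= 2 and L > 0")
    return S / (harmonic_number(n - 1) * L)


def divergence_matrix(
    locus_genotypes: dict[str, dict[str, LocusGenotype]],
    cset: ConservativeSet,
) -> dict[tuple[str, str], PairDivergence]:
    """All unordered sample pairs; stored symmetrically."""
    samples = sorted(locus_genotypes)
    out: dict[tuple[str, str], PairDivergence] = {}
    for i, a in enumerate(samples):
        for b in samples[i + 1 :]:
            pd = count_snps(locus_genotypes[a], locus_genotypes[b], cset)
            out[(a, b)] = pd
            out[(b, a)] = pd
    return out


def write_divergence_matrix(
    matrix: dict[tuple[str, str], PairDivergence],
    samples: list[str],
    path: str | Path,
) -> None:
    """SNP counts in the lower triangle, per-site divergence in the upper."""
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(samples) + "\n")
        for i, a in enumerate(samples):
            row = [a]
            for j, b in enumerate(samples):
                if i == j:
                    row.append("-")
                elif i > j:
                    row.append(str(matrix[(a, b)].snp_count))
                else:
                    row.append(f"{matrix[(a, b)].divergence:.3f}")
            fh.write("\t".join(row) + "\n")
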