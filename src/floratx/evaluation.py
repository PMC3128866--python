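"""Validation experiments: simulation studies that measure how well each
stage of the pipeline recovers known truth.

Each function builds its own synthetic inputs from a seed, runs the
relevant pipeline components, and returns measured quantities (rates,
estimates, orderings).  They back both the acceptance test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import genotyping as gt
from .consensus import build_groups, consense
from .exprstats import bootstrap_ci, differential_expression
from .genotyping import GENOTYPE_PAIRS, _site_posteriors
from .popgen import ConservativeSet, divergence_matrix, watterson_theta
from .seqio import SeqRecord
from .simulate import (
    GENOTYPES,
    SimulationConfig,
    emit_contigs,
    simulate_reads,
    simulate_transcriptome,
)

INGROUP = ("outcrosser", "selfer1", "selfer2")
SELFERS = ["selfer1", "selfer2", "outgroup"]


def zero_divergence_config(n_loci: int = 30, seed: int = 13) -> SimulationConfig:
    """All divergences, het rates, errors and contig artifacts off."""
    return SimulationConfig(
        n_loci=n_loci,
        seed=seed,
        interspecific_divergence=0.0,
        intraspecific_divergence=0.0,
        het_rate_outcrosser=0.0,
        het_rate_selfer=0.0,
        paralog_family_fraction=0.0,
        fragmentation_rate=0.0,
        allelic_duplicate_rate=0.0,
        junk_short_contig_rate=0.0,
        read_error_rate=0.0,
    )


def zero_divergence_run(n_loci: int = 30, seed: int = 13) -> dict:
    """Full in-memory run under zero divergence.

    Returns whether consensus construction reconstructs every truth
    locus byte-exactly and the maximum entry of the divergence matrix
    of called genotypes (which should be zero).
    """
    cfg = zero_divergence_config(n_loci, seed)
    truth = simulate_transcriptome(cfg)
    contigs = emit_contigs(truth, cfg)
    groups, leftovers = build_groups(contigs)
    consensi = [consense(g) for g in groups]
    reconstructed = {c.seq for c in consensi} == set(truth.ancestral.values())

    reads = simulate_reads(truth, cfg)
    reference = sorted(consensi, key=lambda c: c.id)
    index = gt.ReferenceIndex(reference)
    genotypes = {}
    for g in GENOTYPES:
        r1, r2 = reads[g]
        alns = gt.map_reads(r1 + r2, index)
        genotypes[g] = gt.genotype_sample(alns, reference)
    shared = [
        lid
        for lid in sorted(genotypes["outcrosser"])
        if all(genotypes[g][lid].present for g in GENOTYPES)
    ]
    ref_len = {r.id: len(r) for r in reference}
    cset = ConservativeSet(shared, sum(ref_len[lid] for lid in shared))
    matrix = divergence_matrix(genotypes, cset)
    max_div = max(pd.divergence for pd in matrix.values()) if matrix else 0.0
    return {
        "reconstructed_exactly": reconstructed,
        "n_groups": len(groups),
        "n_leftovers": len(leftovers),
        "max_called_divergence": max_div,
        "n_shared_loci": len(shared),
    }


def caller_concordance(
    n_sites: int = 10_000,
    coverage: int = 20,
    error_rate: float = 0.01,
    het_fraction: float = 0.2,
    seed: int = 0,
) -> float:
    """Genotype-call concordance on simulated pileup columns.

    True genotypes are homozygous or (with ``het_fraction``) balanced
    heterozygotes; observations carry uniform base qualities matching
    the error rate.  Concordance is measured over unambiguous calls.
    """
    rng = np.random.default_rng(seed)
    q = int(round(-10 * np.log10(error_rate))) if error_rate > 0 else 40
    correct = called = 0
    for _ in range(n_sites):
        if rng.random() < het_fraction:
            a, b = rng.choice(4, size=2, replace=False)
            true = tuple(sorted((int(a), int(b))))
        else:
            a = int(rng.integers(4))
            true = (a, a)
        alleles = rng.choice(true, size=coverage)
        errors = rng.random(coverage) < error_rate
        obs = alleles.copy()
        for i in np.nonzero(errors)[0]:
            obs[i] = rng.choice([x for x in range(4) if x != alleles[i]])
        post = _site_posteriors(obs, np.full(coverage, q, dtype=float), 0.001)
        gi = int(np.argmax(post))
        qual = -10 * np.log10(max(1 - post[gi], 1e-10))
        if coverage > 5 and qual > 13:
            called += 1
            if tuple(sorted(GENOTYPE_PAIRS[gi])) == true:
                correct += 1
    return correct / called if called else 0.0


def paralog_flag_sensitivity(
    n_seeds: int = 10,
    n_loci: int = 30,
    paralog_family_fraction: float = 0.3,
    paralog_identity: float = 0.97,
    base_seed: int = 0,
) -> float:
    """SUSPECT-flag sensitivity when the reference holds one family member.

    Reads from both paralog copies are mapped against a reference that
    contains only the primary copy; the mis-mapped reads from the
    diverged copy create shared apparent heterozygosity in the selfers,
    which the flag should catch.  Returns the pooled fraction of
    paralogous primary loci flagged SUSPECT.
    """
    flagged = total = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_loci=n_loci,
            paralog_family_fraction=paralog_family_fraction,
            paralog_identity=paralog_identity,
            seed=base_seed + 1000 + i,
        )
        truth = simulate_transcriptome(cfg)
        primaries = [lid for lid in truth.locus_ids if lid not in truth.paralog_of]
        reference = [SeqRecord(lid, truth.ancestral[lid]) for lid in primaries]
        index = gt.ReferenceIndex(reference)
        reads = simulate_reads(truth, cfg)
        genotypes = {}
        for g in GENOTYPES:
            r1, r2 = reads[g]
            alns = gt.map_reads(r1 + r2, index)
            genotypes[g] = gt.genotype_sample(alns, reference)
        flags = gt.flag_mapping_errors(genotypes, SELFERS)
        for fam, (primary, _dup) in truth.paralog_families.items():
            total += 1
            if flags.get(primary) == "SUSPECT":
                flagged += 1
    return flagged / total if total else 0.0


def het_ordering_success(
    n_seeds: int = 10, n_loci: int = 300, base_seed: int = 0
) -> int:
    """Seeds (of ``n_seeds``) where the outcrosser has strictly more
    heterozygous loci than each selfer, under default het rates."""
    ok = 0
    for i in range(n_seeds):
        truth = simulate_transcriptome(
            SimulationConfig(n_loci=n_loci, seed=base_seed + 2000 + i)
        )
        n_out = truth.het_locus_count("outcrosser")
        if n_out > truth.het_locus_count("selfer1") and n_out > truth.het_locus_count(
            "selfer2"
        ):
            ok += 1
    return ok


def theta_recovery(
    n_reps: int = 20, n_loci: int = 30, base_seed: int = 0
) -> tuple[float, float, float]:
    """θ_W over the three ingroup genotypes' true haplotypes.

    Returns (mean θ_W across replicates, standard error, generating
    pairwise polymorphism rate).
    """
    thetas = []
    for i in range(n_reps):
        cfg = SimulationConfig(
            n_loci=n_loci, seed=base_seed + 3000 + i, paralog_family_fraction=0.0
        )
        truth = simulate_transcriptome(cfg)
        gts = []
        for g in INGROUP:
            gts.append(
                {
                    lid: gt.LocusGenotype(
                        lid, truth.haplotypes[(g, lid)][0], 20.0, 0, True
                    )
                    for lid in truth.locus_ids
                }
            )
        cset = ConservativeSet(truth.locus_ids, sum(truth.lengths.values()))
        thetas.append(watterson_theta(gts, cset).theta_w)
    arr = np.array(thetas)
    se = float(arr.std(ddof=1) / np.sqrt(n_reps))
    return float(arr.mean()), se, SimulationConfig().intraspecific_divergence


def de_null_false_positive_rate(
    n_loci: int = 1000, fdr: float = 0.05, seed: int = 0
) -> float:
    """Fraction of loci called significant when no locus is truly DE."""
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.normal(3.0, 1.0, size=n_loci))
    counts_a = {f"L{i}": int(rng.poisson(lam[i])) for i in range(n_loci)}
    counts_b = {f"L{i}": int(rng.poisson(lam[i])) for i in range(n_loci)}
    lengths = {f"L{i}": 1000 for i in range(n_loci)}
    res = differential_expression(
        counts_a,
        counts_b,
        sum(counts_a.values()),
        sum(counts_b.values()),
        lengths,
        fdr=fdr,
    )
    return sum(r.significant for r in res) / len(res)


def bootstrap_ci_coverage(
    n_datasets: int = 200,
    n: int = 200,
    rho: float = 0.8,
    reps: int = 2000,
    seed: int = 0,
) -> float:
    """Empirical coverage of the 95% bootstrap CI for a known correlation."""
    rng = np.random.default_rng(seed)
    cover = 0
    for i in range(n_datasets):
        z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
        lo, hi = bootstrap_ci(z[:, 0], z[:, 1], reps=reps, seed=seed + 5000 + i)
        cover += lo <= rho <= hi
    return cover / n_datasets


def topology_divergence_ordering(n_loci: int = 100, seed: int = 0) -> bool:
    """With selfer2 splitting from the outcrosser lineage more recently,
    the realized divergence ordering must match the configured topology."""
    cfg = SimulationConfig(n_loci=n_loci, seed=seed, selfer2_sister_to_outcrosser=True)
    truth = simulate_transcriptome(cfg)
    d_os2 = truth.pairwise_divergence("outcrosser", "selfer2")
    d_os1 = truth.pairwise_divergence("outcrosser", "selfer1")
    d_s12 = truth.pairwise_divergence("selfer1", "selfer2")
    return d_os2 < d_os1 and d_os2 < d_s12
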