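"""Expression quantification and comparison.

Fragment counts per locus are normalised to FPKM (fragments per
kilobase of transcript per million mapped fragments).  Between-sample
similarity is the Pearson correlation of log FPKM with bootstrap
percentile confidence intervals; differential expression uses an exact
two-sided binomial proportion test per locus with Benjamini–Hochberg
FDR control; GO enrichment uses a two-tailed Fisher's exact test per
term, also BH-corrected.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genotyping import AlignmentRecord


@dataclass
class ExpressionRecord:
    locus_id: str
    sample: str
    fragment_count: int
    locus_length: int
    fpkm: float


@dataclass
class CorrelationResult:
    sample_a: str
    sample_b: str
    r: float
    ci_low: float
    ci_high: float
    n_loci: int


@dataclass
class DEResult:
    locus_id: str
    count_a: int
    count_b: int
    fold_change: float      # FPKM ratio B/A; inf when A is zero
    infinite_fold: bool
    p: float
    q: float
    significant: bool

    @property
    def direction(self) -> str:
        return "up" if self.fold_change > 1 else "down"


@dataclass
class EnrichmentResult:
    term: str
    test_with: int
    test_without: int
    rest_with: int
    rest_without: int
    p: float
    q: float
    direction: str          # over / under in the test set
    significant: bool


def count_fragments(
    alignments: list[AlignmentRecord],
) -> tuple[dict[str, int], list[str]]:
    """One fragment per read pair with ≥1 mapped mate.

    Mate pairing is by read id stem (``/1``/``/2`` suffixes).  Pairs
    whose mates map to different loci are discarded and their ids
    returned as the discard log.
    """
    by_pair: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for a in alignments:
        if a.mapped:
            stem = a.read_id.rsplit("/", 1)[0]
            by_pair[stem].append(a)
    counts: dict[str, int] = defaultdict(int)
    discarded: list[str] = []
    for stem, mates in by_pair.items():
        loci = {m.locus_id for m in mates}
        if len(loci) == 1:
            counts[next(iter(loci))] += 1
        else:
            discarded.append(stem)
    return dict(counts), sorted(discarded)


def fpkm(count: int, locus_length: int, total_fragments: int) -> float:
    """count · 10^9 / (length · total mapped fragments)."""
    if locus_length <= 0 or total_fragments <= 0:
        raise ValueError("locus_length and total_fragments must be positive")
    return count * 1.0e9 / (locus_length * total_fragments)


def expression_table(
    counts: dict[str, int],
    lengths: dict[str, int],
    sample: str,
) -> dict[str, ExpressionRecord]:
    total = sum(counts.values())
    out = {}
    for lid, L in lengths.items():
        c = counts.get(lid, 0)
        out[lid] = ExpressionRecord(lid, sample, c, L, fpkm(c, L, total) if total else 0.0)
    return out


def log_correlation(
    fpkm_a: dict[str, float],
    fpkm_b: dict[str, float],
    pseudocount: float = 0.0,
) -> tuple[float, int, np.ndarray, np.ndarray]:
    """Pearson r of log FPKM over shared loci.

    With the default zero pseudocount, loci with zero FPKM in either
    sample are excluded (log undefined); a positive pseudocount keeps
    them as log(fpkm + pseudocount).  Returns (r, n, log_a, log_b).
    """
    shared = sorted(set(fpkm_a) & set(fpkm_b))
    a = np.array([fpkm_a[k] for k in shared])
    b = np.array([fpkm_b[k] for k in shared])
    if pseudocount > 0:
        a, b = a + pseudocount, b + pseudocount
    else:
        keep = (a > 0) & (b > 0)
        a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError("need at least 3 shared expressed loci")
    la, lb = np.log(a), np.log(b)
    if la.std() == 0 or lb.std() == 0:
        raise ValueError("degenerate variance in log FPKM")
    r = float(np.corrcoef(la, lb)[0, 1])
    return r, len(la), la, lb


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    reps: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the Pearson correlation.

    Loci are resampled with replacement; the (α/2, 1−α/2) percentiles
    of the replicate correlations form the interval.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(reps, n))
    xs, ys = x[idx], y[idx]
    xm = xs - xs.mean(axis=1, keepdims=True)
    ym = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (xm * ym).sum(axis=1) / denom
    rs = rs[np.isfinite(rs)]
    lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def correlate_samples(
    fpkm_a: dict[str, float],
    fpkm_b: dict[str, float],
    name_a: str,
    name_b: str,
    reps: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    r, n, la, lb = log_correlation(fpkm_a, fpkm_b)
    lo, hi = bootstrap_ci(la, lb, reps=reps, seed=seed)
    return CorrelationResult(name_a, name_b, r, lo, hi, n)


def differential_expression(
    counts_a: dict[str, int],
    counts_b: dict[str, int],
    total_a: int,
    total_b: int,
    lengths: dict[str, int],
    fdr: float = 0.05,
) -> list[DEResult]:
    """Per-locus exact binomial test of the A/B fragment split.

    Under equal relative expression a locus's fragments split between
    samples as Binomial(countA+countB, totalA/(totalA+totalB)); the
    two-sided exact p is BH-corrected across loci.  Fold change is the
    FPKM ratio B/A (flagged infinite when A has zero fragments).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("totals must be positive")
    loci = sorted(set(counts_a) | set(counts_b))
    p_null = total_a / (total_a + total_b)
    pvals = []
    rows = []
    for lid in loci:
        ca, cb = counts_a.get(lid, 0), counts_b.get(lid, 0)
        n = ca + cb
        p = 1.0 if n == 0 else stats.binomtest(ca, n, p_null).pvalue
        fa = fpkm(ca, lengths[lid], total_a)
        fb = fpkm(cb, lengths[lid], total_b)
        inf_fold = fa == 0 and fb > 0
        fold = math.inf if inf_fold else (fb / fa if fa > 0 else 1.0)
        pvals.append(p)
        rows.append((lid, ca, cb, fold, inf_fold))
    if not rows:
        return []
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [
        DEResult(lid, ca, cb, fold, inf_fold, p, q, bool(sig and q < fdr))
        for (lid, ca, cb, fold, inf_fold), p, q, sig in zip(rows, pvals, qvals, reject)
    ]


def intersect_de_sets(
    result_sets: list[list[DEResult]], direction: str
) -> set[str]:
    """Loci significant with the given direction in every comparison."""
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sets = []
    for results in result_sets:
        sets.append(
            {r.locus_id for r in results if r.significant and r.direction == direction}
        )
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher's exact p: the sum of probabilities of all
    tables (same margins) no more probable than the observed one."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def go_enrichment(
    test_set: set[str],
    reference_set: set[str],
    term_map: dict[str, list[str]],
    fdr: float = 0.05,
) -> list[EnrichmentResult]:
    """Per-term 2×2 Fisher's exact enrichment of the test set vs rest.

    Terms absent from the reference are skipped; direction is over- or
    under-representation of the term in the test set relative to the
    rest of the reference.
    """
    if not test_set:
        raise ValueError("empty test set")
    if not test_set <= reference_set:
        raise ValueError("test set must be a subset of the reference set")
    rest = reference_set - test_set
    genes_with: dict[str, set[str]] = defaultdict(set)
    for gene, terms in term_map.items():
        if gene in reference_set:
            for t in terms:
                genes_with[t].add(gene)
    rows = []
    for term in sorted(genes_with):
        tw = len(genes_with[term] & test_set)
        rw = len(genes_with[term] & rest)
        if tw + rw == 0:
            continue
        a, b = tw, len(test_set) - tw
        c, d = rw, len(rest) - rw
        p = fisher_two_tailed(a, b, c, d)
        test_frac = a / max(a + b, 1)
        rest_frac = c / max(c + d, 1)
        direction = "over" if test_frac > rest_frac else "under"
        rows.append((term, a, b, c, d, p, direction))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[5] for r in rows], alpha=fdr, method="fdr_bh")
    return [
        EnrichmentResult(term, a, b, c, d, p, q, direction, q < fdr)
        for (term, a, b, c, d, p, direction), q in zip(rows, qvals)
    ]


def write_expression_matrix(
    tables: dict[str, dict[str, ExpressionRecord]], path: str | Path
) -> None:
    samples = sorted(tables)
    loci = sorted({lid for t in tables.values() for lid in t})
    with open(path, "w") as fh:
        header = ["locus"] + [f"{s}_fpkm" for s in samples] + [f"{s}_count" for s in samples]
        fh.write("\t".join(header) + "\n")
        for lid in loci:
            row = [lid]
            row += [f"{tables[s][lid].fpkm:.4f}" if lid in tables[s] else "NA" for s in samples]
            row += [str(tables[s][lid].fragment_count) if lid in tables[s] else "NA" for s in samples]
            fh.write("\t".join(row) + "\n")
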