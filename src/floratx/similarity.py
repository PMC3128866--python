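"""Local nucleotide similarity search and reciprocal-best-hit grouping.

A seed-and-extend aligner stands in for an external BLAST: exact k-mer
seeds on both strands, then per-diagonal ungapped extension that takes
the maximal-scoring contiguous segment (match +1, mismatch −2).  Because
extension is ungapped, the best segment on a diagonal is found exactly
by a maximum-subarray scan, so reported identity agrees with a full
dynamic-programming aligner on indel-free pairs.

Hits feed best-hit tables and reciprocal-best-hit (RBH) pairing — the
standard ortholog-inference heuristic used to group contigs across
samples.  Externally produced tabular hits (BLAST outfmt-6 compatible)
can be ingested instead of running the internal aligner.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seqio import SeqRecord, revcomp


@dataclass
class Hit:
    """One local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    query_span: tuple[int, int]    # half-open, query forward coordinates
    subject_span: tuple[int, int]  # half-open, subject forward coordinates
    strand: str                    # '+' or '-'
    score: int                     # matches - 2*mismatches


def _best_segment(match: np.ndarray) -> tuple[int, int, int, int] | None:
    """Maximal-scoring contiguous segment of a 0/1 match vector under
    +1/−2 scoring.  Returns (start, end, score, n_match) or None."""
    scores = np.where(match, 1, -2)
    prefix = np.concatenate(([0], np.cumsum(scores)))
    running_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - running_min  # best segment ending at each position
    end = int(np.argmax(gains))
    best = int(gains[end])
    if best <= 0:
        return None
    a = int(np.argmax(prefix[: end + 1] == running_min[end]))
    b = end + 1
    n_match = int(match[a:b].sum())
    return a, b, best, n_match


def _diagonal_hit(q: str, s: str, diag: int) -> tuple[int, int, int, int, int] | None:
    """Best ungapped segment on diagonal ``diag`` (= spos − qpos).

    Returns (qstart, qend, score, n_match, aln_len)."""
    qa = np.frombuffer(q.encode(), dtype="S1")
    sa = np.frombuffer(s.encode(), dtype="S1")
    q0 = max(0, -diag)
    s0 = q0 + diag
    n = min(len(qa) - q0, len(sa) - s0)
    if n <= 0:
        return None
    match = qa[q0 : q0 + n] == sa[s0 : s0 + n]
    seg = _best_segment(match)
    if seg is None:
        return None
    a, b, score, n_match = seg
    return q0 + a, q0 + b, score, n_match, b - a


def find_hits(
    queries: list[SeqRecord],
    subjects: list[SeqRecord],
    min_aln_len: int = 100,
    min_identity: float = 0.90,
    k: int = 16,
    max_diagonals: int = 50,
) -> list[Hit]:
    """All qualifying local hits of each query against the subject set.

    Guaranteed to find any pair sharing a ≥95%-identity ungapped region
    of ≥2k bp (such a region must contain an exact k-mer).  Per
    query/subject pair only the best-scoring alignment is reported.
    """
    if not queries or not subjects:
        return []
    shortest = min(len(s) for s in subjects + queries)
    if k > shortest:
        raise ValueError(f"seed size {k} exceeds shortest sequence ({shortest} bp)")
    index: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for si, sub in enumerate(subjects):
        seq = sub.seq
        for pos in range(len(seq) - k + 1):
            index[seq[pos : pos + k]].append((si, pos))

    hits: list[Hit] = []
    for qry in queries:
        best_per_subject: dict[int, tuple[int, Hit]] = {}
        for strand in "+-":
            qseq = qry.seq if strand == "+" else revcomp(qry.seq)
            diags: dict[int, set[int]] = defaultdict(set)
            for qpos in range(len(qseq) - k + 1):
                for si, spos in index.get(qseq[qpos : qpos + k], ()):
                    diags[si].add(spos - qpos)
            for si, dset in diags.items():
                sub = subjects[si]
                if sub.id == qry.id:
                    continue
                cand = sorted(dset)
                if len(cand) > max_diagonals:
                    cand = cand[:: len(cand) // max_diagonals + 1]
                for diag in cand:
                    res = _diagonal_hit(qseq, sub.seq, diag)
                    if res is None:
                        continue
                    qstart, qend, score, n_match, aln_len = res
                    if aln_len < min_aln_len or n_match / aln_len < min_identity:
                        continue
                    if strand == "+":
                        qspan = (qstart, qend)
                    else:  # map back to query forward coordinates
                        qspan = (len(qseq) - qend, len(qseq) - qstart)
                    hit = Hit(
                        query_id=qry.id,
                        subject_id=sub.id,
                        identity=n_match / aln_len,
                        aln_len=aln_len,
                        query_span=qspan,
                        subject_span=(qstart + diag, qend + diag),
                        strand=strand,
                        score=score,
                    )
                    prev = best_per_subject.get(si)
                    if prev is None or score > prev[0]:
                        best_per_subject[si] = (score, hit)
        hits.extend(h for _, h in best_per_subject.values())
    return hits


def best_hit_table(hits: list[Hit]) -> dict[str, str]:
    """Per query, the max-score subject; score ties break to the
    lexicographically smallest subject id."""
    best: dict[str, tuple[int, str]] = {}
    for h in hits:
        key = (h.score, h.subject_id)
        cur = best.get(h.query_id)
        if cur is None or h.score > cur[0] or (h.score == cur[0] and h.subject_id < cur[1]):
            best[h.query_id] = (h.score, h.subject_id)
    return {q: s for q, (_, s) in best.items()}


def reciprocal_best_hits(
    fwd: dict[str, str], rev: dict[str, str]
) -> list[tuple[str, str]]:
    """(q, s) pairs where q's best subject is s and s's best subject is q."""
    return sorted(
        (q, s) for q, s in fwd.items() if rev.get(s) == q
    )


# ---------------------------------------------------------------------------
# tabular interchange

_HIT_COLUMNS = (
    "query",
    "subject",
    "pct_identity",
    "aln_len",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "strand",
    "score",
)


def write_hits_tsv(hits: list[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity * 100:.2f}\t{h.aln_len}\t"
                f"{h.query_span[0]}\t{h.query_span[1]}\t{h.subject_span[0]}\t"
                f"{h.subject_span[1]}\t{h.strand}\t{h.score}\n"
            )


def read_hits_tsv(path: str | Path) -> list[Hit]:
    hits = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query"):
            raise ValueError("not a hit TSV (missing header)")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            hits.append(
                Hit(
                    f[0], f[1], float(f[2]) / 100.0, int(f[3]),
                    (int(f[4]), int(f[5])), (int(f[6]), int(f[7])), f[8], int(f[9]),
                )
            )
    return hits


def read_blast6(path: str | Path) -> list[Hit]:
    """Ingest BLAST outfmt-6: qseqid sseqid pident length mismatch gapopen
    qstart qend sstart send evalue bitscore.  Strand inferred from subject
    coordinate order; 1-based inclusive converted to half-open 0-based."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            pident, length = float(f[2]), int(f[3])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            n_match = int(round(pident / 100.0 * length))
            hits.append(
                Hit(
                    f[0], f[1], pident / 100.0, length,
                    (qs - 1, qe), (ss - 1, se), strand,
                    n_match - 2 * (length - n_match),
                )
            )
    return hits
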