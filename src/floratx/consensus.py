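"""Consensus (reference) transcriptome construction.

Stages mirror a multi-sample de novo transcriptome workflow: collapse
near-identical contigs within each sample, group contigs across samples
by four-way reciprocal best hits, build per-group majority consensus
sequences that keep the longest member's overhangs, extend consensuses
with well-matching leftover contigs, join fragments that map to
non-overlapping regions of one guide protein, admit long annotatable
singletons, and finally re-collapse redundancy.  An assembly-accuracy
assessment flags chimeric consensuses against a trusted sequence set.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
import numpy as np
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

from .seqio import SeqRecord, revcomp
from .similarity import Hit, best_hit_table, find_hits, reciprocal_best_hits


@dataclass(frozen=True)
class GroupingCriteria:
    """Ortholog-grouping thresholds: minimum alignment length, minimum
    identity, and minimum aligned proportion of the shorter sequence
    (guards against collapsing alternatively spliced or partial
    contigs)."""

    min_aln_len: int = 200
    min_identity: float = 0.90
    min_aligned_prop: float = 0.80

    def __post_init__(self) -> None:
        if self.min_aln_len <= 0 or not (0 < self.min_identity <= 1) or not (
            0 < self.min_aligned_prop <= 1
        ):
            raise ValueError("invalid grouping criteria")


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, SeqRecord]          # sample -> contig
    strands: dict[str, str]                # contig id -> strand vs longest member
    consensus: SeqRecord | None = None


@dataclass
class TranscriptomeStats:
    n_contigs: int
    total_length: int
    mean_length: float
    n50: int


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def collapse_redundant(
    contigs: list[SeqRecord], min_contig_len: int = 100
) -> list[SeqRecord]:
    """Drop contigs below ``min_contig_len`` and collapse any pair that is
    >99% identical over ≥95% of the shorter contig, keeping the longer
    (ties break to the lexicographically smaller id).  Collapse is
    applied transitively: each connected component of qualifying pairs
    retains exactly one contig."""
    kept = [c for c in contigs if len(c) >= min_contig_len]
    if len(kept) < 2:
        return kept
    hits = find_hits(kept, kept, min_aln_len=min(50, min_contig_len), min_identity=0.99)
    by_id = {c.id: c for c in kept}
    uf = _UnionFind()
    for h in hits:
        shorter = min(len(by_id[h.query_id]), len(by_id[h.subject_id]))
        if h.identity > 0.99 and h.aln_len >= 0.95 * shorter:
            uf.union(h.query_id, h.subject_id)
    components: dict[str, list[SeqRecord]] = defaultdict(list)
    for c in kept:
        components[uf.find(c.id)].append(c)
    out = [
        max(comp, key=lambda c: (len(c), [-ord(x) for x in c.id]))
        for comp in components.values()
    ]
    return sorted(out, key=lambda c: c.id)


def build_groups(
    samples: dict[str, list[SeqRecord]],
    criteria: GroupingCriteria = GroupingCriteria(),
    min_samples: int = 2,
) -> tuple[list[OrthologGroup], list[SeqRecord]]:
    """Four-way RBH ortholog grouping.

    All directed pairwise comparisons are run; reciprocal best hits that
    pass the criteria are merged into groups by transitive closure.
    Groups keep at most one member per sample (conflicts resolved by
    total RBH score, losers returned to leftovers) and need members
    from at least ``min_samples`` distinct samples.

    Returns (groups, leftovers) where leftovers are contigs placed in
    no group.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    names = sorted(samples)
    by_id: dict[str, SeqRecord] = {}
    sample_of: dict[str, str] = {}
    for s, recs in samples.items():
        for r in recs:
            by_id[r.id] = r
            sample_of[r.id] = s

    pair_hits: dict[tuple[str, str], Hit] = {}
    uf = _UnionFind()
    edges: list[tuple[str, str, Hit]] = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = samples[names[i]], samples[names[j]]
            if not a or not b:
                continue
            fwd_hits = find_hits(a, b, criteria.min_aln_len, criteria.min_identity)
            rev_hits = find_hits(b, a, criteria.min_aln_len, criteria.min_identity)
            for q, s in reciprocal_best_hits(
                best_hit_table(fwd_hits), best_hit_table(rev_hits)
            ):
                h = next(x for x in fwd_hits if x.query_id == q and x.subject_id == s)
                shorter = min(len(by_id[q]), len(by_id[s]))
                if (
                    h.aln_len >= criteria.min_aln_len
                    and h.identity >= criteria.min_identity
                    and h.aln_len > criteria.min_aligned_prop * shorter
                ):
                    pair_hits[(q, s)] = h
                    pair_hits[(s, q)] = h
                    edges.append((q, s, h))
                    uf.union(q, s)

    components: dict[str, list[str]] = defaultdict(list)
    for cid in {c for e in edges for c in e[:2]}:
        components[uf.find(cid)].append(cid)

    groups: list[OrthologGroup] = []
    placed: set[str] = set()
    gid = 0
    for root in sorted(components):
        member_ids = components[root]
        # resolve sample conflicts: keep highest total-RBH-score member
        score_of = defaultdict(int)
        for q, s, h in edges:
            if uf.find(q) == root:
                score_of[q] += h.score
                score_of[s] += h.score
        chosen: dict[str, str] = {}
        for cid in sorted(member_ids, key=lambda c: (-score_of[c], c)):
            chosen.setdefault(sample_of[cid], cid)
        if len(chosen) < min_samples:
            continue
        member_recs = {s: by_id[c] for s, c in chosen.items()}
        strands = _orient_members(member_recs, edges, root, uf)
        if strands is None:
            continue
        groups.append(
            OrthologGroup(f"grp{gid:05d}", member_recs, strands)
        )
        placed.update(chosen.values())
        gid += 1
    leftovers = sorted(
        (r for r in by_id.values() if r.id not in placed), key=lambda r: r.id
    )
    return groups, leftovers


def _orient_members(
    members: dict[str, SeqRecord],
    edges: list[tuple[str, str, Hit]],
    root: str,
    uf: _UnionFind,
) -> dict[str, str] | None:
    """Strand of each member relative to the group's longest contig,
    propagated over the RBH edge graph."""
    ids = {r.id for r in members.values()}
    longest = max(members.values(), key=lambda r: (len(r), r.id)).id
    adj: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for q, s, h in edges:
        if q in ids and s in ids:
            adj[q].append((s, h.strand))
            adj[s].append((q, h.strand))
    strands = {longest: "+"}
    stack = [longest]
    while stack:
        cur = stack.pop()
        for nxt, strand in adj[cur]:
            flipped = "+" if (strands[cur] == "+") == (strand == "+") else "-"
            if nxt not in strands:
                strands[nxt] = flipped
                stack.append(nxt)
    if set(strands) != ids:  # disconnected after conflict resolution: re-anchor
        for cid in ids - set(strands):
            strands[cid] = "+"
    return strands


class GroupAlignmentError(ValueError):
    """Raised when grouped members cannot be stacked into one alignment."""


def consense(group: OrthologGroup) -> SeqRecord:
    """Majority-rule consensus over offset-stacked members.

    Members are ≥90% identical by construction, so each aligns to the
    longest member at a single ungapped offset (anchor diagonal).
    Columns take the majority base; ties take the longest member's base.
    Overhangs of any member extend the consensus beyond the longest
    member's span.
    """
    longest = max(group.members.values(), key=lambda r: (len(r), r.id))
    long_seq = (
        longest.seq if group.strands.get(longest.id, "+") == "+" else revcomp(longest.seq)
    )
    longest = SeqRecord(longest.id, long_seq)
    oriented: list[tuple[SeqRecord, int]] = [(longest, 0)]
    for rec in group.members.values():
        if rec.id == longest.id:
            continue
        seq = rec.seq if group.strands.get(rec.id, "+") == "+" else revcomp(rec.seq)
        o = _best_offset(seq, longest.seq)
        if o is None:
            raise GroupAlignmentError(
                f"{group.group_id}: member {rec.id} does not align to {longest.id}"
            )
        oriented.append((SeqRecord(rec.id, seq), o))

    lo = min(o for _, o in oriented)
    hi = max(o + len(r) for r, o in oriented)
    span = hi - lo
    counts = np.zeros((span, 4), dtype=np.int32)
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    longest_row = np.full(span, -1, dtype=np.int8)
    for rec, o in oriented:
        idx = np.array([code.get(b, -1) for b in rec.seq], dtype=np.int8)
        valid = idx >= 0
        pos = np.arange(len(rec.seq)) + (o - lo)
        np.add.at(counts, (pos[valid], idx[valid].astype(int)), 1)
        if rec.id == longest.id:
            longest_row[pos[valid]] = idx[valid]
    best = counts.max(axis=1)
    bases = []
    lut = "ACGT"
    for i in range(span):
        tied = np.nonzero(counts[i] == best[i])[0]
        if len(tied) == 1:
            bases.append(lut[tied[0]])
        elif longest_row[i] >= 0 and longest_row[i] in tied:
            bases.append(lut[longest_row[i]])
        else:
            bases.append(lut[tied[0]])
    return SeqRecord(group.group_id, "".join(bases))


def _best_offset(query: str, subject: str, k: int = 16) -> int | None:
    """Anchor offset of query on subject via k-mer diagonal voting."""
    index = defaultdict(list)
    for pos in range(len(subject) - k + 1):
        index[subject[pos : pos + k]].append(pos)
    votes: dict[int, int] = defaultdict(int)
    for qpos in range(0, len(query) - k + 1):
        for spos in index.get(query[qpos : qpos + k], ()):
            votes[spos - qpos] += 1
    if not votes:
        return None
    return max(votes, key=lambda d: (votes[d], -abs(d)))


@dataclass
class ExtensionLog:
    merged: list[tuple[str, str]] = field(default_factory=list)      # (leftover, consensus)
    ambiguous: list[str] = field(default_factory=list)
    rejected: list[str] = field(default_factory=list)


def incorporate_extensions(
    consensus_set: list[SeqRecord],
    leftovers: list[SeqRecord],
    min_identity: float = 0.95,
    min_overlap: int = 50,
    edge_slack: int = 5,
) -> tuple[list[SeqRecord], list[SeqRecord], ExtensionLog]:
    """Merge unplaced contigs that extend a consensus.

    A leftover is merged iff its best alignment to a consensus has
    identity > ``min_identity`` over > ``min_overlap`` bp, the aligned
    block is contiguous over the mutual overlap (no unalignable
    segment: the block must reach within ``edge_slack`` of both overlap
    ends), and an unaligned leftover tail extends the consensus.
    Leftovers extending two consensuses are left unmerged (ambiguous).
    Returns (updated consensus set, remaining leftovers, log).
    """
    cons = {c.id: c for c in consensus_set}
    log = ExtensionLog()
    remaining: list[SeqRecord] = []
    if consensus_set and leftovers:
        all_hits = find_hits(
            leftovers, list(cons.values()), min_aln_len=min_overlap + 1,
            min_identity=min_identity,
        )
    else:
        all_hits = []
    hits_by_query: dict[str, list[Hit]] = defaultdict(list)
    for h in all_hits:
        hits_by_query[h.query_id].append(h)
    for lo in leftovers:
        candidates = []
        for h in hits_by_query.get(lo.id, ()):
            if h.identity <= min_identity or h.aln_len <= min_overlap:
                continue
            target = cons[h.subject_id]
            ext = _extension_of(lo, target, h, edge_slack)
            if ext is not None:
                candidates.append((h, ext))
        if not candidates:
            remaining.append(lo)
            if hits_by_query.get(lo.id):
                log.rejected.append(lo.id)
            continue
        if len({h.subject_id for h, _ in candidates}) > 1:
            log.ambiguous.append(lo.id)
            remaining.append(lo)
            continue
        h, new_seq = max(candidates, key=lambda c: c[0].score)
        cons[h.subject_id] = SeqRecord(h.subject_id, new_seq)
        log.merged.append((lo.id, h.subject_id))
    return sorted(cons.values(), key=lambda c: c.id), remaining, log


def _extension_of(
    leftover: SeqRecord, target: SeqRecord, hit: Hit, edge_slack: int
) -> str | None:
    """Extended consensus sequence, or None if the hit does not qualify."""
    q = leftover.seq if hit.strand == "+" else revcomp(leftover.seq)
    qs, qe = hit.query_span
    if hit.strand == "-":
        qs, qe = len(q) - hit.query_span[1], len(q) - hit.query_span[0]
    ss, se = hit.subject_span
    s = target.seq
    diag = ss - qs
    # mutual overlap on the anchor diagonal
    o_q0 = max(0, -diag)
    o_len = min(len(q) - o_q0, len(s) - (o_q0 + diag))
    o_q1 = o_q0 + o_len
    # contiguity: aligned block must reach both overlap ends
    if qs - o_q0 > edge_slack or o_q1 - qe > edge_slack:
        return None
    right_tail_q = len(q) - o_q1
    right_tail_s = len(s) - (o_q1 + diag)
    # consensus core stays; leftover overhangs beyond it are appended
    core = s
    prefix = q[:o_q0] if diag < 0 else ""
    suffix = q[o_q1:] if right_tail_q > right_tail_s else ""
    if not prefix and not suffix:
        return None  # fully contained: no extension
    return prefix + core + suffix


# ---------------------------------------------------------------------------
# protein-guided fragment joining and singleton admission

@dataclass
class GuideHit:
    guide_id: str
    span: tuple[int, int]   # residues on the guide, half-open
    n_aligned: int
    identity: float
    frame_strand: str


_PROT_ALIGNER = PairwiseAligner(
    mode="local", match_score=1, mismatch_score=-1,
    open_gap_score=-5, extend_gap_score=-1,
)


def _six_frames(seq: str) -> list[tuple[str, str]]:
    frames = []
    for strand, nt in (("+", seq), ("-", revcomp(seq))):
        for off in range(3):
            sub = nt[off:]
            sub = sub[: len(sub) - len(sub) % 3]
            if len(sub) >= 30:
                frames.append((strand, str(Seq(sub).translate()).replace("*", "X")))
    return frames


def best_guide_hit(
    record: SeqRecord,
    guides: list[SeqRecord],
    guide_index: dict[str, list[int]] | None = None,
    k: int = 5,
) -> GuideHit | None:
    """Best translated match of a contig against the guide proteins.

    Six-frame translations are screened against a guide k-mer (amino
    acid) index; surviving candidates are aligned with a local protein
    aligner and the best-scoring alignment is reported with its guide
    coordinates."""
    if guide_index is None:
        guide_index = build_guide_index(guides, k)
    best: tuple[float, GuideHit] | None = None
    for strand, prot in _six_frames(record.seq):
        cand: dict[int, int] = defaultdict(int)
        for i in range(len(prot) - k + 1):
            for gi in guide_index.get(prot[i : i + k], ()):
                cand[gi] += 1
        for gi in sorted(cand, key=lambda g: -cand[g])[:3]:
            guide = guides[gi]
            aln = _PROT_ALIGNER.align(guide.seq, prot)
            if len(aln) == 0:
                continue
            a = aln[0]
            blocks = a.aligned[0]
            if len(blocks) == 0:
                continue
            g0, g1 = int(blocks[0][0]), int(blocks[-1][1])
            n_aligned = int(sum(b - a_ for a_, b in blocks))
            n_match = _alignment_matches(a)
            ident = n_match / n_aligned if n_aligned else 0.0
            score = float(a.score)
            gh = GuideHit(guide.id, (g0, g1), n_aligned, ident, strand)
            if best is None or score > best[0]:
                best = (score, gh)
    return None if best is None else best[1]


def _alignment_matches(a) -> int:
    t, q = a.target, a.query
    n = 0
    for (t0, t1), (q0, q1) in zip(a.aligned[0], a.aligned[1]):
        n += sum(x == y for x, y in zip(t[t0:t1], q[q0:q1]))
    return n


def build_guide_index(guides: list[SeqRecord], k: int = 5) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for gi, g in enumerate(guides):
        for i in range(len(g.seq) - k + 1):
            index[g.seq[i : i + k]].append(gi)
    return index


@dataclass
class JoinLog:
    joined: list[tuple[str, ...]] = field(default_factory=list)
    conflicting: list[tuple[str, ...]] = field(default_factory=list)


def join_fragments(
    consensus_set: list[SeqRecord],
    guides: list[SeqRecord],
    max_overlap: int = 15,
) -> tuple[list[SeqRecord], JoinLog]:
    """Join consensuses that are fragments of one protein.

    Consensuses sharing a best guide whose guide intervals overlap by at
    most ``max_overlap`` residues are concatenated in guide order with
    an N spacer three times the implied residue gap.  Fragments with
    conflicting order (interval overlap beyond tolerance) are left
    unjoined."""
    index = build_guide_index(guides)
    hits: dict[str, GuideHit] = {}
    for rec in consensus_set:
        gh = best_guide_hit(rec, guides, index)
        if gh is not None:
            hits[rec.id] = gh
    by_guide: dict[str, list[SeqRecord]] = defaultdict(list)
    for rec in consensus_set:
        if rec.id in hits:
            by_guide[hits[rec.id].guide_id].append(rec)

    log = JoinLog()
    out: list[SeqRecord] = []
    consumed: set[str] = set()
    for gid in sorted(by_guide):
        frags = by_guide[gid]
        if len(frags) < 2:
            continue
        frags = sorted(frags, key=lambda r: hits[r.id].span)
        ok = True
        for a, b in zip(frags, frags[1:]):
            overlap = hits[a.id].span[1] - hits[b.id].span[0]
            if overlap > max_overlap:
                ok = False
        if not ok:
            log.conflicting.append(tuple(r.id for r in frags))
            continue
        parts: list[str] = []
        for i, rec in enumerate(frags):
            seq = rec.seq if hits[rec.id].frame_strand == "+" else revcomp(rec.seq)
            if i > 0:
                gap = hits[rec.id].span[0] - hits[frags[i - 1].id].span[1]
                if gap > 0:
                    parts.append("N" * (3 * gap))
            parts.append(seq)
        joined_id = "+".join(r.id for r in frags)
        out.append(SeqRecord(joined_id, "".join(parts)))
        consumed.update(r.id for r in frags)
        log.joined.append(tuple(r.id for r in frags))
    out.extend(r for r in consensus_set if r.id not in consumed)
    return sorted(out, key=lambda r: r.id), log


def add_singletons(
    consensus_set: list[SeqRecord],
    leftovers: list[SeqRecord],
    guides: list[SeqRecord],
    min_len: int = 1000,
    min_aligned_residues: int = 50,
    min_guide_identity: float = 0.60,
) -> list[SeqRecord]:
    """Append long, guide-supported leftovers, then re-collapse redundancy.

    The guide criterion (≥``min_aligned_residues`` aligned residues at
    ≥``min_guide_identity`` identity) is a deliberate stand-in for an
    E-value threshold; it selects leftovers with credible protein
    homology."""
    index = build_guide_index(guides)
    added: list[SeqRecord] = []
    for rec in leftovers:
        if len(rec) < min_len:
            continue
        gh = best_guide_hit(rec, guides, index)
        if gh is None:
            continue
        if gh.n_aligned >= min_aligned_residues and gh.identity >= min_guide_identity:
            added.append(rec)
    return collapse_redundant(list(consensus_set) + added)


def transcriptome_stats(contigs: list[SeqRecord]) -> TranscriptomeStats:
    """Count, total bp, mean length and N50 of a contig set.

    N50 is the largest length L such that contigs of length ≥ L hold at
    least half the total bases."""
    if not contigs:
        raise ValueError("empty contig set")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for L in lengths:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    return TranscriptomeStats(len(lengths), total, total / len(lengths), n50)


@dataclass
class ConflictReport:
    n_assessed: int
    conflicts: list[tuple[str, str]]

    @property
    def n_conflicts(self) -> int:
        return len(self.conflicts)


def assess_against_reference(
    assembled: list[SeqRecord],
    trusted: list[SeqRecord],
    strong_len: int = 100,
    strong_identity: float = 0.95,
    flank_len: int = 50,
    flank_identity: float = 0.80,
) -> ConflictReport:
    """Conflict detection against a trusted sequence set.

    For each assembled contig's best trusted match: CONFLICT iff a
    ≥``strong_len`` bp region at ≥``strong_identity`` identity exists
    and another mutually overlapping region of ≥``flank_len`` bp aligns
    below ``flank_identity`` — the signature of a chimeric assembly.
    """
    if not assembled or not trusted:
        return ConflictReport(0, [])
    hits = find_hits(assembled, trusted, min_aln_len=strong_len, min_identity=strong_identity)
    best: dict[str, Hit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or h.score > cur.score:
            best[h.query_id] = h
    trusted_by_id = {t.id: t for t in trusted}
    asm_by_id = {a.id: a for a in assembled}
    conflicts: list[tuple[str, str]] = []
    for qid, h in sorted(best.items()):
        q = asm_by_id[qid].seq if h.strand == "+" else revcomp(asm_by_id[qid].seq)
        qs, qe = h.query_span
        if h.strand == "-":
            qs, qe = len(q) - h.query_span[1], len(q) - h.query_span[0]
        s = trusted_by_id[h.subject_id].seq
        diag = h.subject_span[0] - qs
        o_q0 = max(0, -diag)
        o_len = min(len(q) - o_q0, len(s) - (o_q0 + diag))
        o_q1 = o_q0 + o_len
        for f0, f1 in ((o_q0, qs), (qe, o_q1)):
            if f1 - f0 < flank_len:
                continue
            qa = np.frombuffer(q[f0:f1].encode(), dtype="S1")
            sa = np.frombuffer(s[f0 + diag : f1 + diag].encode(), dtype="S1")
            ident = float(np.mean(qa == sa)) if len(qa) else 1.0
            if ident < flank_identity:
                conflicts.append((qid, h.subject_id))
                break
    return ConflictReport(len(best), conflicts)
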