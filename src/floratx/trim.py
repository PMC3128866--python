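"""Quality-based read trimming.

Illumina base quality decays toward the 3' end of a read, so reads are
truncated at the first run of ``consecutive`` bases whose Phred quality
falls below ``q_threshold`` (default Q20, i.e. 1% error).  Leading and
trailing runs of ambiguous ``N`` bases are stripped first, and reads
shorter than ``min_length`` after trimming are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import SeqRecord


@dataclass(frozen=True)
class TrimPolicy:
    q_threshold: int = 20
    consecutive: int = 2
    min_length: int = 20

    def __post_init__(self) -> None:
        if self.q_threshold < 0 or self.consecutive < 1 or self.min_length < 1:
            raise ValueError("invalid trim policy")


def phred_error_prob(q: float) -> float:
    """Error probability of a Phred-scaled quality: 10^(-q/10)."""
    if q < 0:
        raise ValueError("Phred quality must be non-negative")
    return 10.0 ** (-q / 10.0)


def phred_from_error(p: float, cap: int = 99) -> int:
    """Phred-scale an error probability, capped (Q99 at p ~ 1.26e-10)."""
    import math

    if p <= 0:
        return cap
    return min(cap, int(round(-10.0 * math.log10(p))))


def trim_read(read: SeqRecord, policy: TrimPolicy = TrimPolicy()) -> SeqRecord | None:
    """Trim one read; return ``None`` when it is discarded.

    Steps, in order: strip terminal N runs; truncate immediately before
    the first window of ``consecutive`` sub-threshold qualities; discard
    if shorter than ``min_length``.  A single low-quality base does not
    trigger truncation.
    """
    if read.quals is None:
        raise ValueError(f"{read.id}: trimming requires qualities")
    seq, quals = read.seq, read.quals
    start = 0
    while start < len(seq) and seq[start] == "N":
        start += 1
    end = len(seq)
    while end > start and seq[end - 1] == "N":
        end -= 1
    seq, quals = seq[start:end], quals[start:end]

    k = policy.consecutive
    cut = len(seq)
    run = 0
    for i, q in enumerate(quals):
        run = run + 1 if q < policy.q_threshold else 0
        if run == k:
            cut = i - k + 1
            break
    seq, quals = seq[:cut], quals[:cut]
    if len(seq) < policy.min_length:
        return None
    return SeqRecord(read.id, seq, quals)


def trim_pairs(
    pairs: list[tuple[SeqRecord, SeqRecord]],
    policy: TrimPolicy = TrimPolicy(),
    keep_orphans: bool = False,
) -> list[tuple[SeqRecord, SeqRecord | None]]:
    """Trim mates independently; by default a pair survives only whole.

    With ``keep_orphans`` a surviving single mate is retained with its
    partner set to ``None``.
    """
    out: list[tuple[SeqRecord, SeqRecord | None]] = []
    for r1, r2 in pairs:
        t1, t2 = trim_read(r1, policy), trim_read(r2, policy)
        if t1 is not None and t2 is not None:
            out.append((t1, t2))
        elif keep_orphans and (t1 is not None or t2 is not None):
            surviving = t1 if t1 is not None else t2
            assert surviving is not None
            out.append((surviving, None))
    return out
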