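"""FASTQ preprocessing: adapter trimming, pair merging, quality filtering
and dereplication into a per-round variant count table.

This is a deliberately small reimplementation of the standard
amplicon-counting path (the published analyses of this kind delegate it to
pipelines such as DiMSum): exact adapter matching, best ungapped overlap
merging with quality-aware consensus, a minimum-base-quality filter, and
exact-sequence dereplication. Its fidelity target is the zero/low-error
regime used for simulator round-trips, not bit-compatibility with any
external pipeline.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ProcessedRead",
    "RoundTable",
    "trim_adapters",
    "merge_pair",
    "quality_filter",
    "dereplicate",
    "process_round",
    "read_fastq",
    "revcomp",
]

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ProcessedRead:
    """A merged (or surviving single) read with per-base Phred qualities."""

    sequence: str
    quality: tuple[int, ...]
    merged_from: str = "pair"  # pair | singleton

    @property
    def min_quality(self) -> int:
        return min(self.quality)


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Parse a FASTQ file into (id, sequence, quality-string) tuples."""
    with open(path) as fh:
        return [(rid, seq.upper(), qual) for rid, seq, qual in FastqGeneralIterator(fh)]


def trim_adapters(seq: str, qual: str, adapters, min_length: int = 10):
    """Remove adapter occurrences, keeping the longest adapter-free insert.

    Returns the trimmed ``(seq, qual)`` or None when the insert is shorter
    than ``min_length`` (a counted rejection, not an error).
    """
    spans = []
    for ad in adapters:
        if not ad:
            continue
        start = seq.find(ad)
        while start != -1:
            spans.append((start, start + len(ad)))
            start = seq.find(ad, start + 1)
    if not spans:
        frag = (0, len(seq))
    else:
        spans.sort()
        frags, prev = [], 0
        for a, b in spans:
            if a > prev:
                frags.append((prev, a))
            prev = max(prev, b)
        if prev < len(seq):
            frags.append((prev, len(seq)))
        if not frags:
            return None
        frag = max(frags, key=lambda f: f[1] - f[0])
    a, b = frag
    if b - a < min_length:
        return None
    return seq[a:b], qual[a:b]


def _qarr(qual: str) -> np.ndarray:
    return np.frombuffer(qual.encode(), dtype=np.uint8).astype(np.int16) - 33


def merge_pair(fwd: tuple[str, str], rev: tuple[str, str],
               min_overlap: int = 20, max_mismatch_frac: float = 0.10,
               qual_floor: int = 2) -> ProcessedRead | None:
    """Merge an inward-facing read pair by best ungapped overlap.

    The reverse read is reverse-complemented and slid along the forward
    read; the offset maximising (matches - mismatches) wins, ties broken
    towards the largest overlap. At agreeing positions the consensus takes
    the higher quality; at disagreements the higher-quality base is kept
    with quality ``max(|Qf - Qr|, qual_floor)``. Pairs whose best overlap is
    shorter than ``min_overlap`` or has a mismatch fraction above
    ``max_mismatch_frac`` are rejected (None).
    """
    fseq, fqual = fwd
    rseq_rc = revcomp(rev[0])
    rqual_rc = rev[1][::-1]
    fa = np.frombuffer(fseq.encode(), dtype=np.uint8)
    ra = np.frombuffer(rseq_rc.encode(), dtype=np.uint8)
    nf, nr = len(fa), len(ra)
    max_d = nf - min_overlap
    if max_d < 0:
        return None

    def score_at(d: int):
        o = min(nf - d, nr)
        if o < min_overlap:
            return None
        m = int((fa[d : d + o] == ra[:o]).sum())
        return 2 * m - o, o, o - m  # score, overlap, mismatches

    # seed candidate offsets via exact k-mer hits, fall back to a full scan
    candidates: list[int] = []
    for k0 in (0, 20, 40):
        if k0 + 16 > nr:
            break
        seed = rseq_rc[k0 : k0 + 16]
        start = fseq.find(seed)
        while start != -1:
            d = start - k0
            if 0 <= d <= max_d:
                candidates.append(d)
            start = fseq.find(seed, start + 1)
    best = None
    for d in sorted(set(candidates)):
        s = score_at(d)
        if s and (best is None or s[0] > best[0][0] or (s[0] == best[0][0] and d < best[1])):
            best = (s, d)
    if best is None or best[0][2] / best[0][1] > max_mismatch_frac:
        best = None
        for d in range(max_d + 1):
            s = score_at(d)
            if s and (best is None or s[0] > best[0][0]):
                best = (s, d)
    if best is None:
        return None
    (score, o, mism), d = best
    if mism / o > max_mismatch_frac:
        return None

    fq, rq = _qarr(fqual), _qarr(rqual_rc)
    ov_f, ov_r = fa[d : d + o], ra[:o]
    ov_fq, ov_rq = fq[d : d + o], rq[:o]
    agree = ov_f == ov_r
    take_f = ov_fq >= ov_rq
    cons = np.where(agree | take_f, ov_f, ov_r)
    cons_q = np.where(agree, np.maximum(ov_fq, ov_rq),
                      np.maximum(np.abs(ov_fq - ov_rq), qual_floor))
    seq = fseq[:d] + cons.tobytes().decode() + rseq_rc[o:]
    qual = np.concatenate([fq[:d], cons_q, rq[o:]])
    return ProcessedRead(seq, tuple(int(q) for q in qual), merged_from="pair")


def quality_filter(reads, min_q: int = 20):
    """Keep reads whose minimum base quality is at least ``min_q``."""
    return [r for r in reads if r.min_quality >= min_q]


@dataclass
class RoundTable:
    """Variant read counts per sorting round.

    ``rounds`` maps a round label to a Counter of exact (uppercased)
    nucleotide sequences.
    """

    rounds: dict[str, Counter] = field(default_factory=dict)

    def round_labels(self) -> list[str]:
        return list(self.rounds)

    def counts(self, label: str) -> Counter:
        return self.rounds[label]

    def total(self, label: str) -> int:
        return sum(self.rounds[label].values())

    def n_unique(self, label: str | None = None) -> int:
        if label is not None:
            return len(self.rounds[label])
        return len(self.sequences())

    def sequences(self) -> set[str]:
        out: set[str] = set()
        for c in self.rounds.values():
            out |= c.keys()
        return out

    def frequencies(self, label: str) -> dict[str, float]:
        tot = self.total(label)
        return {s: c / tot for s, c in self.rounds[label].items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rounds).fillna(0).astype(int)
        df.index.name = "sequence"
        return df.sort_index()

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "RoundTable":
        df = pd.read_csv(path, index_col="sequence")
        return cls({col: Counter({s: int(c) for s, c in df[col].items() if c > 0})
                    for col in df.columns})


def dereplicate(reads_per_round: dict[str, list]) -> RoundTable:
    """Group exact sequences (uppercased) and count them per round.

    Accepts plain sequence strings or ProcessedRead objects.
    """
    table = RoundTable()
    for label, reads in reads_per_round.items():
        seqs = (r.sequence if isinstance(r, ProcessedRead) else r for r in reads)
        table.rounds[label] = Counter(s.upper() for s in seqs)
    return table


def process_round(fastq1, fastq2, adapters=(), min_length: int = 10,
                  min_q: int = 20, min_overlap: int = 20,
                  max_mismatch_frac: float = 0.10):
    """Run trim -> merge -> quality filter -> N-bin for one round.

    Returns ``(sequences, report)`` where ``report`` counts every pair's
    fate exactly once (input = trimmed_rejected + merge_rejected +
    quality_rejected + ambiguous_n + passed).
    """
    r1, r2 = read_fastq(fastq1), read_fastq(fastq2)
    if len(r1) != len(r2):
        raise ValueError("unpaired FASTQ files")
    report = dict(input_pairs=len(r1), trimmed_rejected=0, merge_rejected=0,
                  quality_rejected=0, ambiguous_n=0, passed=0)
    out: list[str] = []
    for (_, s1, q1), (_, s2, q2) in zip(r1, r2):
        t1 = trim_adapters(s1, q1, adapters, min_length)
        t2 = trim_adapters(s2, q2, adapters, min_length)
        if t1 is None or t2 is None:
            report["trimmed_rejected"] += 1
            continue
        merged = merge_pair(t1, t2, min_overlap=min_overlap,
                            max_mismatch_frac=max_mismatch_frac)
        if merged is None:
            report["merge_rejected"] += 1
            continue
        if merged.min_quality < min_q:
            report["quality_rejected"] += 1
            continue
        if "N" in merged.sequence:
            report["ambiguous_n"] += 1
            continue
        report["passed"] += 1
        out.append(merged.sequence)
    return out, report
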