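"""Alignment ingestion and per-position pileup construction.

Three routes feed the pileup engine:

* truth alignments carried by simulated reads (exact, used by default for
  simulated runs);
* a built-in semi-global aligner (read fully aligned, free end gaps on the
  reference, affine gap penalties) for FASTQ without alignments;
* external SAM via pysam, with CIGAR ``M`` resolved to ``=``/``X`` against
  the reference.

Pileup conventions follow the standard dialect: every ``=``/``X`` adds one
base call at its reference position; a deletion adds one deletion call at
*each* deleted reference position (so deleted bases contribute to depth);
insertions are anchored to the preceding reference position and excluded
from depth. Single-base (and uniform multi-base) indels are left-normalized
within homopolymer runs so equivalent placements aggregate at one locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .simdata import (ReferenceRegion, SimulatedRead, encode, decode,
                      revcomp, ops_ref_span)

NEG_INF = -(10 ** 9)


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """A read expressed as reference-forward edit operations.

    ``ops`` consume exactly [ref_start, ref_start + ref span) on the
    reference; ``X``/``I`` operations carry their bases in reference-forward
    orientation.
    """

    read_id: str
    ref_start: int
    ops: tuple[tuple[int, str, str], ...]
    strand: str = "+"
    sample_id: str | None = None

    @property
    def ref_end(self) -> int:
        return self.ref_start + ops_ref_span(self.ops)


def _ops_ref_forward(ops: Sequence[tuple[int, str, str]], strand: str
                     ) -> tuple[tuple[int, str, str], ...]:
    """Convert read-orientation ops to reference-forward orientation."""
    if strand == "+":
        return tuple(ops)
    out = []
    for n, op, b in reversed(ops):
        out.append((n, op, revcomp(b) if b else b))
    return tuple(out)


def from_simulated(read: SimulatedRead) -> AlignedRead:
    """Turn a simulated read's truth record into an AlignedRead."""
    return AlignedRead(
        read_id=read.read_id, ref_start=read.ref_start,
        ops=_ops_ref_forward(read.ops, read.strand),
        strand=read.strand, sample_id=read.sample_id_truth)


def from_truth_record(rec) -> AlignedRead:
    return AlignedRead(
        read_id=rec.read_id, ref_start=rec.ref_start,
        ops=_ops_ref_forward(rec.ops, rec.strand),
        strand=rec.strand, sample_id=rec.sample)


# ---------------------------------------------------------------------------
# Built-in semi-global aligner (affine gaps)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scoring:
    """Alignment scores; a gap of length g costs ``gap_open + g*gap_extend``."""

    match: int = 1
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass(frozen=True)
class Alignment:
    ref_start: int
    ops: tuple[tuple[int, str, str], ...]
    score: int


def align_read(read_bases: str, ref_seq: str,
               scoring: Scoring = Scoring(),
               score_floor: int | None = None) -> Alignment | None:
    """Best semi-global alignment of the read against the reference.

    The read is aligned end-to-end; leading/trailing reference bases are
    free. Ties are broken deterministically: leftmost end position, and
    within equal-score paths match/mismatch is preferred over deletion over
    insertion. Returns None when the best score falls below ``score_floor``.
    """
    if not read_bases or not ref_seq:
        raise ValueError("read and reference must be non-empty")
    r = encode(read_bases)
    t = encode(ref_seq)
    m, n = len(r), len(t)
    oe = scoring.gap_open + scoring.gap_extend
    e = scoring.gap_extend

    M = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    I = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    D = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    # pointers: predecessor state of each cell (0=start,1=M,2=I,3=D)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pI = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pD = np.zeros((m + 1, n + 1), dtype=np.uint8)

    best_prev = np.zeros(n + 1, dtype=np.int32)  # row 0: free start anywhere
    state_prev = np.zeros(n + 1, dtype=np.uint8)  # 0 = start
    Mp = np.full(n + 1, NEG_INF, dtype=np.int32)
    Ip = np.full(n + 1, NEG_INF, dtype=np.int32)
    Dp = np.full(n + 1, NEG_INF, dtype=np.int32)

    jj = np.arange(n + 1, dtype=np.int64)
    for i in range(1, m + 1):
        sub = np.where(t == r[i - 1], scoring.match, scoring.mismatch)
        Mi = M[i]
        Mi[1:] = best_prev[:-1] + sub
        pM[i, 1:] = state_prev[:-1]

        # insertion (consumes read only): from previous row, same column
        cand_open = np.maximum(Mp + oe, Dp + oe)
        open_from = np.where(Mp >= Dp, 1, 3).astype(np.uint8)
        ext = Ip + e
        Ii = I[i]
        np.copyto(Ii, np.where(cand_open >= ext, cand_open, ext))
        pI[i] = np.where(cand_open >= ext, open_from, 2)

        # deletion (consumes ref only): prefix-scan within the row
        A = np.maximum(Mi, Ii)
        a_from = np.where(Mi >= Ii, 1, 2).astype(np.uint8)
        g = A + scoring.gap_open - e * jj
        g[0] = max(g[0], NEG_INF)
        run = np.maximum.accumulate(g[:-1])
        Di = D[i]
        Di[0] = NEG_INF
        Di[1:] = run + e * jj[1:]
        opened = Di[1:] == A[:-1] + oe
        pD[i, 1:] = np.where(opened, a_from[:-1], 3)

        best_prev = np.maximum(np.maximum(Mi, Ii), Di)
        # tie preference M > D > I for the next row's diagonal predecessor
        state_prev = np.where(Mi >= best_prev, 1,
                              np.where(Di >= best_prev, 3, 2)).astype(np.uint8)
        Mp, Ip, Dp = Mi, Ii, Di

    final = np.maximum(M[m], I[m])  # a trailing deletion is never optimal
    j = int(np.argmax(final))
    score = int(final[j])
    if score_floor is not None and score < score_floor:
        return None

    # traceback
    state = 1 if M[m, j] >= I[m, j] else 2
    i = m
    rev_ops: list[tuple[int, str, str]] = []
    while i > 0:
        if state == 1:
            op = ("=", "") if t[j - 1] == r[i - 1] else ("X", read_bases[i - 1])
            rev_ops.append((1, *op))
            state = int(pM[i, j])
            i, j = i - 1, j - 1
        elif state == 2:
            rev_ops.append((1, "I", read_bases[i - 1]))
            state = int(pI[i, j])
            i -= 1
        elif state == 3:
            rev_ops.append((1, "D", ""))
            state = int(pD[i, j])
            j -= 1
        else:
            break
    # state 0 is only reachable at i == 0
    ops: list[tuple[int, str, str]] = []
    for nn, op, b in reversed(rev_ops):
        if ops and ops[-1][1] == op:
            pn, _, pb = ops[-1]
            ops[-1] = (pn + nn, op, pb + b)
        else:
            ops.append((nn, op, b))
    return Alignment(ref_start=j, ops=tuple(ops), score=score)


# ---------------------------------------------------------------------------
# SAM ingestion
# ---------------------------------------------------------------------------

def read_sam(path, region: ReferenceRegion) -> tuple[list[AlignedRead], int]:
    """Convert mapped SAM records overlapping the region into AlignedReads.

    CIGAR ``M`` runs are resolved to ``=``/``X`` against the region sequence;
    soft/hard clips are dropped; unmapped records are skipped and counted.
    Returns ``(aligned_reads, n_unmapped)``.
    """
    import pysam

    ref = region.sequence
    L = len(region)
    out: list[AlignedRead] = []
    n_unmapped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for lineno, rec in enumerate(sam.fetch(until_eof=True), start=1):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            if rec.reference_name != region.name:
                continue
            if rec.cigartuples is None or rec.query_sequence is None:
                raise ValueError(f"malformed SAM record at line {lineno}")
            p = rec.reference_start
            if p >= L or p < 0:
                continue
            q = 0
            seq = rec.query_sequence.upper()
            ops: list[tuple[int, str, str]] = []
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):  # M, =, X -> resolve against reference
                    for k in range(ln):
                        rb = ref[p + k] if p + k < L else "N"
                        qb = seq[q + k]
                        if qb == rb:
                            if ops and ops[-1][1] == "=":
                                ops[-1] = (ops[-1][0] + 1, "=", "")
                            else:
                                ops.append((1, "=", ""))
                        else:
                            if ops and ops[-1][1] == "X":
                                ops[-1] = (ops[-1][0] + 1, "X", ops[-1][2] + qb)
                            else:
                                ops.append((1, "X", qb))
                    p += ln
                    q += ln
                elif op == 1:  # I
                    ops.append((ln, "I", seq[q:q + ln]))
                    q += ln
                elif op in (2, 3):  # D, N
                    ops.append((ln, "D", ""))
                    p += ln
                elif op == 4:  # S
                    q += ln
                elif op == 5 or op == 6:  # H, P
                    pass
                else:
                    raise ValueError(
                        f"unsupported CIGAR op {op} at line {lineno}")
            strand = "-" if rec.is_reverse else "+"
            out.append(AlignedRead(read_id=rec.query_name,
                                   ref_start=rec.reference_start,
                                   ops=tuple(ops), strand=strand))
    return out, n_unmapped


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGTN"


@dataclass
class PileupColumn:
    """Per-position tally: base calls, deletion calls, anchored insertions."""

    ref_pos: int
    ref_base: str
    base_counts: dict[str, int]
    del_count: int
    ins_events: Counter = field(default_factory=Counter)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values()) + self.del_count


class Pileup:
    """Column tallies over a reference region, stored as dense arrays."""

    def __init__(self, region: ReferenceRegion,
                 counts: np.ndarray | None = None,
                 dels: np.ndarray | None = None,
                 ins: dict[int, Counter] | None = None,
                 n_reads: int = 0, n_skipped: int = 0,
                 n_ins_clipped: int = 0):
        L = len(region)
        self.region = region
        self.counts = counts if counts is not None else np.zeros(
            (5, L), dtype=np.int64)
        self.dels = dels if dels is not None else np.zeros(L, dtype=np.int64)
        self.ins: dict[int, Counter] = ins if ins is not None else {}
        self.n_reads = n_reads
        self.n_skipped = n_skipped
        self.n_ins_clipped = n_ins_clipped

    def __len__(self) -> int:
        return len(self.region)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0) + self.dels

    def column(self, pos: int) -> PileupColumn:
        return PileupColumn(
            ref_pos=pos, ref_base=self.region.sequence[pos],
            base_counts={b: int(self.counts[i, pos])
                         for i, b in enumerate(_BASE_ORDER)},
            del_count=int(self.dels[pos]),
            ins_events=Counter(self.ins.get(pos, {})))

    def columns(self) -> Iterable[PileupColumn]:
        for pos in range(len(self)):
            yield self.column(pos)

    def __add__(self, other: "Pileup") -> "Pileup":
        if other.region is not self.region and \
                other.region.sequence != self.region.sequence:
            raise ValueError("cannot pool pileups over different regions")
        ins: dict[int, Counter] = {p: Counter(c) for p, c in self.ins.items()}
        for p, c in other.ins.items():
            ins.setdefault(p, Counter()).update(c)
        return Pileup(self.region, self.counts + other.counts,
                      self.dels + other.dels, ins,
                      self.n_reads + other.n_reads,
                      self.n_skipped + other.n_skipped,
                      self.n_ins_clipped + other.n_ins_clipped)


def _run_starts(seq_idx: np.ndarray) -> np.ndarray:
    """For each position, the start of the maximal homopolymer run holding it."""
    L = len(seq_idx)
    bnd = np.flatnonzero(seq_idx[1:] != seq_idx[:-1]) + 1
    starts = np.concatenate(([0], bnd))
    run_id = np.zeros(L, dtype=np.int64)
    run_id[bnd] = 1
    run_id = np.cumsum(run_id)
    return starts[run_id]


def build_pileup(aligned_reads: Iterable[AlignedRead],
                 region: ReferenceRegion,
                 normalize_indels: bool = True) -> Pileup:
    """Accumulate aligned reads into per-position columns.

    Reads falling entirely outside the region are skipped and counted.
    Positions of each op outside [0, region length) are clipped away. With
    ``normalize_indels`` (default), indels whose bases form a single
    homopolymer are shifted to their leftmost equivalent placement.
    """
    L = len(region)
    seq_idx = region.seq_idx
    run_start = _run_starts(seq_idx) if normalize_indels else None

    match_diff = np.zeros(L + 1, dtype=np.int64)
    del_diff = np.zeros(L + 1, dtype=np.int64)
    x_pos: list[int] = []
    x_base: list[int] = []
    ins: dict[int, Counter] = {}
    n_reads = n_skipped = n_ins_clipped = 0

    enc = {b: i for i, b in enumerate(_BASE_ORDER)}
    for ar in aligned_reads:
        if ar.ref_end <= 0 or ar.ref_start >= L:
            n_skipped += 1
            continue
        n_reads += 1
        p = ar.ref_start
        for n, op, b in ar.ops:
            if op == "=":
                lo, hi = max(p, 0), min(p + n, L)
                if lo < hi:
                    match_diff[lo] += 1
                    match_diff[hi] -= 1
                p += n
            elif op == "X":
                for k in range(n):
                    pos = p + k
                    if 0 <= pos < L:
                        x_pos.append(pos)
                        x_base.append(enc.get(b[k], 4))
                p += n
            elif op == "D":
                lo, hi = max(p, 0), min(p + n, L)
                if lo < hi:
                    if normalize_indels and bool(
                            (seq_idx[lo:hi] == seq_idx[lo]).all()):
                        width = hi - lo
                        lo = int(run_start[lo])
                        hi = lo + width
                    del_diff[lo] += 1
                    del_diff[hi] -= 1
                p += n
            elif op == "I":
                anchor = p - 1
                if normalize_indels and len(set(b)) == 1 and anchor >= 0:
                    bi = enc.get(b[0], 4)
                    while anchor >= 0 and seq_idx[anchor] == bi:
                        anchor = int(run_start[anchor]) - 1
                if 0 <= anchor < L:
                    ins.setdefault(anchor, Counter())[b] += 1
                else:
                    n_ins_clipped += 1
            else:
                raise ValueError(f"unknown op {op!r} in read {ar.read_id}")

    pu = Pileup(region, n_reads=n_reads, n_skipped=n_skipped,
                n_ins_clipped=n_ins_clipped)
    match_cov = np.cumsum(match_diff[:-1])
    pu.counts[seq_idx, np.arange(L)] += match_cov
    if x_pos:
        np.add.at(pu.counts, (np.asarray(x_base), np.asarray(x_pos)), 1)
    pu.dels[:] = np.cumsum(del_diff[:-1])
    pu.ins = ins
    return pu


def pileup_from_simulated(reads: Iterable[SimulatedRead],
                          region: ReferenceRegion,
                          normalize_indels: bool = True) -> Pileup:
    return build_pileup((from_simulated(r) for r in reads), region,
                        normalize_indels=normalize_indels)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def write_pileup_tsv(pileup: Pileup, path) -> None:
    """Columns as TSV with 1-based chromosome positions."""
    region = pileup.region
    depth = pileup.depth
    with open(path, "w") as fh:
        fh.write("pos\tref\tA\tC\tG\tT\tN\tdel\tdepth\tins\n")
        for pos in range(len(pileup)):
            cnt = pileup.counts[:, pos]
            insf = ";".join(f"{s}:{c}" for s, c in
                            sorted(pileup.ins.get(pos, {}).items())) or "."
            fh.write(f"{region.abs_pos_1based(pos)}\t{region.sequence[pos]}\t"
                     f"{cnt[0]}\t{cnt[1]}\t{cnt[2]}\t{cnt[3]}\t{cnt[4]}\t"
                     f"{pileup.dels[pos]}\t{depth[pos]}\t{insf}\n")


def read_pileup_tsv(path, region: ReferenceRegion) -> Pileup:
    pu = Pileup(region)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("pos\t"):
            raise ValueError(f"not a pileup TSV: {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            pos = region.offset_of(int(f[0]))
            pu.counts[:, pos] = [int(x) for x in f[2:7]]
            pu.dels[pos] = int(f[7])
            if f[9] != ".":
                c = Counter()
                for item in f[9].split(";"):
                    s, n = item.rsplit(":", 1)
                    c[s] = int(n)
                pu.ins[pos] = c
    return pu
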