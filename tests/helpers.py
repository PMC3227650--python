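"""Shared independent oracles and builders for the test suite.

The oracles here deliberately re-derive results with the plainest possible
code (per-column recounts, full dynamic programming without vectorization)
so they stay independent of the library implementations they check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from pyrofrag.errorstats import AnalysisParams, ErrorStats
from pyrofrag.pileup import PileupColumn, Scoring

NEG = -(10 ** 9)


# ---------------------------------------------------------------------------
# Brute-force per-column recount of the raw error statistic
# ---------------------------------------------------------------------------

def brute_method1(columns, params: AnalysisParams = AnalysisParams()
                  ) -> ErrorStats:
    """Plain re-statement of the raw error-count rules, column by column."""
    st = ErrorStats()
    for col in columns:
        base = {b: col.base_counts.get(b, 0) for b in "ACGT"}
        n_calls = col.base_counts.get("N", 0)
        depth = sum(base.values()) + n_calls + col.del_count
        if depth < params.min_depth:
            continue
        major_cnt = max(max(base.values()), col.del_count)
        if (depth - major_cnt) / depth >= params.max_alt_freq:
            continue
        if col.ins_events and max(col.ins_events.values()) > 0.5 * depth:
            continue
        st.eligible_positions += 1
        st.false_ins_calls += sum(col.ins_events.values())
        ref = col.ref_base
        if col.del_count > max(base.values()):
            st.correct_calls += col.del_count + base.get(ref, 0)
            st.false_sub_calls += sum(base.values()) + n_calls - base.get(ref, 0)
        else:
            best = max(base.values())
            if base.get(ref, 0) == best:
                major = ref
            else:
                major = [b for b in "ACGT" if base[b] == best][0]
            correct = base[major] + (base[ref] if major != ref else 0)
            st.correct_calls += correct
            st.false_sub_calls += sum(base.values()) + n_calls - correct
            st.false_del_calls += col.del_count
    return st


def random_columns(rng: np.random.Generator, n: int) -> list[PileupColumn]:
    """Random pileup columns covering all rule branches (deletions as major,
    insertion pluralities, N calls, low depth)."""
    cols = []
    for pos in range(n):
        ref = "ACGT"[rng.integers(0, 4)]
        counts = {b: int(rng.integers(0, 40)) for b in "ACGT"}
        counts["N"] = int(rng.integers(0, 3)) if rng.random() < 0.2 else 0
        dels = int(rng.integers(0, 60)) if rng.random() < 0.4 else 0
        ins = Counter()
        if rng.random() < 0.4:
            for _ in range(int(rng.integers(1, 3))):
                s = "".join("ACGT"[i] for i in rng.integers(0, 4,
                                                            rng.integers(1, 3)))
                ins[s] += int(rng.integers(1, 50))
        cols.append(PileupColumn(ref_pos=pos, ref_base=ref,
                                 base_counts=counts, del_count=dels,
                                 ins_events=ins))
    return cols


# ---------------------------------------------------------------------------
# Brute-force semi-global affine alignment score
# ---------------------------------------------------------------------------

def brute_align_score(read: str, ref: str, sc: Scoring = Scoring()) -> int:
    """Exhaustive DP over the three affine states; score only."""
    m, n = len(read), len(ref)
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(0, n + 1):
            if j >= 1:
                prev = 0 if i == 1 else max(M[i - 1][j - 1], I[i - 1][j - 1],
                                            D[i - 1][j - 1])
                s = sc.match if read[i - 1] == ref[j - 1] else sc.mismatch
                M[i][j] = prev + s
            I[i][j] = max(I[i - 1][j] + sc.gap_extend,
                          M[i - 1][j] + sc.gap_open + sc.gap_extend,
                          D[i - 1][j] + sc.gap_open + sc.gap_extend)
            if j >= 1:
                D[i][j] = max(D[i][j - 1] + sc.gap_extend,
                              M[i][j - 1] + sc.gap_open + sc.gap_extend,
                              I[i][j - 1] + sc.gap_open + sc.gap_extend)
    return max(max(M[m]), max(I[m]))


# ---------------------------------------------------------------------------
# SAM text from truth alignments (for the external-input pipeline route)
# ---------------------------------------------------------------------------

def sam_from_truth(reads, region) -> str:
    """Render simulated reads' truth alignments as SAM records."""
    from pyrofrag.pileup import from_simulated
    from pyrofrag.simdata import revcomp

    lines = [f"@HD\tVN:1.6\tSO:unknown",
             f"@SQ\tSN:{region.name}\tLN:{len(region)}"]
    for r in reads:
        ar = from_simulated(r)
        cig = []
        for n, op, _ in ar.ops:
            c = {"=": "M", "X": "M", "I": "I", "D": "D"}[op]
            if cig and cig[-1][1] == c:
                cig[-1][0] += n
            else:
                cig.append([n, c])
        cigar = "".join(f"{n}{c}" for n, c in cig)
        seq = r.insert_bases if r.strand == "+" else revcomp(r.insert_bases)
        flag = 0 if r.strand == "+" else 16
        lines.append("\t".join((
            r.read_id, str(flag), region.name, str(ar.ref_start + 1), "60",
            cigar, "*", "0", "0", seq, "*")))
    return "\n".join(lines) + "\n"
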