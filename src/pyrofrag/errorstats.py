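"""Raw per-position error statistics and the between-method comparison.

The raw error statistic is computed on unfiltered pileups. Only positions
with sufficient coverage (depth >= ``min_depth``, default 20) and an
unambiguous genotype (alternative-allele frequency below ``max_alt_freq``,
default 20%) are eligible. At eligible positions, base calls equal to the
reference base or the major allele are "correct"; all other base calls are
missense errors; deletion calls are deletion errors (unless the deletion
itself is the major allele, in which case deletions are correct and base
calls that match neither reference nor major are missense); each anchored
insertion event is an insertion error, unless one identical insertion is
carried by the majority of covering reads, in which case the position is
ambiguous and ineligible. Counts accumulate over the region and each error
class is reported as a percentage of the total calls.

Method comparison: per error class, replicate percentages of two methods are
compared with a two-sample t-test (group means and the statistic reported;
degenerate zero-variance groups are flagged rather than tested).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .pileup import Pileup, PileupColumn

ERROR_CLASSES = ("missense", "insertion", "deletion")


@dataclass(frozen=True)
class AnalysisParams:
    """Eligibility thresholds for the raw error statistic."""

    min_depth: int = 20
    max_alt_freq: float = 0.20
    region_start: int | None = None  # region-relative, half-open
    region_end: int | None = None

    def __post_init__(self):
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not (0.0 < self.max_alt_freq < 1.0):
            raise ValueError("max_alt_freq must lie in (0, 1)")


@dataclass
class ErrorStats:
    """Accumulated correct/false call counts with per-class percentages."""

    eligible_positions: int = 0
    correct_calls: int = 0
    false_sub_calls: int = 0
    false_ins_calls: int = 0
    false_del_calls: int = 0

    @property
    def total_calls(self) -> int:
        return (self.correct_calls + self.false_sub_calls
                + self.false_ins_calls + self.false_del_calls)

    def _pct(self, x: int) -> float:
        t = self.total_calls
        return 100.0 * x / t if t else 0.0

    @property
    def pct_missense(self) -> float:
        return self._pct(self.false_sub_calls)

    @property
    def pct_insertion(self) -> float:
        return self._pct(self.false_ins_calls)

    @property
    def pct_deletion(self) -> float:
        return self._pct(self.false_del_calls)

    def pct(self, cls: str) -> float:
        return {"missense": self.pct_missense,
                "insertion": self.pct_insertion,
                "deletion": self.pct_deletion}[cls]


def _column_tallies(column: PileupColumn):
    counts = [column.base_counts.get(b, 0) for b in "ACGT"]
    n_count = column.base_counts.get("N", 0)
    return counts, n_count, column.del_count


def eligible(column: PileupColumn, params: AnalysisParams = AnalysisParams()
             ) -> bool:
    """Depth and unambiguous-genotype gate for one column."""
    counts, n_count, dels = _column_tallies(column)
    depth = sum(counts) + n_count + dels
    if depth < params.min_depth:
        return False
    major = max(max(counts), dels)
    return (depth - major) / depth < params.max_alt_freq


def _ins_ambiguous(column: PileupColumn) -> bool:
    if not column.ins_events:
        return False
    depth = column.depth
    return depth > 0 and max(column.ins_events.values()) > 0.5 * depth


def method1_stats(columns, params: AnalysisParams = AnalysisParams(),
                  ) -> ErrorStats:
    """Accumulate the raw error statistic over a sample's pileup.

    ``columns`` is a Pileup (fast vectorized path) or an iterable of
    PileupColumn. The pileup must be unfiltered.
    """
    if isinstance(columns, Pileup):
        return _method1_stats_pileup(columns, params)
    stats = ErrorStats()
    for col in columns:
        _accumulate_column(col, params, stats)
    return stats


def _accumulate_column(col: PileupColumn, params: AnalysisParams,
                       stats: ErrorStats) -> None:
    if not eligible(col, params) or _ins_ambiguous(col):
        return
    counts, n_count, dels = _column_tallies(col)
    ref_i = "ACGT".index(col.ref_base) if col.ref_base in "ACGT" else None
    base_max = max(counts)
    n_ins = sum(col.ins_events.values())
    stats.eligible_positions += 1
    if dels > base_max:
        # deletion is the major allele: deletions correct, only reference
        # base calls correct among bases
        ref_cnt = counts[ref_i] if ref_i is not None else 0
        stats.correct_calls += dels + ref_cnt
        stats.false_sub_calls += sum(counts) + n_count - ref_cnt
    else:
        # major-allele ties break toward the reference base
        if ref_i is not None and counts[ref_i] == base_max:
            major_i = ref_i
        else:
            major_i = counts.index(base_max)
        correct = counts[major_i]
        if ref_i is not None and major_i != ref_i:
            correct += counts[ref_i]
        stats.correct_calls += correct
        stats.false_sub_calls += sum(counts) + n_count - correct
        stats.false_del_calls += dels
    stats.false_ins_calls += n_ins


def _method1_stats_pileup(pu: Pileup, params: AnalysisParams) -> ErrorStats:
    L = len(pu)
    lo = params.region_start or 0
    hi = params.region_end if params.region_end is not None else L
    counts = pu.counts[:4, lo:hi]
    n_counts = pu.counts[4, lo:hi]
    dels = pu.dels[lo:hi]
    ref_idx = pu.region.seq_idx[lo:hi].astype(np.int64)
    cols = np.arange(hi - lo)

    depth = counts.sum(axis=0) + n_counts + dels
    base_max = counts.max(axis=0)
    major = np.maximum(base_max, dels)
    with np.errstate(divide="ignore", invalid="ignore"):
        alt_frac = np.where(depth > 0, (depth - major) / np.maximum(depth, 1), 1.0)
    elig = (depth >= params.min_depth) & (alt_frac < params.max_alt_freq)

    ins_total = np.zeros(hi - lo, dtype=np.int64)
    ins_max = np.zeros(hi - lo, dtype=np.int64)
    for pos, c in pu.ins.items():
        if lo <= pos < hi:
            ins_total[pos - lo] = sum(c.values())
            ins_max[pos - lo] = max(c.values())
    elig &= ~((ins_max > 0) & (ins_max > 0.5 * depth))

    ref_cnt = counts[ref_idx, cols]
    del_major = dels > base_max
    # base-major branch (ties toward reference)
    major_is_ref = ref_cnt == base_max
    correct_base = np.where(major_is_ref, ref_cnt, base_max + ref_cnt)
    correct = np.where(del_major, dels + ref_cnt, correct_base)
    false_sub = counts.sum(axis=0) + n_counts - np.where(
        del_major, ref_cnt, correct_base)
    false_del = np.where(del_major, 0, dels)

    stats = ErrorStats(
        eligible_positions=int(elig.sum()),
        correct_calls=int(correct[elig].sum()),
        false_sub_calls=int(false_sub[elig].sum()),
        false_ins_calls=int(ins_total[elig].sum()),
        false_del_calls=int(false_del[elig].sum()),
    )
    return stats


# ---------------------------------------------------------------------------
# Between-method comparison
# ---------------------------------------------------------------------------

def compare_methods(stats_by_method: Mapping[str, Sequence[ErrorStats]]):
    """Pairwise two-sample t-tests on replicate error percentages.

    Returns a DataFrame with one row per (method pair, error class):
    group means, t statistic and p-value. Pairs with fewer than two
    replicates on either side are marked not-testable; zero-variance
    inputs are reported as degenerate.
    """
    import pandas as pd
    from scipy import stats as sps

    rows = []
    for (ma, sa), (mb, sb) in itertools.combinations(
            stats_by_method.items(), 2):
        for cls in ERROR_CLASSES:
            va = np.array([s.pct(cls) for s in sa], dtype=float)
            vb = np.array([s.pct(cls) for s in sb], dtype=float)
            mean_a, mean_b = (va.mean() if len(va) else np.nan,
                              vb.mean() if len(vb) else np.nan)
            if len(va) < 2 or len(vb) < 2:
                rows.append((ma, mb, cls, mean_a, mean_b, np.nan, np.nan,
                             "not-testable"))
                continue
            if va.std() == 0.0 and vb.std() == 0.0:
                if mean_a == mean_b:
                    rows.append((ma, mb, cls, mean_a, mean_b, 0.0, 1.0,
                                 "degenerate"))
                else:
                    rows.append((ma, mb, cls, mean_a, mean_b,
                                 np.inf if mean_a > mean_b else -np.inf,
                                 0.0, "degenerate"))
                continue
            t, p = sps.ttest_ind(va, vb, equal_var=True)
            rows.append((ma, mb, cls, mean_a, mean_b, float(t), float(p), ""))
    return pd.DataFrame(rows, columns=[
        "method_a", "method_b", "class", "mean_a", "mean_b",
        "statistic", "p", "note"])


def stats_table(stats_by_sample: Mapping[str, ErrorStats]):
    import pandas as pd
    rows = [(s, st.eligible_positions, st.correct_calls, st.false_sub_calls,
             st.false_ins_calls, st.false_del_calls, st.pct_missense,
             st.pct_insertion, st.pct_deletion)
            for s, st in stats_by_sample.items()]
    return pd.DataFrame(rows, columns=[
        "sample", "eligible_positions", "correct", "false_sub", "false_ins",
        "false_del", "pct_missense", "pct_insertion", "pct_deletion"])
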