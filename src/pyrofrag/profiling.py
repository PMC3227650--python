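"""Coverage, 3'-quality and read-length profiles of a sequencing run.

These profiles expose the run-level signatures of the experimental design:
per-amplicon coverage (equimolar pooling plus size selection depletes short
amplicons), PHRED quality decay toward the 3' read end (averaged in 5-base
windows across reads and replicates), and the read-length distribution in
50-bp bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pileup import Pileup
from .simdata import AmpliconPanel


# ---------------------------------------------------------------------------
# Coverage by amplicon
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Per-position depth plus per-amplicon summaries.

    Positions inside amplicon overlaps contribute to every covering
    amplicon.
    """

    depth: np.ndarray
    amplicon_ids: list[str]
    amplicon_lengths: list[int]
    mean_depth: list[float]
    median_depth: list[float]

    def as_table(self):
        import pandas as pd
        return pd.DataFrame({
            "amplicon": self.amplicon_ids,
            "length": self.amplicon_lengths,
            "mean_depth": self.mean_depth,
            "median_depth": self.median_depth,
        })


def coverage_by_amplicon(pileup: Pileup, panel: AmpliconPanel
                         ) -> CoverageProfile:
    if not panel.amplicons:
        raise ValueError("empty amplicon panel")
    depth = pileup.depth
    ids, lengths, means, medians = [], [], [], []
    for a in panel.amplicons:
        d = depth[a.start:a.end]
        ids.append(a.id)
        lengths.append(a.length)
        means.append(float(d.mean()))
        medians.append(float(np.median(d)))
    return CoverageProfile(depth, ids, lengths, means, medians)


# ---------------------------------------------------------------------------
# 3'-anchored quality decay
# ---------------------------------------------------------------------------

@dataclass
class QualityProfile:
    """Mean quality per 5-base window indexed from the 3' end.

    ``mean`` and ``sd`` are across replicate groups (sd is zero when a
    single group is supplied); window 0 is the 3'-terminal window.
    """

    window: int
    mean: np.ndarray
    sd: np.ndarray
    per_group: dict[str, np.ndarray]


def _group_window_means(reads: Sequence, window: int,
                        anchor3: bool = True) -> np.ndarray:
    """Per-position mean quality (anchored at the 3' end), then averaged in
    windows of ``window`` bases."""
    max_len = max((len(r.qualities) for r in reads), default=0)
    if max_len == 0:
        return np.empty(0)
    sums = np.zeros(max_len)
    cnts = np.zeros(max_len)
    for r in reads:
        q = np.asarray(r.qualities, dtype=float)
        if anchor3:
            q = q[::-1]
        sums[:len(q)] += q
        cnts[:len(q)] += 1
    pos_mean = sums / np.maximum(cnts, 1)
    pos_mean[cnts == 0] = np.nan
    n_win = max_len // window
    if n_win == 0:
        return np.empty(0)
    return pos_mean[:n_win * window].reshape(n_win, window).mean(axis=1)


def quality_decay(reads_by_group: Mapping[str, Sequence] | Sequence,
                  window: int = 5, anchor3: bool = True) -> QualityProfile:
    """3'-anchored windowed quality profile, averaged across replicates.

    ``reads_by_group`` maps a replicate label to its reads (anything with a
    ``qualities`` attribute); a bare sequence of reads is treated as one
    group.
    """
    if not isinstance(reads_by_group, Mapping):
        reads_by_group = {"all": reads_by_group}
    per_group = {g: _group_window_means(rs, window, anchor3)
                 for g, rs in reads_by_group.items()}
    n = min((len(v) for v in per_group.values()), default=0)
    stack = np.stack([v[:n] for v in per_group.values()]) if n else \
        np.empty((0, 0))
    mean = stack.mean(axis=0) if n else np.empty(0)
    sd = stack.std(axis=0, ddof=0) if n else np.empty(0)
    return QualityProfile(window, mean, sd, per_group)


# ---------------------------------------------------------------------------
# Read-length histogram
# ---------------------------------------------------------------------------

@dataclass
class ReadLengthHistogram:
    """Counts per fixed-width length bin plus summary statistics.

    The mode is computed on raw integer lengths, not on bins.
    """

    bin_width: int
    bin_edges: np.ndarray
    counts: np.ndarray
    n: int
    median: float
    mean: float
    sd: float
    mode: int


def readlength_hist(reads: Iterable, bin_width: int = 50
                    ) -> ReadLengthHistogram:
    lengths = np.array([len(r.bases) if hasattr(r, "bases") else int(r)
                        for r in reads], dtype=np.int64)
    if len(lengths) == 0:
        return ReadLengthHistogram(bin_width, np.array([0]), np.array([]),
                                   0, 0.0, 0.0, 0.0, 0)
    top = (int(lengths.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(lengths, bins=edges)
    vals, freq = np.unique(lengths, return_counts=True)
    mode = int(vals[np.argmax(freq)])  # ties resolve to the smallest length
    return ReadLengthHistogram(
        bin_width, edges, counts, int(len(lengths)),
        float(np.median(lengths)), float(lengths.mean()),
        float(lengths.std(ddof=0)), mode)


# ---------------------------------------------------------------------------
# TSV / plot output
# ---------------------------------------------------------------------------

def write_coverage_tsv(profile: CoverageProfile, pileup: Pileup, path) -> None:
    region = pileup.region
    with open(path, "w") as fh:
        fh.write("pos\tdepth\n")
        for i, d in enumerate(profile.depth):
            fh.write(f"{region.abs_pos_1based(i)}\t{int(d)}\n")


def write_quality_profile_tsv(profile: QualityProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("window_from_3prime\tmean_quality\tsd\n")
        for i, (m, s) in enumerate(zip(profile.mean, profile.sd)):
            fh.write(f"{i}\t{m:.3f}\t{s:.3f}\n")


def write_readlength_tsv(hist: ReadLengthHistogram, path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\tcount\n")
        for lo, hi, c in zip(hist.bin_edges[:-1], hist.bin_edges[1:],
                             hist.counts):
            fh.write(f"{lo}\t{hi}\t{c}\n")


def plot_profiles(coverage: CoverageProfile | None,
                  quality: QualityProfile | None,
                  lengths: ReadLengthHistogram | None, path) -> None:
    """Optional three-panel figure (coverage, quality decay, read lengths)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(14, 4))
    if coverage is not None:
        axes[0].plot(coverage.depth, lw=0.5)
        axes[0].set_xlabel("region position")
        axes[0].set_ylabel("depth")
    if quality is not None:
        x = np.arange(len(quality.mean))
        axes[1].errorbar(x, quality.mean, yerr=quality.sd, fmt="-")
        axes[1].set_xlabel(f"{quality.window}-bp window from 3' end")
        axes[1].set_ylabel("mean PHRED quality")
        axes[1].invert_xaxis()
    if lengths is not None and lengths.n:
        axes[2].bar(lengths.bin_edges[:-1], lengths.counts,
                    width=lengths.bin_width, align="edge")
        axes[2].set_xlabel("read length (bp)")
        axes[2].set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
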