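"""MID barcode demultiplexing.

Reads from a pooled run are assigned to their sample by comparing the first
``k`` bases against every barcode by Hamming distance. A read is assigned to
the unique sample within ``max_mismatch``; if no barcode is close enough, or
two barcodes tie at the minimum distance, the read is UNASSIGNED. Assigned
reads have the barcode stripped (qualities trimmed in lockstep).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .simdata import MIDTag, encode

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class FastqRead:
    """A plain read as parsed from FASTQ."""

    read_id: str
    bases: str
    qualities: np.ndarray


@dataclass
class DemuxResult:
    """Per-sample read lists (barcode-stripped) plus the unassigned pool."""

    assigned: dict[str, list]
    unassigned: list
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.counts:
            self.counts = {s: len(v) for s, v in self.assigned.items()}
            self.counts[UNASSIGNED] = len(self.unassigned)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    @property
    def unassigned_fraction(self) -> float:
        return self.counts[UNASSIGNED] / self.n_total if self.n_total else 0.0

    def summary_table(self):
        import pandas as pd
        n = self.n_total
        rows = [(s, c, c / n if n else 0.0) for s, c in self.counts.items()]
        return pd.DataFrame(rows, columns=["sample", "n_reads", "fraction"])


def _check_mids(mids: Sequence[MIDTag]) -> int:
    lens = {len(m.barcode) for m in mids}
    if len(lens) != 1:
        raise ValueError("heterogeneous barcode lengths")
    return lens.pop()


def assign_mid(read_bases: str, mids: Sequence[MIDTag],
               max_mismatch: int = 1) -> str:
    """Assign a single read prefix; returns a sample id or UNASSIGNED."""
    k = _check_mids(mids)
    if len(read_bases) < k:
        return UNASSIGNED
    prefix = read_bases[:k]
    dists = [sum(a != b for a, b in zip(prefix, m.barcode)) for m in mids]
    best = min(dists)
    if best > max_mismatch or dists.count(best) > 1:
        return UNASSIGNED
    return mids[dists.index(best)].sample_id


def demultiplex(reads: Sequence, mids: Sequence[MIDTag],
                max_mismatch: int = 1) -> DemuxResult:
    """Assign every read and strip the barcode from assigned reads.

    ``reads`` may be SimulatedReads or FastqReads (anything with read_id,
    bases and qualities). Read count is conserved across the output bins.
    """
    k = _check_mids(mids)
    barcode_arr = np.stack([encode(m.barcode) for m in mids])  # (S, k)
    sample_ids = [m.sample_id for m in mids]

    usable = [r for r in reads if len(r.bases) >= k]
    short = [r for r in reads if len(r.bases) < k]
    assigned: dict[str, list] = {s: [] for s in sample_ids}
    unassigned: list = list(short)

    if usable:
        prefixes = np.stack([encode(r.bases[:k]) for r in usable])  # (N, k)
        dists = (prefixes[:, None, :] != barcode_arr[None, :, :]).sum(axis=2)
        best = dists.min(axis=1)
        n_best = (dists == best[:, None]).sum(axis=1)
        which = dists.argmin(axis=1)
        ok = (best <= max_mismatch) & (n_best == 1)
        for r, is_ok, s_idx in zip(usable, ok, which):
            if is_ok:
                assigned[sample_ids[s_idx]].append(FastqRead(
                    read_id=r.read_id, bases=r.bases[k:],
                    qualities=np.asarray(r.qualities)[k:]))
            else:
                unassigned.append(r)
    return DemuxResult(assigned=assigned, unassigned=unassigned)
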