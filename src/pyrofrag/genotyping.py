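"""Homopolymer-aware genotype calling and concordance against Sanger truth.

Pyrosequencing miscalls homopolymer lengths, producing spurious indel
alleles inside long runs. Before genotype calling, indel observations at
positions inside (or with an insertion anchor abutting) a homopolymer run of
length >= ``hp_min_run`` (default 5) are removed from the calling view; base
counts are untouched and the unfiltered counts are retained for reporting
(the reported allele percentage comes from the pre-filter counts while the
genotype is called after filtering).

Genotypes are called from the filtered allele frequencies with a single
threshold: major-allele frequency f >= 0.8 is homozygous, otherwise
heterozygous major|second. A deletion may itself be an allele (rendered
``[]``). Replicates are pooled by summing depths and coverage-weighting the
per-replicate major-allele percentages. Concordance compares called allele
sets against Sanger-determined genotypes; dinucleotide loci are compared as
two adjacent positions jointly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pileup import Pileup, PileupColumn
from .simdata import ReferenceRegion

DELETION_ALLELE = "-"
_ALLELE_ORDER = {b: i for i, b in enumerate("ACGTN-")}


# ---------------------------------------------------------------------------
# Sanger truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SangerTruthEntry:
    """One Sanger-validated locus (single position or adjacent position pair).

    ``positions`` are 1-based chromosome coordinates; ``alleles`` holds one
    allele for homozygous loci and two distinct alleles for heterozygous
    ones (per-position strings; ``-`` marks a deleted base).
    """

    chrom: str
    positions: tuple[int, ...]
    ref: str
    zygosity: str
    alleles: tuple[str, ...]

    def __post_init__(self):
        if self.zygosity not in ("hom", "het"):
            raise ValueError("zygosity must be 'hom' or 'het'")
        if self.zygosity == "het" and (len(self.alleles) != 2
                                       or self.alleles[0] == self.alleles[1]):
            raise ValueError("het entries carry two distinct alleles")
        if len(self.positions) not in (1, 2):
            raise ValueError("only single or dinucleotide loci supported")

    @property
    def allele_set(self) -> frozenset:
        return frozenset(self.alleles)


def write_truth_genotypes_tsv(entries: Iterable[SangerTruthEntry], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos_start\tpos_end\tref\tzygosity\talleles\n")
        for e in entries:
            fh.write(f"{e.chrom}\t{e.positions[0]}\t{e.positions[-1]}\t"
                     f"{e.ref}\t{e.zygosity}\t{'/'.join(e.alleles)}\n")


def read_truth_genotypes_tsv(path) -> list[SangerTruthEntry]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError(f"not a truth genotype TSV: {path}")
        for line in fh:
            chrom, p0, p1, ref, zyg, alleles = line.rstrip("\n").split("\t")
            positions = (int(p0),) if p0 == p1 else (int(p0), int(p1))
            out.append(SangerTruthEntry(chrom, positions, ref, zyg,
                                        tuple(alleles.split("/"))))
    return out


# ---------------------------------------------------------------------------
# Homopolymer runs and indel filtering
# ---------------------------------------------------------------------------

def homopolymer_runs(reference_seq: str, min_len: int = 5
                     ) -> list[tuple[int, int, str]]:
    """Maximal runs of identical bases with length >= ``min_len``, sorted."""
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    runs = []
    i, L = 0, len(reference_seq)
    while i < L:
        j = i + 1
        while j < L and reference_seq[j] == reference_seq[i]:
            j += 1
        if j - i >= min_len:
            runs.append((i, j - i, reference_seq[i]))
        i = j
    return runs


def _run_mask(runs: Sequence[tuple[int, int, str]], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for start, n, _ in runs:
        mask[start:start + n] = True
    return mask


def filter_indels(columns, runs: Sequence[tuple[int, int, str]]):
    """Remove indel observations inside homopolymer runs from the calling view.

    Accepts a Pileup (returns a filtered copy) or a single PileupColumn.
    Deletion calls at in-run positions and insertions anchored inside or
    immediately left of a run are dropped; base counts are untouched.
    """
    if isinstance(columns, PileupColumn):
        col = columns
        in_run = any(s <= col.ref_pos < s + n for s, n, _ in runs)
        abuts = any(s <= col.ref_pos + 1 < s + n or s <= col.ref_pos < s + n
                    for s, n, _ in runs)
        from collections import Counter
        return PileupColumn(
            ref_pos=col.ref_pos, ref_base=col.ref_base,
            base_counts=dict(col.base_counts),
            del_count=0 if in_run else col.del_count,
            ins_events=Counter() if abuts else Counter(col.ins_events))
    pu: Pileup = columns
    L = len(pu)
    mask = _run_mask(runs, L)
    dels = pu.dels.copy()
    dels[mask] = 0
    ins = {}
    for pos, c in pu.ins.items():
        if not (mask[pos] or (pos + 1 < L and mask[pos + 1])):
            ins[pos] = c.copy()
    return Pileup(pu.region, pu.counts.copy(), dels, ins,
                  pu.n_reads, pu.n_skipped, pu.n_ins_clipped)


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """A called genotype at one position.

    ``alleles`` is the ordered pair (major first, lexicographic tie-break),
    or None for a no-call. Pre-filter depth and major-allele percentage are
    attached (allele counts are reported before the homopolymer filter while
    the genotype is called after it).
    """

    position: int  # region-relative offset
    alleles: tuple[str, str] | None
    depth_prefilter: int
    major_allele_prefilter: str | None
    major_pct_prefilter: float
    depth_view: int
    filtered_indel: bool = False

    @property
    def allele_set(self) -> frozenset | None:
        return None if self.alleles is None else frozenset(self.alleles)

    def render(self) -> str:
        if self.alleles is None:
            return "no-call"
        return "|".join(a.replace(DELETION_ALLELE, "[]") for a in self.alleles)


def _allele_counts(col: PileupColumn) -> list[tuple[str, int]]:
    pairs = [(b, col.base_counts.get(b, 0)) for b in "ACGT"]
    pairs.append((DELETION_ALLELE, col.del_count))
    return [(a, c) for a, c in pairs if c > 0]


def _major(pairs: Sequence[tuple[str, int]]) -> tuple[str, int]:
    return max(pairs, key=lambda ac: (ac[1], -_ALLELE_ORDER[ac[0]]))


def call_genotype(filtered: PileupColumn,
                  prefilter: PileupColumn | None = None,
                  het_thresh: float = 0.2) -> GenotypeCall:
    """Call hom/het from the filtered allele frequencies.

    Major-allele frequency f >= 1 - het_thresh calls homozygous major|major;
    otherwise heterozygous major|second (second most frequent allele,
    lexicographic tie-break). Depth 0 yields a no-call.
    """
    pre = prefilter if prefilter is not None else filtered
    pre_pairs = _allele_counts(pre)
    pre_depth = sum(c for _, c in pre_pairs)
    if pre_pairs:
        pre_major, pre_cnt = _major(pre_pairs)
        pre_pct = 100.0 * pre_cnt / pre_depth
    else:
        pre_major, pre_pct = None, 0.0
    filtered_flag = (pre.del_count != filtered.del_count
                     or sum(pre.ins_events.values())
                     != sum(filtered.ins_events.values()))

    pairs = _allele_counts(filtered)
    depth = sum(c for _, c in pairs)
    if depth == 0:
        return GenotypeCall(filtered.ref_pos, None, pre_depth, pre_major,
                            pre_pct, 0, filtered_flag)
    major, cnt = _major(pairs)
    f = cnt / depth
    if f >= 1.0 - het_thresh:
        alleles = (major, major)
    else:
        rest = [(a, c) for a, c in pairs if a != major]
        second, _ = _major(rest)
        alleles = (major, second)
    return GenotypeCall(filtered.ref_pos, alleles, pre_depth, pre_major,
                        pre_pct, depth, filtered_flag)


def round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pool_replicates(entries: Sequence[tuple[int, float]]
                    ) -> tuple[int, int]:
    """Pool per-replicate (depth, major-allele %) pairs at one position.

    Pooled depth is the sum of depths; the pooled percentage is the
    coverage-weighted mean of the per-replicate percentages (equivalently
    the pooled count ratio when counts are available), rounded to the
    nearest integer percent (half away from zero).
    """
    if not entries:
        raise ValueError("at least one replicate required")
    depths = np.array([d for d, _ in entries], dtype=float)
    pcts = np.array([p for _, p in entries], dtype=float)
    total = depths.sum()
    if total == 0:
        return 0, 0
    return int(total), round_half_away(float((depths * pcts).sum() / total))


# ---------------------------------------------------------------------------
# Locus-level calls and concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusCall:
    """A genotype call over one locus (1 or 2 adjacent positions)."""

    positions: tuple[int, ...]
    alleles: tuple[str, str] | None
    depth: int            # mean depth over the locus positions (pre-filter)
    major_pct: float      # pre-filter major/ref-allele percentage
    rendered: str = ""

    @property
    def allele_set(self) -> frozenset | None:
        return None if self.alleles is None else frozenset(self.alleles)


def call_locus(offsets: tuple[int, ...], filtered: Pileup, prefilter: Pileup,
               het_thresh: float = 0.2) -> LocusCall:
    """Call a single- or dinucleotide locus from filtered/pre-filter pileups.

    For dinucleotide loci each position is called separately and the locus
    alleles are the per-position alleles concatenated (major with major,
    second with second); the reported percentage uses all counts for both
    positions and the reported depth is the mean coverage over both.
    """
    calls = []
    for off in offsets:
        calls.append(call_genotype(filtered.column(off),
                                   prefilter.column(off), het_thresh))
    if any(c.alleles is None for c in calls):
        depth = round_half_away(float(np.mean([c.depth_prefilter
                                               for c in calls])))
        return LocusCall(offsets, None, depth, 0.0, "no-call")
    if len(calls) == 1:
        c = calls[0]
        return LocusCall(offsets, c.alleles, c.depth_prefilter,
                         c.major_pct_prefilter, c.render())
    a1 = "".join(c.alleles[0] for c in calls)
    a2 = "".join(c.alleles[1] for c in calls)
    depth = round_half_away(float(np.mean([c.depth_prefilter for c in calls])))
    pooled = pool_replicates([(c.depth_prefilter, c.major_pct_prefilter)
                              for c in calls])
    rendered = "|".join(a.replace(DELETION_ALLELE, "[]") for a in (a1, a2))
    return LocusCall(offsets, (a1, a2), depth, float(pooled[1]), rendered)


@dataclass
class ConcordanceRecord:
    """Per-locus comparison of NGS calls against the Sanger genotype."""

    truth: SangerTruthEntry
    per_sample: dict[str, LocusCall]
    agreement: dict[str, bool | None]  # None = no-call (not discordant)
    pooled: LocusCall
    pooled_agrees: bool | None

    @property
    def n_discordant(self) -> int:
        return sum(1 for v in self.agreement.values() if v is False)


@dataclass
class ConcordanceSummary:
    discordant_pairs_by_method: dict[str, int]
    n_loci_any_discordant: int
    n_loci: int


def _truth_allele_set(entry: SangerTruthEntry) -> frozenset:
    return entry.allele_set


def concordance(truth: Sequence[SangerTruthEntry],
                pileups_by_sample: Mapping[str, Pileup],
                region: ReferenceRegion,
                hp_min_run: int = 5,
                het_thresh: float = 0.2,
                methods: Mapping[str, str] | None = None,
                ) -> tuple[list[ConcordanceRecord], ConcordanceSummary]:
    """Compare NGS genotype calls (per sample and pooled) with Sanger truth.

    A truth locus with zero NGS coverage in a sample is a no-call for that
    sample, not a discordance. The summary counts discordant
    (sample, locus) pairs per fragmentation method and the number of loci
    with at least one discordant sample.
    """
    runs = homopolymer_runs(region.sequence, hp_min_run)
    filtered = {s: filter_indels(pu, runs)
                for s, pu in pileups_by_sample.items()}
    pooled_pre = None
    for pu in pileups_by_sample.values():
        pooled_pre = pu if pooled_pre is None else pooled_pre + pu
    pooled_filt = filter_indels(pooled_pre, runs)

    records = []
    by_method: dict[str, int] = {}
    n_any = 0
    for entry in truth:
        offsets = tuple(region.offset_of(p) for p in entry.positions)
        for off in offsets:
            if not (0 <= off < len(region)):
                raise ValueError(f"truth position {entry.positions} "
                                 "outside region")
        tset = _truth_allele_set(entry)
        per_sample: dict[str, LocusCall] = {}
        agreement: dict[str, bool | None] = {}
        for s in pileups_by_sample:
            call = call_locus(offsets, filtered[s], pileups_by_sample[s],
                              het_thresh)
            per_sample[s] = call
            if call.alleles is None:
                agreement[s] = None
            else:
                agreement[s] = call.allele_set == tset
        pooled_call = call_locus(offsets, pooled_filt, pooled_pre, het_thresh)
        pooled_ok = (None if pooled_call.alleles is None
                     else pooled_call.allele_set == tset)
        rec = ConcordanceRecord(entry, per_sample, agreement, pooled_call,
                                pooled_ok)
        records.append(rec)
        if rec.n_discordant:
            n_any += 1
        for s, ok in agreement.items():
            if ok is False:
                m = methods.get(s, s) if methods else s
                by_method[m] = by_method.get(m, 0) + 1
    summary = ConcordanceSummary(by_method, n_any, len(truth))
    return records, summary


def concordance_table(records: Sequence[ConcordanceRecord],
                      region: ReferenceRegion):
    """Flat DataFrame mirroring the Sanger/ALL/per-sample report layout."""
    import pandas as pd
    rows = []
    for rec in records:
        row = {
            "position": "-".join(f"{p:,}".replace(",", ".")
                                 for p in rec.truth.positions),
            "ref": rec.truth.ref,
            "sanger": rec.truth.zygosity,
            "ALL": f"{rec.pooled.rendered} S{rec.pooled.depth} "
                   f"{rec.pooled.major_pct:.0f}%",
            "ALL_discordant": rec.pooled_agrees is False,
        }
        for s, call in rec.per_sample.items():
            flag = "*" if rec.agreement[s] is False else ""
            row[s] = (f"{call.rendered} S{call.depth} "
                      f"{call.major_pct:.0f}%{flag}")
        rows.append(row)
    return pd.DataFrame(rows)
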