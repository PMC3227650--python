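"""Synthetic 454-style amplicon sequencing with method-specific fragmentation.

This module simulates the wet-lab half of a long-range-PCR resequencing
experiment: an equimolar pool of overlapping PCR amplicons tiling a genomic
region is fragmented (nebulization, sonication, or enzymatic digestion),
small fragments are removed by size selection, and each retained fragment is
"pyrosequenced" from a random end under an error model with the two
signatures of the 454 platform:

* homopolymer length miscalls -- a maximal run of n identical bases is
  emitted with length n +/- 1 with probability ``min(hp_beta * n, hp_pmax)``,
  reflecting the non-linear luminescence response to long homopolymers;
* a per-base substitution rate that ramps linearly along the read, and
  PHRED-style qualities that decay toward the 3' end.

Enzymatic digestion additionally injects uniform random indels
(``extra_indel_rate``), modelling nick-repair artifacts.

Every read carries a machine-readable truth record (sample, amplicon,
reference interval, strand, and an edit string in a CIGAR-with-substitutions
dialect ``=/X/I/D``) so that downstream alignment, pileup and error
statistics can be checked against ground truth exactly.

Coordinates are 0-based half-open everywhere internally; 1-based closed
positions appear only in human-facing reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# ---------------------------------------------------------------------------
# DNA helpers
# ---------------------------------------------------------------------------

_ALPHABET = "ACGTN"
_B2I = {b: i for i, b in enumerate(_ALPHABET)}
_I2B = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
_ENC = np.full(256, 255, dtype=np.uint8)
for _b, _i in _B2I.items():
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

NEBULIZATION = "nebulization"
SONICATION = "sonication"
ENZYMATIC = "enzymatic"
METHODS = (NEBULIZATION, SONICATION, ENZYMATIC)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 indices (A=0,C=1,G=2,T=3,N=4)."""
    arr = _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        raise ValueError("sequence contains characters outside ACGTN")
    return arr


def decode(arr: np.ndarray) -> str:
    return _I2B[arr].tobytes().decode()


def revcomp_idx(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an index array restricted to A/C/G/T."""
    return (3 - arr)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_idx(encode(seq)))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceRegion:
    """A labelled reference interval with its sequence.

    ``start``/``end`` are 0-based half-open coordinates on the chromosome;
    ``sequence`` covers exactly [start, end).
    """

    name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if self.end - self.start != len(self.sequence):
            raise ValueError("sequence length does not match [start, end)")
        if set(self.sequence) - set("ACGT"):
            raise ValueError("reference alphabet must be a subset of {A,C,G,T}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def seq_idx(self) -> np.ndarray:
        return encode(self.sequence)

    def abs_pos_1based(self, offset: int) -> int:
        """Region-relative 0-based offset -> chromosome 1-based position."""
        return self.start + offset + 1

    def offset_of(self, pos_1based: int) -> int:
        return pos_1based - self.start - 1


@dataclass(frozen=True)
class Amplicon:
    """One long-range-PCR product, as a region-relative interval."""

    id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AmpliconPanel:
    """The set of overlapping amplicons tiling a reference region."""

    region: ReferenceRegion
    amplicons: tuple[Amplicon, ...]
    min_length: int = 1000
    max_length: int = 9000

    def __post_init__(self):
        if not self.amplicons:
            raise ValueError("panel must contain at least one amplicon")
        L = len(self.region)
        for a in self.amplicons:
            if not (0 <= a.start < a.end <= L):
                raise ValueError(f"amplicon {a.id} outside region")
            if not (self.min_length <= a.length <= self.max_length):
                raise ValueError(
                    f"amplicon {a.id} length {a.length} outside "
                    f"[{self.min_length}, {self.max_length}]"
                )
        ivs = sorted((a.start, a.end) for a in self.amplicons)
        cover = ivs[0][1]
        if ivs[0][0] != 0:
            raise ValueError("amplicons do not cover the region start")
        for s, e in ivs[1:]:
            if s > cover:
                raise ValueError("amplicons leave a gap in the region")
            cover = max(cover, e)
        if cover < L:
            raise ValueError("amplicons do not cover the region end")

    def amplicon_seq_idx(self, a: Amplicon) -> np.ndarray:
        return self.region.seq_idx[a.start:a.end]


@dataclass(frozen=True)
class MIDTag:
    """A multiplex identifier: a sample label and its 5' barcode."""

    sample_id: str
    barcode: str

    def __post_init__(self):
        if set(self.barcode) - set("ACGT"):
            raise ValueError("barcode must be ACGT only")


#: Nine fixed 10-mer barcodes with pairwise Hamming distance >= 5, one per
#: replicate library (three per fragmentation method).
DEFAULT_BARCODES = (
    "CACTAATTAC", "ACATTACTAT", "GCGCTGTCTA",
    "GCGCACCGGT", "CGATATTAGA", "GTCCAGGCGC",
    "AACCGATAGT", "AATGTACTGG", "TCACGATTAG",
)

DEFAULT_SAMPLES = (
    "Neb1", "Neb2", "Neb3", "Son1", "Son2", "Son3", "Enz1", "Enz2", "Enz3",
)


def default_mids() -> tuple[MIDTag, ...]:
    return tuple(MIDTag(s, b) for s, b in zip(DEFAULT_SAMPLES, DEFAULT_BARCODES))


def default_methods() -> dict[str, str]:
    return {
        "Neb1": NEBULIZATION, "Neb2": NEBULIZATION, "Neb3": NEBULIZATION,
        "Son1": SONICATION, "Son2": SONICATION, "Son3": SONICATION,
        "Enz1": ENZYMATIC, "Enz2": ENZYMATIC, "Enz3": ENZYMATIC,
    }


@dataclass(frozen=True)
class FragMethodParams:
    """Fragment-length distribution (gamma renewal) and artifact indel rate.

    The gamma family gives positive support and tunable dispersion; the
    defaults (shape 9, scale 50) put the mean fragment length at 450 bp,
    matching the observed ~450 bp read medians. ``extra_indel_rate`` is the
    per-base probability of a nick-repair indel artifact: zero for the two
    mechanical methods, positive for enzymatic digestion.
    """

    length_shape: float = 9.0
    length_scale: float = 50.0
    extra_indel_rate: float = 0.0

    def __post_init__(self):
        if self.length_shape <= 0 or self.length_scale <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.extra_indel_rate < 0:
            raise ValueError("extra_indel_rate must be >= 0")

    @property
    def mean_length(self) -> float:
        return self.length_shape * self.length_scale


def default_frag_params() -> dict[str, FragMethodParams]:
    return {
        NEBULIZATION: FragMethodParams(),
        SONICATION: FragMethodParams(),
        ENZYMATIC: FragMethodParams(extra_indel_rate=0.001),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of one simulated sequencing run.

    Probabilities are per base unless noted. ``seed`` fully determines the
    output (byte-identical re-runs).
    """

    panel: AmpliconPanel
    mids: tuple[MIDTag, ...] = field(default_factory=default_mids)
    methods: Mapping[str, str] = field(default_factory=default_methods)
    frag_params: Mapping[str, FragMethodParams] = field(
        default_factory=default_frag_params)
    molecules_per_amplicon: int = 360
    size_select_min: int = 500
    max_read_len_mean: float = 450.0
    max_read_len_sd: float = 120.0
    sub_rate0: float = 0.002
    sub_rate_slope: float = 0.003
    hp_beta: float = 0.01
    hp_pmax: float = 0.5
    hp_min_len: int = 2
    q0: float = 38.0
    q_decay: float = 20.0
    q_gamma: float = 1.7
    q_noise: int = 2
    mid_corrupt_prob: float = 0.025
    het_snps: tuple[tuple[int, str], ...] = ()
    seed: int = 0

    def __post_init__(self):
        ids = [m.sample_id for m in self.mids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids in MID list")
        lens = {len(m.barcode) for m in self.mids}
        if len(lens) != 1:
            raise ValueError("all barcodes must have the same length")
        for s in ids:
            if s not in self.methods:
                raise ValueError(f"no fragmentation method for sample {s}")
            if self.methods[s] not in self.frag_params:
                raise ValueError(f"no FragMethodParams for {self.methods[s]}")
        for p in (self.sub_rate0, self.hp_beta, self.hp_pmax,
                  self.mid_corrupt_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.size_select_min < 0:
            raise ValueError("size_select_min must be >= 0")
        if self.molecules_per_amplicon < 1:
            raise ValueError("molecules_per_amplicon must be >= 1")
        L = len(self.panel.region)
        for pos, alt in self.het_snps:
            if not (0 <= pos < L) or alt not in "ACGT":
                raise ValueError("het_snps entries must be (offset, ACGT base)")
            if alt == self.panel.region.sequence[pos]:
                raise ValueError("het SNP alt equals the reference base")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.mids)


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated read plus its truth provenance.

    ``bases`` includes the 5' MID (possibly corrupted). ``ops`` is the edit
    string, in read orientation, that turns the reference slice
    [ref_start, ref_end) (reverse-complemented first for '-' strand reads)
    into the post-MID bases.
    """

    read_id: str
    sample_id_truth: str
    bases: str
    qualities: np.ndarray
    amplicon_id: str
    ref_start: int
    ref_end: int
    strand: str
    ops: tuple[tuple[int, str, str], ...]
    mid_corrupted: bool
    mid_len: int

    def __post_init__(self):
        if len(self.bases) != len(self.qualities):
            raise ValueError("bases and qualities must have equal length")

    @property
    def insert_bases(self) -> str:
        """Read bases with the 5' MID stripped."""
        return self.bases[self.mid_len:]


# ---------------------------------------------------------------------------
# Edit-string dialect (=/X/I/D with explicit bases for X and I)
# ---------------------------------------------------------------------------

def ops_to_string(ops: Iterable[tuple[int, str, str]]) -> str:
    """Serialize, e.g. ``[(120,'=',''),(1,'X','G'),(2,'D','')] -> '120=1XG2D'``."""
    out = []
    for n, op, b in ops:
        out.append(f"{n}{op}{b}")
    return "".join(out)


def ops_from_string(s: str) -> tuple[tuple[int, str, str], ...]:
    ops = []
    i, n = 0, len(s)
    while i < n:
        j = i
        while j < n and s[j].isdigit():
            j += 1
        if j == i or j >= n:
            raise ValueError(f"malformed edit string at offset {i}: {s!r}")
        count = int(s[i:j])
        op = s[j]
        j += 1
        bases = ""
        if op in "XI":
            bases = s[j:j + count]
            if len(bases) != count:
                raise ValueError(f"truncated bases for {op} in {s!r}")
            j += count
        elif op not in "=D":
            raise ValueError(f"unknown edit op {op!r} in {s!r}")
        ops.append((count, op, bases))
        i = j
    return tuple(ops)


def apply_ops(template_idx: np.ndarray, ops: Sequence[tuple[int, str, str]]
              ) -> np.ndarray:
    """Replay an edit string against its template; returns the read indices."""
    parts = []
    t = 0
    for n, op, b in ops:
        if op == "=":
            parts.append(template_idx[t:t + n])
            t += n
        elif op == "X":
            parts.append(encode(b))
            t += n
        elif op == "D":
            t += n
        elif op == "I":
            parts.append(encode(b))
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op!r}")
    if t != len(template_idx):
        raise ValueError("edit string does not consume the template exactly")
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts)


def ops_ref_span(ops: Sequence[tuple[int, str, str]]) -> int:
    return sum(n for n, op, _ in ops if op in "=XD")


def ops_read_len(ops: Sequence[tuple[int, str, str]]) -> int:
    return sum(n for n, op, _ in ops if op in "=XI")


# ---------------------------------------------------------------------------
# Reference / panel construction
# ---------------------------------------------------------------------------

def synthetic_reference(length: int, seed: int = 1234, hp_runs: int = 0,
                        hp_len: tuple[int, int] = (6, 9)) -> str:
    """Random ACGT reference; optionally plant extra long homopolymer runs.

    ``hp_runs`` extra runs with lengths uniform in ``hp_len`` are overwritten
    at random positions (used for homopolymer-rich test scenarios; random DNA
    already contains many runs of length >= 5).
    """
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 4, size=length).astype(np.uint8)
    for _ in range(hp_runs):
        n = int(rng.integers(hp_len[0], hp_len[1] + 1))
        p = int(rng.integers(0, max(1, length - n)))
        arr[p:p + n] = rng.integers(0, 4)
    return decode(arr)


_DEFAULT_REGION_START = 99_724_999  # 0-based; 1-based positions begin at 99,725,000
_DEFAULT_REGION_LEN = 49_000
_DEFAULT_AMPLICONS = (
    ("F1", 0, 9_000),
    ("F2", 8_940, 17_940),
    ("F3", 17_880, 26_380),
    ("F4", 26_320, 34_760),
    ("F5", 34_700, 37_200),   # 2.5 kbp
    ("F6", 37_140, 39_140),   # 2.0 kbp
    ("F7", 39_080, 40_280),   # 1.2 kbp
    ("F8", 40_220, 49_000),
)


def default_panel(ref_seed: int = 1234) -> AmpliconPanel:
    """The default study panel: eight overlapping 1.2-9 kbp amplicons on a
    fixed synthetic ~49 kbp region (the reference genome does not change with
    the simulation seed)."""
    region = ReferenceRegion(
        "chr1", _DEFAULT_REGION_START,
        _DEFAULT_REGION_START + _DEFAULT_REGION_LEN,
        synthetic_reference(_DEFAULT_REGION_LEN, seed=ref_seed),
    )
    amps = tuple(Amplicon(i, s, e) for i, s, e in _DEFAULT_AMPLICONS)
    return AmpliconPanel(region, amps)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    return SimulationConfig(panel=default_panel(), seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Fragmentation and size selection
# ---------------------------------------------------------------------------

def fragment_molecule(amplicon_length: int, params: FragMethodParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Cut one molecule into contiguous fragments (gamma renewal process).

    Lengths are i.i.d. gamma draws rounded to integers >= 1; the final
    fragment is truncated so the fragments tile [0, amplicon_length) exactly.
    """
    if amplicon_length < 1:
        raise ValueError("amplicon_length must be >= 1")
    est = int(amplicon_length / params.mean_length) + 4
    est += int(3 * np.sqrt(est))
    while True:
        draws = np.maximum(
            1, np.rint(rng.gamma(params.length_shape, params.length_scale,
                                 size=est))).astype(np.int64)
        cum = np.cumsum(draws)
        if cum[-1] >= amplicon_length:
            break
        est *= 2
    k = int(np.searchsorted(cum, amplicon_length))
    lengths = draws[:k + 1].copy()
    lengths[k] = amplicon_length - (cum[k - 1] if k > 0 else 0)
    return lengths


def _frag_len(frag) -> int:
    if isinstance(frag, (int, np.integer)):
        return int(frag)
    start, end = frag
    return int(end) - int(start)


def size_select(fragments: Sequence, min_len: int) -> list:
    """Retain fragments with length >= ``min_len`` (order preserved).

    Accepts plain lengths or (start, end) intervals.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    return [f for f in fragments if _frag_len(f) >= min_len]


# ---------------------------------------------------------------------------
# Per-fragment sequencing error model
# ---------------------------------------------------------------------------

def _merge_ops(ops: list[tuple[int, str, str]]) -> tuple[tuple[int, str, str], ...]:
    merged: list[tuple[int, str, str]] = []
    for n, op, b in ops:
        if merged and merged[-1][1] == op:
            pn, _, pb = merged[-1]
            merged[-1] = (pn + n, op, pb + b)
        else:
            merged.append((n, op, b))
    return tuple(merged)


def sequence_fragment(frag_mol_idx: np.ndarray, config: SimulationConfig,
                      rng: np.random.Generator,
                      extra_indel_rate: float = 0.0,
                      frag_ref_idx: np.ndarray | None = None,
                      ) -> tuple[np.ndarray, np.ndarray, str, int,
                                 tuple[tuple[int, str, str], ...]]:
    """Sequence one fragment molecule from a uniformly chosen end.

    ``frag_mol_idx`` is the fragment's molecule sequence in reference-forward
    orientation; ``frag_ref_idx`` is the corresponding reference slice (equal
    to the molecule unless the molecule carries planted variants), against
    which the truth edit string is expressed (so real variants appear as X).

    Returns ``(read_idx, qualities, strand, ref_span, ops)`` where ``ops`` is
    in read orientation against the (strand-adjusted) reference template of
    length ``ref_span``.
    """
    L_frag = len(frag_mol_idx)
    if L_frag == 0:
        raise ValueError("fragment must be non-empty")
    if frag_ref_idx is None:
        frag_ref_idx = frag_mol_idx

    strand = "+" if rng.random() < 0.5 else "-"
    draw = rng.normal(config.max_read_len_mean, config.max_read_len_sd)
    span = int(min(L_frag, max(1.0, np.rint(draw))))
    if strand == "+":
        tmpl = frag_mol_idx[:span]
        tmpl_ref = frag_ref_idx[:span]
    else:
        tmpl = revcomp_idx(frag_mol_idx)[:span]
        tmpl_ref = revcomp_idx(frag_ref_idx)[:span]
    L = span

    # Maximal homopolymer runs of the molecule template.
    if L > 1:
        bnd = np.flatnonzero(tmpl[1:] != tmpl[:-1]) + 1
    else:
        bnd = np.empty(0, dtype=np.int64)
    starts = np.concatenate(([0], bnd))
    ends = np.concatenate((bnd, [L]))
    lens = ends - starts

    elig = lens >= config.hp_min_len
    p_run = np.where(elig, np.minimum(config.hp_beta * lens, config.hp_pmax), 0.0)
    hp_event = rng.random(len(lens)) < p_run
    hp_plus = rng.random(len(lens)) < 0.5

    del_mask = np.zeros(L, dtype=bool)
    ins_after: dict[int, list[int]] = {}

    for r in np.flatnonzero(hp_event):
        last = int(ends[r]) - 1
        if hp_plus[r]:
            ins_after.setdefault(last, []).append(int(tmpl[int(starts[r])]))
        else:
            del_mask[last] = True

    if extra_indel_rate > 0:
        for p in np.flatnonzero(rng.random(L) < extra_indel_rate):
            if rng.random() < 0.5:
                del_mask[int(p)] = True
            else:
                ins_after.setdefault(int(p), []).append(int(rng.integers(0, 4)))

    # Substitutions ramp along the read; skip deleted and variant positions.
    variant = tmpl != tmpl_ref
    ramp = config.sub_rate0 + config.sub_rate_slope * (np.arange(L) / max(L, 1))
    sub_mask = (rng.random(L) < ramp) & ~del_mask & ~variant
    sub_bases = (tmpl[sub_mask] + 1 + rng.integers(0, 3, size=int(sub_mask.sum()))
                 ).astype(np.uint8) % 4

    # Assemble the edit string against the reference template.
    x_mask = (sub_mask | variant) & ~del_mask
    x_bases = tmpl.copy()
    x_bases[sub_mask] = sub_bases
    evt = sorted(set(np.flatnonzero(del_mask | x_mask).tolist())
                 | set(ins_after.keys()))
    ops: list[tuple[int, str, str]] = []
    cur = 0
    for p in evt:
        if del_mask[p] or x_mask[p]:
            if p > cur:
                ops.append((p - cur, "=", ""))
            if del_mask[p]:
                ops.append((1, "D", ""))
            else:
                ops.append((1, "X", decode(x_bases[p:p + 1])))
            cur = p + 1
        else:  # insertion anchor only: the base itself is a match
            ops.append((p + 1 - cur, "=", ""))
            cur = p + 1
        if p in ins_after:
            b = decode(np.asarray(ins_after[p], dtype=np.uint8))
            ops.append((len(b), "I", b))
    if cur < L:
        ops.append((L - cur, "=", ""))
    ops_t = _merge_ops(ops)

    read_idx = apply_ops(tmpl_ref, ops_t)
    n = len(read_idx)
    idx = np.arange(n)
    q = np.rint(config.q0 - config.q_decay * (idx / max(n - 1, 1)) ** config.q_gamma)
    if config.q_noise > 0:
        q = q + rng.integers(-config.q_noise, config.q_noise + 1, size=n)
    quals = np.clip(q, 2, 41).astype(np.int16)
    return read_idx, quals, strand, span, ops_t


# ---------------------------------------------------------------------------
# Whole-run simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    config: SimulationConfig
    reads: list[SimulatedRead]

    @property
    def n_reads(self) -> int:
        return len(self.reads)


def simulate_run(config: SimulationConfig) -> SimulationResult:
    """Simulate the pooled run: every sample's molecules are fragmented,
    size-selected and sequenced (one read per retained fragment), the sample
    MID is prepended (destroyed with probability ``mid_corrupt_prob``), and
    all reads are interleaved by a seeded shuffle."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.samples) + 1)
    mid_by_sample = {m.sample_id: m.barcode for m in config.mids}
    mid_len = len(config.mids[0].barcode)
    region_idx = config.panel.region.seq_idx
    snps = [(p, _B2I[a]) for p, a in config.het_snps]

    reads: list[SimulatedRead] = []
    for sample, child in zip(config.samples, children):
        rng = np.random.default_rng(child)
        method = config.methods[sample]
        fp = config.frag_params[method]
        barcode = mid_by_sample[sample]
        for amp in config.panel.amplicons:
            ref_amp = region_idx[amp.start:amp.end]
            amp_snps = [(p - amp.start, ai) for p, ai in snps
                        if amp.start <= p < amp.end]
            for mol_i in range(config.molecules_per_amplicon):
                if amp_snps:
                    mol = ref_amp.copy()
                    for off, ai in amp_snps:
                        if rng.random() < 0.5:
                            mol[off] = ai
                else:
                    mol = ref_amp
                lengths = fragment_molecule(amp.length, fp, rng)
                offs = np.concatenate(([0], np.cumsum(lengths)[:-1]))
                frags = list(zip(offs.tolist(), (offs + lengths).tolist()))
                for k, (fs, fe) in enumerate(size_select(frags,
                                                         config.size_select_min)):
                    frag_mol = mol[fs:fe]
                    frag_ref = ref_amp[fs:fe] if amp_snps else frag_mol
                    read_idx, quals, strand, span, ops = sequence_fragment(
                        frag_mol, config, rng, fp.extra_indel_rate,
                        frag_ref_idx=frag_ref)
                    if strand == "+":
                        r0 = amp.start + fs
                        r1 = r0 + span
                    else:
                        r1 = amp.start + fe
                        r0 = r1 - span
                    corrupted = rng.random() < config.mid_corrupt_prob
                    mid_seq = (decode(rng.integers(0, 4, size=mid_len)
                                      .astype(np.uint8))
                               if corrupted else barcode)
                    mid_quals = np.full(mid_len, 35, dtype=np.int16)
                    reads.append(SimulatedRead(
                        read_id=f"{sample}:{amp.id}:{mol_i}:{k}",
                        sample_id_truth=sample,
                        bases=mid_seq + decode(read_idx),
                        qualities=np.concatenate((mid_quals, quals)),
                        amplicon_id=amp.id,
                        ref_start=r0, ref_end=r1, strand=strand,
                        ops=ops, mid_corrupted=corrupted, mid_len=mid_len,
                    ))
    shuffle_rng = np.random.default_rng(children[-1])
    order = shuffle_rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    return SimulationResult(config=config, reads=reads)


def reconstruct_read(read: SimulatedRead, region: ReferenceRegion) -> str:
    """Replay a read's truth edits against the reference; must equal the
    post-MID bases (the truth-consistency invariant)."""
    ref_slice = region.seq_idx[read.ref_start:read.ref_end]
    tmpl = ref_slice if read.strand == "+" else revcomp_idx(ref_slice)
    return decode(apply_ops(tmpl, read.ops))


# ---------------------------------------------------------------------------
# File IO (FASTQ / truth TSV / BED / FASTA / JSON config)
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable, path) -> None:
    """Write reads (anything with read_id/bases/qualities) as Sanger FASTQ."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    def records():
        for r in reads:
            rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
            yield rec

    with open(path, "w") as fh:
        SeqIO.write(records(), fh, "fastq")


def read_fastq(path) -> list:
    """Read a Sanger FASTQ into lightweight read objects."""
    from Bio import SeqIO
    from .demux import FastqRead

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(FastqRead(
            read_id=rec.id, bases=str(rec.seq),
            qualities=np.asarray(rec.letter_annotations["phred_quality"],
                                 dtype=np.int16)))
    return out


TRUTH_COLUMNS = ("read_id", "sample", "amplicon", "ref_start", "ref_end",
                 "strand", "edits", "mid_corrupted")


def write_truth_tsv(reads: Iterable[SimulatedRead], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for r in reads:
            fh.write("\t".join((
                r.read_id, r.sample_id_truth, r.amplicon_id,
                str(r.ref_start), str(r.ref_end), r.strand,
                ops_to_string(r.ops), "1" if r.mid_corrupted else "0")) + "\n")


def read_truth_tsv(path) -> "list[TruthRecord]":
    import csv
    out = []
    with open(path) as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            out.append(TruthRecord(
                read_id=row["read_id"], sample=row["sample"],
                amplicon=row["amplicon"], ref_start=int(row["ref_start"]),
                ref_end=int(row["ref_end"]), strand=row["strand"],
                ops=ops_from_string(row["edits"]),
                mid_corrupted=row["mid_corrupted"] == "1"))
    return out


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    sample: str
    amplicon: str
    ref_start: int
    ref_end: int
    strand: str
    ops: tuple[tuple[int, str, str], ...]
    mid_corrupted: bool


def write_panel_bed(panel: AmpliconPanel, path) -> None:
    """Amplicon intervals as BED (0-based half-open, chromosome coordinates)."""
    with open(path, "w") as fh:
        for a in panel.amplicons:
            fh.write(f"{panel.region.name}\t{panel.region.start + a.start}\t"
                     f"{panel.region.start + a.end}\t{a.id}\n")


def write_region_fasta(region: ReferenceRegion, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    rec = SeqRecord(Seq(region.sequence), id=region.name,
                    description=f"{region.start + 1}-{region.end}")
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def read_region_fasta(path, name: str | None = None,
                      start: int = 0) -> ReferenceRegion:
    from Bio import SeqIO
    recs = list(SeqIO.parse(str(path), "fasta"))
    if not recs:
        raise ValueError(f"no FASTA records in {path}")
    rec = recs[0] if name is None else next(r for r in recs if r.id == name)
    seq = str(rec.seq).upper()
    return ReferenceRegion(rec.id, start, start + len(seq), seq)


def config_to_json(config: SimulationConfig) -> str:
    d = {
        "region": {
            "name": config.panel.region.name,
            "start": config.panel.region.start,
            "end": config.panel.region.end,
            "sequence": config.panel.region.sequence,
        },
        "amplicons": [[a.id, a.start, a.end] for a in config.panel.amplicons],
        "mids": [[m.sample_id, m.barcode] for m in config.mids],
        "methods": dict(config.methods),
        "frag_params": {k: dataclasses.asdict(v)
                        for k, v in config.frag_params.items()},
        "het_snps": [[p, a] for p, a in config.het_snps],
    }
    for f in ("molecules_per_amplicon", "size_select_min", "max_read_len_mean",
              "max_read_len_sd", "sub_rate0", "sub_rate_slope", "hp_beta",
              "hp_pmax", "hp_min_len", "q0", "q_decay", "q_gamma", "q_noise",
              "mid_corrupt_prob", "seed"):
        d[f] = getattr(config, f)
    return json.dumps(d, indent=2)


def config_from_json(text: str) -> SimulationConfig:
    d = json.loads(text)
    region = ReferenceRegion(**d["region"])
    panel = AmpliconPanel(region, tuple(Amplicon(i, s, e)
                                        for i, s, e in d["amplicons"]))
    kwargs = {f: d[f] for f in (
        "molecules_per_amplicon", "size_select_min", "max_read_len_mean",
        "max_read_len_sd", "sub_rate0", "sub_rate_slope", "hp_beta", "hp_pmax",
        "hp_min_len", "q0", "q_decay", "q_gamma", "q_noise",
        "mid_corrupt_prob", "seed") if f in d}
    return SimulationConfig(
        panel=panel,
        mids=tuple(MIDTag(s, b) for s, b in d["mids"]),
        methods=d["methods"],
        frag_params={k: FragMethodParams(**v)
                     for k, v in d["frag_params"].items()},
        het_snps=tuple((int(p), a) for p, a in d.get("het_snps", [])),
        **kwargs)
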