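"""Bundled worked-example data: a published nine-replicate 454 benchmark.

Seven Sanger-validated positions of a human gene (chromosome 1, hg19) from a
pooled GS Junior run of nine replicate libraries (three library preparations
per fragmentation method: nebulization, sonication, enzymatic digestion).
For every locus the per-replicate coverage (number of sequence fragments
covering the position) and the percentage of calls for the major allele are
recorded, together with the Sanger zygosity and alleles. The four
heterozygous SNP rows and the 99,767,383 row are internally consistent
(replicate coverages sum to the pooled coverage); the two dinucleotide rows
and one homozygous row use the source's footnote conventions (mean coverage
over both positions, indel-poor subsets pooled) and their printed pooled
values are retained verbatim rather than recomputed.

These numbers serve as ground truth for the replicate-pooling arithmetic
and for composition checks; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genotyping import SangerTruthEntry

#: Replicate labels in table order (three per method).
REPLICATES = ("Neb1", "Neb2", "Neb3", "Son1", "Son2", "Son3",
              "Enz1", "Enz2", "Enz3")

REPLICATE_METHODS = {
    "Neb1": "nebulization", "Neb2": "nebulization", "Neb3": "nebulization",
    "Son1": "sonication", "Son2": "sonication", "Son3": "sonication",
    "Enz1": "enzymatic", "Enz2": "enzymatic", "Enz3": "enzymatic",
}


@dataclass(frozen=True)
class ValidationLocus:
    """One benchmark locus with per-replicate coverage and major-allele %."""

    positions: tuple[int, ...]      # 1-based, chromosome 1 (hg19)
    ref: str
    zygosity: str                   # Sanger zygosity
    alleles: tuple[str, ...]        # Sanger alleles
    depths: tuple[int, ...]         # per replicate, table order
    major_pct: tuple[int, ...]      # per replicate, table order
    pooled_depth: int               # printed pooled coverage
    pooled_major_pct: int           # printed pooled major-allele %
    consistent: bool                # replicate depths sum to pooled depth

    def truth_entry(self) -> SangerTruthEntry:
        return SangerTruthEntry("chr1", self.positions, self.ref,
                                self.zygosity, self.alleles)


VALIDATION_LOCI: tuple[ValidationLocus, ...] = (
    ValidationLocus(
        positions=(99_748_311,), ref="T", zygosity="het", alleles=("T", "G"),
        depths=(44, 143, 71, 150, 36, 96, 98, 53, 62),
        major_pct=(59, 52, 52, 51, 64, 47, 55, 43, 40),
        pooled_depth=753, pooled_major_pct=51, consistent=True),
    ValidationLocus(
        positions=(99_748_324,), ref="C", zygosity="het", alleles=("C", "T"),
        depths=(49, 140, 71, 144, 35, 85, 87, 55, 63),
        major_pct=(67, 65, 69, 57, 69, 61, 71, 65, 52),
        pooled_depth=729, pooled_major_pct=63, consistent=True),
    ValidationLocus(
        positions=(99_748_522,), ref="A", zygosity="het", alleles=("A", "G"),
        depths=(62, 151, 78, 157, 43, 102, 75, 49, 62),
        major_pct=(60, 52, 54, 46, 49, 53, 53, 49, 45),
        pooled_depth=779, pooled_major_pct=51, consistent=True),
    ValidationLocus(
        positions=(99_762_338, 99_762_339), ref="AA", zygosity="hom",
        alleles=("AA",),
        depths=(157, 228, 146, 205, 54, 160, 123, 99, 121),
        major_pct=(74, 100, 98, 99, 72, 100, 99, 99, 99),
        pooled_depth=1221, pooled_major_pct=99, consistent=False),
    ValidationLocus(
        positions=(99_764_728,), ref="T", zygosity="hom", alleles=("T",),
        depths=(22, 109, 62, 84, 16, 67, 42, 42, 37),
        major_pct=(100, 100, 100, 99, 75, 100, 100, 100, 97),
        pooled_depth=482, pooled_major_pct=100, consistent=False),
    ValidationLocus(
        positions=(99_767_383,), ref="C", zygosity="het", alleles=("C", "G"),
        depths=(13, 29, 21, 16, 4, 22, 11, 12, 10),
        major_pct=(31, 59, 29, 56, 50, 45, 64, 50, 60),
        pooled_depth=138, pooled_major_pct=49, consistent=True),
    ValidationLocus(
        positions=(99_772_437, 99_772_438), ref="TT", zygosity="hom",
        alleles=("TT",),
        depths=(37, 109, 132, 109, 22, 98, 82, 54, 78),
        major_pct=(100, 100, 100, 100, 100, 77, 99, 99, 100),
        pooled_depth=675, pooled_major_pct=100, consistent=False),
)


def sanger_truth_entries() -> list[SangerTruthEntry]:
    return [loc.truth_entry() for loc in VALIDATION_LOCI]


def zygosity_counts() -> dict[str, int]:
    out = {"het": 0, "hom": 0}
    for loc in VALIDATION_LOCI:
        out[loc.zygosity] += 1
    return out
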