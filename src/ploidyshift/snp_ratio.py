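"""Bi-allelic SNP filtering, replicate intersection and read-ratio computation.

The ploidy signal lives in the reference-allele read fraction at
heterozygous sites: a diploid heterozygote sequences reference and
alternate reads 1:1 (ratio 0.5); a triploid at 1:2 or 2:1 (1/3, 2/3);
a tetraploid at 1:3, 1:1 or 3:1 (0.25, 0.5, 0.75).  Raw per-replicate
calls are depth-filtered, only variants confirmed in both replicate
libraries are kept, and their read counts are pooled before ratios are
taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class SnpRecord:
    """One bi-allelic variant call in one replicate library."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValueError("read counts must be non-negative")
        if self.ref_count + self.alt_count < 1:
            raise ValueError("a SNP record needs at least one read")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the variant: contig, position and both alleles."""
        return (self.contig, self.position, self.ref_allele, self.alt_allele)

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass(frozen=True)
class RatioSet:
    """Reference-allele read fractions for one sample, with depths."""

    sample: str
    ratios: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ratios", np.asarray(self.ratios, dtype=float))
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=int))
        if self.ratios.shape != self.depths.shape:
            raise ValueError("ratios and depths must align")

    def __len__(self) -> int:
        return len(self.ratios)


def filter_biallelic(
    records: Iterable[SnpRecord],
    min_total: int = 10,
    max_total: int = 300,
    min_ref: int = 5,
) -> list[SnpRecord]:
    """Apply the per-replicate depth filters.

    Keeps records with total depth in ``[min_total, max_total]`` and at
    least ``min_ref`` reference reads.  The reference-allele minimum is
    deliberately asymmetric (no mirrored alternate-allele minimum); pass
    the records through twice with swapped alleles if a symmetric filter
    is wanted.  Order is preserved and the input is untouched.
    """
    if min_total < 1 or max_total < min_total or min_ref < 0:
        raise ValueError("inconsistent filter thresholds")
    return [
        r
        for r in records
        if min_total <= r.total <= max_total and r.ref_count >= min_ref
    ]


def intersect_replicates(
    rep1: Iterable[SnpRecord], rep2: Iterable[SnpRecord]
) -> list[SnpRecord]:
    """Keep variants confirmed in both replicate libraries, pooling reads.

    A variant is matched by (contig, position, ref allele, alt allele);
    for each variant present in both inputs the output carries the sum
    of the replicate read counts.  Output order follows ``rep1``.

    Raises ``ValueError`` if either replicate contains the same variant
    twice.
    """
    by_key: dict[tuple, SnpRecord] = {}
    for r in rep2:
        if r.key in by_key:
            raise ValueError(f"duplicate variant in replicate 2: {r.key}")
        by_key[r.key] = r
    out: list[SnpRecord] = []
    seen: set[tuple] = set()
    for r in rep1:
        if r.key in seen:
            raise ValueError(f"duplicate variant in replicate 1: {r.key}")
        seen.add(r.key)
        other = by_key.get(r.key)
        if other is not None:
            out.append(
                SnpRecord(
                    contig=r.contig,
                    position=r.position,
                    ref_allele=r.ref_allele,
                    alt_allele=r.alt_allele,
                    ref_count=r.ref_count + other.ref_count,
                    alt_count=r.alt_count + other.alt_count,
                )
            )
    return out


def compute_ratios(records: Sequence[SnpRecord], sample: str = "sample") -> RatioSet:
    """Reference-read fraction ref/(ref+alt) per combined record.

    This orientation puts the diploid heterozygote peak at 0.5, the
    triploid peaks at 1/3 and 2/3, and the tetraploid peaks at 0.25,
    0.5 and 0.75.
    """
    ratios = np.empty(len(records))
    depths = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        if r.total == 0:
            raise ValueError(f"zero total depth at {r.key}")
        ratios[i] = r.ref_count / r.total
        depths[i] = r.total
    return RatioSet(sample=sample, ratios=ratios, depths=depths)
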