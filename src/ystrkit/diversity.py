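"""Forensic diversity statistics for Y-STR haplotype data.

Implements the standard suite a Y-STR population report prints:

* per-locus allele frequencies by direct count (DYS385a/b analyzed as a
  combined, ascending-sorted allele pair counted once per sample);
* Nei's unbiased gene diversity, GD = (n/(n-1)) * (1 - sum p_i^2);
* whole-haplotype parameters: match probability MP = sum p_i^2, haplotype
  diversity HD = (n/(n-1)) * (1 - MP), and discrimination capacity
  DC = (number of distinct haplotypes) / n.

Null alleles are not repeat-count alleles, so they are excluded from
per-locus gene diversity by default (reported separately as a dropout
count), but they are legitimate distinguishing states in whole-haplotype
identity and stay in the haplotype counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

from .core import Allele, PopulationDataset, ValidationError


@dataclass
class FrequencyTable:
    """Per-locus allele counts and frequencies.

    Keys are :class:`Allele` for single-copy loci and sorted allele tuples
    for DYS385 combined pairs (or longer tuples for copy-number variants).
    ``n`` counts the samples contributing a non-null observation;
    ``null_count`` reports dropouts separately.
    """

    locus: str
    counts: Dict[object, int]
    n: int
    null_count: int = 0

    @property
    def frequencies(self) -> Dict[object, float]:
        return {k: c / self.n for k, c in self.counts.items()}


@dataclass
class HaplotypeCounts:
    """Occurrence counts of whole haplotypes."""

    counts: Dict[object, int]
    n: int
    k_distinct: int
    k_singleton: int

    @classmethod
    def from_counter(cls, counter: Dict[object, int]) -> "HaplotypeCounts":
        n = sum(counter.values())
        return cls(
            counts=dict(counter),
            n=n,
            k_distinct=len(counter),
            k_singleton=sum(1 for c in counter.values() if c == 1),
        )

    @classmethod
    def from_spectrum(cls, spectrum: Dict[int, int]) -> "HaplotypeCounts":
        """Build from a count spectrum ``{occurrence count: number of
        haplotypes}``, e.g. ``{1: 908, 2: 4}`` for 908 singletons and 4
        doubletons."""
        counter: Dict[object, int] = {}
        idx = 0
        for count, k in sorted(spectrum.items()):
            if count < 1 or k < 0:
                raise ValidationError("spectrum entries must be positive")
            for _ in range(k):
                counter[f"h{idx}"] = count
                idx += 1
        return cls.from_counter(counter)


def allele_frequencies(
    dataset: PopulationDataset, locus: str, include_nulls: bool = False
) -> FrequencyTable:
    """Allele (or DYS385 combined-pair) frequencies by direct count."""
    ld = dataset.locus(locus)
    counter: Counter = Counter()
    null_count = 0
    for rec in dataset.records:
        alleles = tuple(sorted(rec.haplotype[locus]))
        is_null_obs = any(a.is_null for a in alleles)
        if is_null_obs and not include_nulls:
            null_count += 1
            continue
        key: object = alleles if ld.copy_number > 1 else alleles[0]
        counter[key] += 1
    if not counter:
        raise ValidationError(f"locus {locus}: no non-null observations")
    n = sum(counter.values())
    return FrequencyTable(locus=locus, counts=dict(counter), n=n, null_count=null_count)


def gene_diversity(freqs: FrequencyTable) -> float:
    """Nei's unbiased gene diversity, GD = (n/(n-1)) * (1 - sum p_i^2)."""
    if freqs.n < 2:
        raise ValidationError(f"locus {freqs.locus}: gene diversity needs n >= 2")
    homozygosity = sum(p * p for p in freqs.frequencies.values())
    return (freqs.n / (freqs.n - 1)) * (1.0 - homozygosity)


def haplotype_counts(
    dataset: PopulationDataset, loci_subset: Optional[Sequence[str]] = None
) -> HaplotypeCounts:
    """Count whole-haplotype occurrences.

    Haplotype identity is the tuple of allele states over the chosen loci
    (DYS385 as sorted pair); nulls and microvariants are distinguishing
    states.
    """
    counter: Counter = Counter()
    for rec in dataset.records:
        counter[dataset.haplotype_key(rec, loci_subset)] += 1
    return HaplotypeCounts.from_counter(counter)


def match_probability(counts: HaplotypeCounts) -> float:
    """MP = sum over haplotypes of (count/n)^2: the probability that two
    randomly drawn samples share a haplotype (with replacement)."""
    if counts.n < 1:
        raise ValidationError("match probability needs n >= 1")
    return sum((c / counts.n) ** 2 for c in counts.counts.values())


def haplotype_diversity(counts: HaplotypeCounts) -> float:
    """HD = (n/(n-1)) * (1 - MP), Nei's estimator on whole haplotypes."""
    if counts.n < 2:
        raise ValidationError("haplotype diversity needs n >= 2")
    return (counts.n / (counts.n - 1)) * (1.0 - match_probability(counts))


def discrimination_capacity(counts: HaplotypeCounts) -> float:
    """DC = number of distinct haplotypes / sample size."""
    if counts.n < 1:
        raise ValidationError("discrimination capacity needs n >= 1")
    return counts.k_distinct / counts.n


@dataclass
class DiversityReport:
    """Full diversity summary of one dataset."""

    per_locus_gd: Dict[str, float]
    null_counts: Dict[str, int]
    hd: float
    mp: float
    dc: float
    n: int
    k_distinct: int
    k_singleton: int

    def rounded(self) -> Dict[str, object]:
        """Report-style rounding: GD/MP/DC to 4 decimals, HD to 5."""
        return {
            "per_locus_gd": {k: round(v, 4) for k, v in self.per_locus_gd.items()},
            "null_counts": dict(self.null_counts),
            "HD": round(self.hd, 5),
            "MP": round(self.mp, 4),
            "DC": round(self.dc, 4),
            "n": self.n,
            "k_distinct": self.k_distinct,
            "k_singleton": self.k_singleton,
        }


def diversity_report(dataset: PopulationDataset) -> DiversityReport:
    """Per-locus GD plus the whole-haplotype forensic parameters."""
    gd: Dict[str, float] = {}
    nulls: Dict[str, int] = {}
    for ld in dataset.loci:
        ft = allele_frequencies(dataset, ld.name)
        gd[ld.name] = gene_diversity(ft) if ft.n >= 2 else float("nan")
        nulls[ld.name] = ft.null_count
    counts = haplotype_counts(dataset)
    return DiversityReport(
        per_locus_gd=gd,
        null_counts=nulls,
        hd=haplotype_diversity(counts) if counts.n >= 2 else float("nan"),
        mp=match_probability(counts),
        dc=discrimination_capacity(counts),
        n=counts.n,
        k_distinct=counts.k_distinct,
        k_singleton=counts.k_singleton,
    )
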