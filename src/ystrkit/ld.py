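"""Pairwise linkage-disequilibrium testing between Y-STR loci.

The Y chromosome's male-specific region does not recombine, so panel loci
travel together as one haplotype and strong pairwise association is the
expected outcome.  For each locus pair the association between allele
states is summarized by the likelihood-ratio statistic
``G = 2 * sum O * ln(O / E)`` on the two-locus contingency table (E from
independence of the margins), and significance comes from a permutation
null: the second locus's allele column is shuffled across samples,
p = (k+1)/(N+1).

DYS385a/b handling: the full matrix defaults to entering DYS385a and
DYS385b as two separate column loci (the smaller allele of the sorted pair
is "a"), which gives the familiar C(23,2) = 253 comparisons for this panel.
Alternatively the combined sorted pair can be tested as one categorical
state (``dys385="combined"``, 22 loci, 231 comparisons).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import PopulationDataset, ValidationError


def ld_locus_names(dataset: PopulationDataset, dys385: str = "split") -> Tuple[str, ...]:
    """Column loci entering the LD scan.

    ``dys385="split"`` expands multi-copy loci into per-copy columns
    (DYS385a/DYS385b); ``"combined"`` keeps one combined-pair locus.
    """
    if dys385 not in ("split", "combined"):
        raise ValidationError(f"dys385 must be 'split' or 'combined': {dys385!r}")
    names: List[str] = []
    for ld in dataset.loci:
        if ld.copy_number == 1:
            names.append(ld.name)
        elif dys385 == "split":
            names.extend(f"{ld.name}{s}" for s in "ab"[: ld.copy_number])
        else:
            names.append(ld.name)
    return tuple(names)


def _locus_states(dataset: PopulationDataset, locus: str) -> List[str]:
    """Per-sample categorical allele state at a (possibly virtual) locus.

    Accepts registered locus names, ``"DYS385"`` (combined sorted pair as
    one state), and per-copy names like ``"DYS385a"``/``"DYS385b"``.
    """
    registered = set(dataset.locus_names)
    if locus in registered:
        ld = dataset.locus(locus)
        out = []
        for rec in dataset.records:
            alleles = sorted(rec.haplotype[locus])
            if ld.copy_number == 1:
                out.append(str(alleles[0]))
            else:
                out.append("-".join(str(a) for a in alleles))
        return out
    base, suffix = locus[:-1], locus[-1]
    if base in registered and suffix in "ab":
        copy = "ab".index(suffix)
        ld = dataset.locus(base)
        if copy < ld.copy_number:
            return [str(sorted(rec.haplotype[base])[copy]) for rec in dataset.records]
    raise ValidationError(f"locus not in panel: {locus!r}")


def two_locus_table(
    dataset: PopulationDataset, locus_a: str, locus_b: str
) -> pd.DataFrame:
    """Joint allele-state contingency table; margins reproduce the
    single-locus counts."""
    a = _locus_states(dataset, locus_a)
    b = _locus_states(dataset, locus_b)
    return pd.crosstab(pd.Series(a, name=locus_a), pd.Series(b, name=locus_b))


def g_statistic(table) -> float:
    """Likelihood-ratio statistic G = 2 * sum O ln(O/E) over cells with O>0."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    if total < 1:
        raise ValidationError("contingency table is empty")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def _g_from_codes(a: np.ndarray, b: np.ndarray, n_a: int, n_b: int) -> float:
    obs = np.bincount(a * n_b + b, minlength=n_a * n_b).astype(float).reshape(n_a, n_b)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    mask = obs > 0
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / expected[mask])))


def ld_pair_test(
    dataset: PopulationDataset,
    locus_a: str,
    locus_b: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> Tuple[float, float, bool]:
    """Permutation G-test for one locus pair.

    Returns ``(G, p, monomorphic)``.  A monomorphic locus carries no
    association information: G = 0 and p = 1 by convention, flagged.
    """
    if n_permutations < 99:
        raise ValidationError("n_permutations must be >= 99")
    # canonical pair order so (A, B) and (B, A) permute the same column
    if locus_a > locus_b:
        locus_a, locus_b = locus_b, locus_a
    sa = _locus_states(dataset, locus_a)
    sb = _locus_states(dataset, locus_b)
    a, cats_a = pd.factorize(np.asarray(sa))
    b, cats_b = pd.factorize(np.asarray(sb))
    if len(cats_a) < 2 or len(cats_b) < 2:
        return 0.0, 1.0, True
    n_a, n_b = len(cats_a), len(cats_b)
    g_obs = _g_from_codes(a, b, n_a, n_b)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_permutations):
        if _g_from_codes(a, rng.permutation(b), n_a, n_b) >= g_obs - 1e-12:
            k += 1
    return g_obs, (k + 1) / (n_permutations + 1), False


@dataclass
class PairTest:
    locus_a: str
    locus_b: str
    g: float
    p: float
    significant: bool
    monomorphic: bool = False


@dataclass
class LDResult:
    """All pairwise LD tests for one panel."""

    pairs: List[PairTest]
    alpha: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_significant(self) -> int:
        return sum(1 for p in self.pairs if p.significant)

    @property
    def fraction_significant(self) -> float:
        return self.n_significant / self.n_pairs if self.pairs else float("nan")

    @property
    def percent_significant(self) -> float:
        """Significant fraction as a percentage, 1 decimal (report style)."""
        return round(100.0 * self.fraction_significant, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_a": p.locus_a,
                    "locus_b": p.locus_b,
                    "G": p.g,
                    "p": p.p,
                    "significant": p.significant,
                    "monomorphic": p.monomorphic,
                }
                for p in self.pairs
            ]
        )


def ld_matrix(
    dataset: PopulationDataset,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    dys385: str = "split",
    loci: Optional[Sequence[str]] = None,
) -> LDResult:
    """Test all C(L, 2) locus pairs at an uncorrected level ``alpha``.

    Each pair gets an independent permutation stream derived from ``seed``.
    """
    names = tuple(loci) if loci is not None else ld_locus_names(dataset, dys385)
    if len(names) < 2:
        raise ValidationError("LD matrix needs >= 2 loci")
    pairs: List[PairTest] = []
    for idx, (la, lb) in enumerate(itertools.combinations(names, 2)):
        pair_seed = (seed * 99991 + idx) % (2**31 - 1)
        g, p, mono = ld_pair_test(dataset, la, lb, n_permutations, pair_seed)
        pairs.append(PairTest(la, lb, g, p, significant=(p < alpha), monomorphic=mono))
    return LDResult(pairs=pairs, alpha=alpha)
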