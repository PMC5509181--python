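"""Pairwise R_ST between populations via one-level AMOVA on squared
repeat-count differences, with permutation significance.

R_ST is the microsatellite analogue of F_ST: the molecular distance between
two haplotypes is the sum over allele copies of squared repeat-count
differences, which under the stepwise mutation model weights distant alleles
by their mutational separation.  A one-level analysis of molecular variance
partitions the total sum of squared distances into among- and within-group
variance components (sigma2_a, sigma2_w); R_ST = sigma2_a / (sigma2_a +
sigma2_w).  Significance comes from permuting population labels over the
pooled samples while preserving group sizes, with the standard add-one
estimator p = (k+1)/(N+1).

Samples carrying null alleles, intermediate (microvariant) alleles, or
copy-number variants have no defined repeat distance and are removed as
whole samples before the analysis (:func:`filter_for_rst`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import Haplotype, LocusDef, PopulationDataset, SampleRecord, ValidationError


@dataclass
class RstConfig:
    """Configuration of an R_ST matrix run."""

    n_permutations: int = 10000
    seed: int = 0
    excluded_loci: Tuple[str, ...] = ()
    alpha: float = 0.05
    #: override the Bonferroni divisor; default m = C(L, 2) from the data
    bonferroni_m: Optional[int] = None
    min_pop_size: int = 2

    def validate(self) -> None:
        if self.n_permutations < 99:
            raise ValidationError("n_permutations must be >= 99")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")


@dataclass
class RstResult:
    """Symmetric pairwise R_ST and permutation P-value matrices."""

    labels: Tuple[str, ...]
    rst: np.ndarray
    pvals: np.ndarray
    n_comparisons: int
    bonferroni_threshold: float
    significant: np.ndarray
    filtered_counts: Dict[str, int]
    config: RstConfig
    warnings: List[str] = field(default_factory=list)

    def pair(self, a: str, b: str) -> Tuple[float, float]:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.rst[i, j]), float(self.pvals[i, j])


def filter_for_rst(
    dataset: PopulationDataset, min_pop_size: int = 2
) -> Tuple[PopulationDataset, List[Tuple[str, str]]]:
    """Remove samples unusable under the repeat-distance model.

    A sample is dropped if it carries any null allele, any intermediate
    (step != 0) allele, or a copy-number variant.  Returns the filtered
    dataset and a log of ``(sample_id, reason)`` pairs.  Raises if any
    population is left with fewer than ``min_pop_size`` samples.
    """
    kept: List[SampleRecord] = []
    log: List[Tuple[str, str]] = []
    for rec in dataset.records:
        if rec.has_null():
            log.append((rec.sample_id, "null"))
        elif rec.has_intermediate():
            log.append((rec.sample_id, "intermediate"))
        elif rec.has_cnv:
            log.append((rec.sample_id, "copy_number_variant"))
        else:
            kept.append(rec)
    if not kept:
        raise ValidationError("no samples survive the R_ST filter")
    out = PopulationDataset(kept, dataset.loci, dict(dataset.provenance))
    out.provenance["rst_filtered"] = len(log)
    for pop, recs in out.by_population().items():
        if len(recs) < min_pop_size:
            raise ValidationError(
                f"population {pop!r} reduced to {len(recs)} sample(s) "
                f"(< {min_pop_size}) by the R_ST filter"
            )
    return out, log


def rst_distance(
    h1: Haplotype, h2: Haplotype, loci: Sequence[LocusDef]
) -> float:
    """Sum of squared repeat differences between two clean haplotypes.

    Multi-copy loci contribute one term per copy, with both tuples sorted
    ascending and matched positionally.
    """
    total = 0.0
    for ld in loci:
        a = sorted(h1[ld.name])
        b = sorted(h2[ld.name])
        if len(a) != len(b):
            raise ValidationError(
                f"locus {ld.name}: allele arity mismatch ({len(a)} vs {len(b)})"
            )
        for x, y in zip(a, b):
            if x.is_null or y.is_null or x.is_intermediate or y.is_intermediate:
                raise ValidationError(
                    f"locus {ld.name}: null/intermediate allele in distance; filter first"
                )
            total += (x.value - y.value) ** 2
    return total


def _squared_distance_matrix(
    records: Sequence[SampleRecord],
    loci: Sequence[LocusDef],
    exclude_loci: Sequence[str] = (),
) -> np.ndarray:
    ds = PopulationDataset(list(records), tuple(loci))
    mat, _ = ds.to_repeat_matrix(exclude_loci)
    return squareform(pdist(mat, metric="sqeuclidean"))


def variance_components(
    dsq: np.ndarray, groups: np.ndarray
) -> Tuple[float, float, bool]:
    """One-level AMOVA variance components from a squared-distance matrix.

    Parameters
    ----------
    dsq:
        (N, N) symmetric matrix of squared molecular distances.
    groups:
        length-N integer group assignment.

    Returns ``(sigma2_among, sigma2_within, degenerate)`` where
    ``degenerate`` flags zero total variance.
    """
    groups = np.asarray(groups)
    n_total = len(groups)
    labels, sizes = np.unique(groups, return_counts=True)
    n_groups = len(labels)
    if n_groups < 2:
        raise ValidationError("AMOVA needs at least two groups")
    if np.any(sizes < 1):
        raise ValidationError("empty group in AMOVA")

    ssd_total = dsq.sum() / (2.0 * n_total)
    ssd_within = 0.0
    for g, size in zip(labels, sizes):
        idx = np.flatnonzero(groups == g)
        ssd_within += dsq[np.ix_(idx, idx)].sum() / (2.0 * size)
    ssd_among = ssd_total - ssd_within

    df_within = n_total - n_groups
    df_among = n_groups - 1
    sigma2_w = ssd_within / df_within if df_within > 0 else 0.0
    n_c = (n_total - (sizes.astype(float) ** 2).sum() / n_total) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_c

    degenerate = ssd_total <= 0.0
    return float(sigma2_a), float(sigma2_w), degenerate


def _rst_from_components(sigma2_a: float, sigma2_w: float, degenerate: bool) -> float:
    if degenerate or (sigma2_a + sigma2_w) == 0.0:
        return 0.0
    return sigma2_a / (sigma2_a + sigma2_w)


def pairwise_rst(
    pop_a: Sequence[SampleRecord],
    pop_b: Sequence[SampleRecord],
    loci: Sequence[LocusDef],
    exclude_loci: Sequence[str] = (),
) -> float:
    """R_ST between two filtered populations (may be slightly negative).

    Returns 0.0 (with no among-group signal) when the pooled sample has
    zero molecular variance.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValidationError("pairwise R_ST needs >= 2 samples per population")
    records = list(pop_a) + list(pop_b)
    dsq = _squared_distance_matrix(records, loci, exclude_loci)
    groups = np.array([0] * len(pop_a) + [1] * len(pop_b))
    return _rst_from_components(*variance_components(dsq, groups))


def _rst_two_groups(dsq: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                    total_pair_sum: float, n_c: float, df_w: int) -> float:
    """Fast two-group R_ST given precomputed constants (permutation core)."""
    n_a, n_b = len(idx_a), len(idx_b)
    within_a = dsq[np.ix_(idx_a, idx_a)].sum() / (2.0 * n_a)
    within_b = dsq[np.ix_(idx_b, idx_b)].sum() / (2.0 * n_b)
    ssd_within = within_a + within_b
    ssd_total = total_pair_sum
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / df_w
    sigma2_a = (ssd_among - sigma2_w) / n_c  # df_among = 1
    if ssd_total <= 0.0 or (sigma2_a + sigma2_w) == 0.0:
        return 0.0
    return sigma2_a / (sigma2_a + sigma2_w)


def permutation_p(
    pop_a: Sequence[SampleRecord],
    pop_b: Sequence[SampleRecord],
    loci: Sequence[LocusDef],
    n_permutations: int = 10000,
    seed: int = 0,
    exclude_loci: Sequence[str] = (),
) -> Tuple[float, float]:
    """Permutation P-value for the observed pairwise R_ST.

    Population labels are permuted over the pooled samples ``n_permutations``
    times preserving group sizes; p = (k+1)/(N+1) with k the number of
    permutations whose R_ST is >= the observed value.  Returns
    ``(rst_observed, p)``.
    """
    if n_permutations < 99:
        raise ValidationError("n_permutations must be >= 99")
    records = list(pop_a) + list(pop_b)
    dsq = _squared_distance_matrix(records, loci, exclude_loci)
    n_a, n_b = len(pop_a), len(pop_b)
    rst_obs, p = _permutation_p_from_matrix(dsq, n_a, n_b, n_permutations, seed)
    return rst_obs, p


def _permutation_p_from_matrix(
    dsq: np.ndarray, n_a: int, n_b: int, n_permutations: int, seed: int
) -> Tuple[float, float]:
    n_total = n_a + n_b
    total_pair_sum = dsq.sum() / (2.0 * n_total)
    df_w = n_total - 2
    n_c = (n_total - (n_a * n_a + n_b * n_b) / n_total)  # / df_among(=1)
    idx = np.arange(n_total)
    rst_obs = _rst_two_groups(dsq, idx[:n_a], idx[n_a:], total_pair_sum, n_c, df_w)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n_total)
        r = _rst_two_groups(dsq, perm[:n_a], perm[n_a:], total_pair_sum, n_c, df_w)
        if r >= rst_obs - 1e-15:
            k += 1
    return rst_obs, (k + 1) / (n_permutations + 1)


def bonferroni_threshold(n_populations: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / C(L, 2) for an L-population matrix."""
    m = math.comb(n_populations, 2)
    if m < 1:
        raise ValidationError("need at least two populations")
    return alpha / m


def rst_matrix(
    dataset: PopulationDataset,
    config: Optional[RstConfig] = None,
    prefiltered: bool = False,
) -> RstResult:
    """All pairwise R_ST values and permutation P-values for a dataset.

    The dataset is passed through :func:`filter_for_rst` first unless
    ``prefiltered``.  Each unordered population pair gets an independent
    permutation stream derived from ``config.seed``.
    """
    config = config or RstConfig()
    config.validate()
    filtered_counts: Dict[str, int] = {}
    if prefiltered:
        clean = dataset
    else:
        before = {p: len(r) for p, r in dataset.by_population().items()}
        clean, _log = filter_for_rst(dataset, config.min_pop_size)
        after = {p: len(r) for p, r in clean.by_population().items()}
        filtered_counts = {p: before[p] - after.get(p, 0) for p in before}
    groups = clean.by_population()
    labels = clean.populations()
    n_pops = len(labels)
    if n_pops < 2:
        raise ValidationError("R_ST matrix needs >= 2 populations after filtering")

    rst = np.zeros((n_pops, n_pops))
    pvals = np.ones((n_pops, n_pops))
    warnings: List[str] = []
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            pair_seed = (config.seed * 100003 + i * 1009 + j) % (2**31 - 1)
            try:
                r, p = permutation_p(
                    groups[labels[i]],
                    groups[labels[j]],
                    clean.loci,
                    config.n_permutations,
                    pair_seed,
                    config.excluded_loci,
                )
            except ValidationError as exc:
                raise ValidationError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
            if r == 0.0 and p == 1.0:
                warnings.append(f"pair ({labels[i]}, {labels[j]}): degenerate or null signal")
            rst[i, j] = rst[j, i] = r
            pvals[i, j] = pvals[j, i] = p
    m = config.bonferroni_m if config.bonferroni_m is not None else math.comb(n_pops, 2)
    threshold = config.alpha / m
    significant = (pvals < threshold) & ~np.eye(n_pops, dtype=bool)
    return RstResult(
        labels=labels,
        rst=rst,
        pvals=pvals,
        n_comparisons=math.comb(n_pops, 2),
        bonferroni_threshold=threshold,
        significant=significant,
        filtered_counts=filtered_counts,
        config=config,
        warnings=warnings,
    )


def format_rst_table(result: RstResult, digits: int = 4) -> str:
    """Lower triangle = R_ST, upper triangle = permutation P (report layout)."""
    labels = result.labels
    rows = ["\t".join(["", *labels])]
    for i, lab in enumerate(labels):
        cells = [lab]
        for j in range(len(labels)):
            if i == j:
                cells.append("#")
            elif i > j:
                cells.append(f"{result.rst[i, j]:.{digits}f}")
            else:
                cells.append(f"{result.pvals[i, j]:.{digits}f}")
        rows.append("\t".join(cells))
    return "\n".join(rows) + "\n"


def write_phylip_matrix(labels: Sequence[str], d: np.ndarray, path) -> None:
    """PHYLIP-style square distance matrix (for external tree/MDS tools)."""
    from pathlib import Path

    lines = [f"{len(labels)}"]
    for lab, row in zip(labels, np.asarray(d)):
        name = lab.replace(" ", "_")[:10].ljust(10)
        lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
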