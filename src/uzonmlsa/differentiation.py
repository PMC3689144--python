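"""Pairwise F_ST from sequence differences, and isolation by distance.

F_ST is estimated by haplotypic AMOVA (the Arlequin default for sequence
data): pairwise nucleotide difference counts are treated as squared
distances, sums of squared deviations are computed from the distance
matrix,

    SSD_total  = (1/N)  sum_{i<j} d_ij
    SSD_within = sum_g (1/n_g) sum_{i<j in g} d_ij
    SSD_among  = SSD_total - SSD_within

and variance components follow from the expected mean squares with
average subsample size n' = (N - sum n_g^2 / N)/(P-1):

    sigma2_w = SSD_within / (N - P)
    sigma2_a = (SSD_among/(P-1) - sigma2_w) / n'
    F_ST     = sigma2_a / (sigma2_a + sigma2_w)

Negative estimates are reported as computed (they arise when between-group
distances are no larger than within-group ones). For balanced two-deme
designs this estimator reduces exactly to (pi_b - pi_w)/pi_b, the classical
mean-pairwise-distance form.

Significance is by permutation: individuals are randomly reassigned
between the two subpopulations (sizes preserved) and the observed F_ST is
compared with the permuted distribution (add-one estimator).

Isolation by distance uses a Mantel-type permutation test on Spearman's
rank correlation between a genetic and a geographic distance matrix.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import DistanceMatrix

logger = logging.getLogger("uzonmlsa")


@dataclass
class FstResult:
    subset_a: str
    subset_b: str
    fst: float
    p_value: Optional[float] = None
    permutations: int = 0
    seed: Optional[int] = None


@dataclass
class MantelResult:
    rho: float
    significance_percent: Optional[float]
    permutations: int
    seed: Optional[int] = None


def pairwise_nt_differences(
    sequences: Mapping[str, str], p_distance: bool = False
) -> DistanceMatrix:
    """Pairwise difference counts (or p-distances) between aligned sequences.

    Positions where either sequence has missing data ('N', '-') are excluded
    pair by pair; with ``p_distance`` each count is divided by the number of
    compared sites.
    """
    labels = list(sequences)
    seqs = [sequences[k].upper() for k in labels]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("sequences must have equal length")
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), -1)
    missing = np.isin(mat, (b"N", b"-"))
    n = len(labels)
    condensed = np.empty(n * (n - 1) // 2, dtype=float)
    for idx, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        comparable = ~missing[i] & ~missing[j]
        diff = float(np.sum(mat[i, comparable] != mat[j, comparable]))
        if p_distance:
            n_sites = int(comparable.sum())
            if n_sites == 0:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) has no comparable sites"
                )
            diff /= n_sites
        condensed[idx] = diff
    return DistanceMatrix(labels, condensed)


def _ssd(square: np.ndarray, idx: Sequence[int]) -> float:
    sub = square[np.ix_(idx, idx)]
    return float(sub.sum() / 2.0 / len(idx))


def _amova_fst(square: np.ndarray, groups: Sequence[Sequence[int]]) -> float:
    sizes = np.array([len(g) for g in groups], dtype=float)
    n_total = int(sizes.sum())
    n_pops = len(groups)
    ssd_within = sum(_ssd(square, g) for g in groups)
    ssd_total = _ssd(square, [i for g in groups for i in g])
    ssd_among = ssd_total - ssd_within
    sigma2_w = ssd_within / (n_total - n_pops)
    n_prime = (n_total - float(np.sum(sizes**2)) / n_total) / (n_pops - 1)
    sigma2_a = (ssd_among / (n_pops - 1) - sigma2_w) / n_prime
    denom = sigma2_a + sigma2_w
    if denom == 0.0:
        return 0.0  # no variation at all: conventionally no differentiation
    return sigma2_a / denom


def pairwise_fst(
    distances: DistanceMatrix,
    partition: Mapping[str, str],
    subset_a: str,
    subset_b: str,
) -> float:
    """AMOVA F_ST between two subpopulations of a labelled distance matrix.

    ``partition`` maps each sample label to its subpopulation label.
    Returns NaN when either subset has fewer than two members.
    """
    idx_a = [i for i, lab in enumerate(distances.labels) if partition.get(lab) == subset_a]
    idx_b = [i for i, lab in enumerate(distances.labels) if partition.get(lab) == subset_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        return float("nan")
    return _amova_fst(distances.square(), [idx_a, idx_b])


def fst_significance(
    distances: DistanceMatrix,
    partition: Mapping[str, str],
    permutations: int = 1000,
    seed: Optional[int] = None,
) -> list[FstResult]:
    """Pairwise F_ST with permutation P for every subpopulation pair.

    The null reassigns individuals at random between the two subsets
    (sizes preserved); P = (#{F_perm >= F_obs} + 1)/(permutations + 1).
    """
    if permutations < 100:
        raise ValueError("use >= 100 permutations")
    rng = np.random.default_rng(seed)
    square = distances.square()
    subsets = sorted(set(partition.values()))
    results = []
    for a, b in itertools.combinations(subsets, 2):
        idx_a = [i for i, lab in enumerate(distances.labels) if partition.get(lab) == a]
        idx_b = [i for i, lab in enumerate(distances.labels) if partition.get(lab) == b]
        if len(idx_a) < 2 or len(idx_b) < 2:
            results.append(FstResult(a, b, float("nan"), None, permutations, seed))
            continue
        f_obs = _amova_fst(square, [idx_a, idx_b])
        pooled = np.array(idx_a + idx_b)
        n_a = len(idx_a)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(pooled)
            f_perm = _amova_fst(square, [perm[:n_a], perm[n_a:]])
            if f_perm >= f_obs:
                hits += 1
        p = (hits + 1) / (permutations + 1)
        results.append(FstResult(a, b, f_obs, p, permutations, seed))
    return results


def fst_table(results: Sequence[FstResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subset_a": r.subset_a,
                "subset_b": r.subset_b,
                "F_ST": r.fst,
                "P": np.nan if r.p_value is None else r.p_value,
                "permutations": r.permutations,
            }
            for r in results
        ]
    )


def mantel_spearman(
    genetic: DistanceMatrix,
    geographic: DistanceMatrix,
    permutations: int = 999,
    seed: Optional[int] = None,
) -> MantelResult:
    """Mantel-type permutation test on Spearman's rho between two matrices.

    Labels must match in order. The significance level is the percentage of
    row/column label permutations of the geographic matrix whose rho is >=
    the observed one (add-one corrected), matching the convention of
    ecological RELATE-style tests. A constant matrix has undefined rho:
    NaN is returned with a warning.
    """
    if genetic.labels != geographic.labels:
        raise ValueError("distance matrices must have identical labels in order")
    n = len(genetic.labels)
    if n < 4:
        raise ValueError("Mantel test needs >= 4 samples")
    x = genetic.condensed
    y = geographic.condensed
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("constant distance matrix: Spearman's rho undefined")
        return MantelResult(float("nan"), None, permutations, seed)
    rho_obs = float(spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    sq_y = geographic.square()
    hits = 0
    for _ in range(permutations):
        order = rng.permutation(n)
        perm = sq_y[np.ix_(order, order)]
        y_perm = perm[np.triu_indices(n, k=1)]
        if float(spearmanr(x, y_perm).statistic) >= rho_obs:
            hits += 1
    significance = 100.0 * (hits + 1) / (permutations + 1)
    return MantelResult(rho_obs, significance, permutations, seed)
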