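"""Allele frequencies and unbiased genetic diversity H.

H is the probability that two isolates sampled without replacement carry
different alleles at a locus: H = (n/(n-1)) * (1 - sum(p_i^2)). The n/(n-1)
factor makes the estimator unbiased; it is the convention used by the LIAN
family of clonality tests and by standard MLST practice.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import IsolateTable


def allele_frequencies(
    table: IsolateTable,
    locus: str,
    st_mode: bool = False,
) -> pd.Series:
    """Allele relative frequencies at one locus, over isolates.

    With ``st_mode`` the frequencies are computed over distinct sequence
    types instead (each ST counted once), the deduplicated view used when
    clonal resampling should not weight the counts.
    """
    if len(table) == 0:
        raise ValueError("empty isolate set")
    j = table.locus_index(locus)
    profiles = table.profiles_array()
    if st_mode:
        profiles = np.unique(profiles, axis=0)
    col = profiles[:, j]
    values, counts = np.unique(col, return_counts=True)
    freqs = pd.Series(counts / counts.sum(), index=values, name=locus)
    freqs.index.name = "allele"
    return freqs


def genetic_diversity_h(frequencies: Sequence[float], n: int) -> float:
    """Unbiased genetic diversity H = (n/(n-1)) * (1 - sum p_i^2).

    Returns NaN for n < 2 (undefined). Clamped to [0, 1].
    """
    if n < 2:
        return float("nan")
    p = np.asarray(frequencies, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"frequencies sum to {p.sum()}, expected 1")
    h = (n / (n - 1)) * (1.0 - float(np.sum(p**2)))
    return float(min(max(h, 0.0), 1.0))


def locus_h(table: IsolateTable, locus: str, st_mode: bool = False) -> float:
    """Convenience: H at one locus for an isolate (or deduplicated ST) set."""
    freqs = allele_frequencies(table, locus, st_mode=st_mode)
    n = len(np.unique(table.profiles_array(), axis=0)) if st_mode else len(table)
    return genetic_diversity_h(freqs.to_numpy(), n)


def diversity_summary(
    table: IsolateTable,
    group_by: Optional[Sequence[str]] = None,
    st_mode: bool = False,
) -> pd.DataFrame:
    """Per-(subset, locus) diversity table plus a mean-H row per subset.

    ``group_by`` may name isolate attributes ('spring', 'year'); None
    analyses the whole table as one subset labelled 'all'. The mean-H row
    (locus = 'mean') is the unweighted mean of H over loci.
    """
    if group_by:
        groups = {
            "/".join(str(k) for k in key): sub
            for key, sub in table.groups(tuple(group_by)).items()
        }
    else:
        groups = {"all": table}

    rows = []
    for label, sub in groups.items():
        hs = []
        profiles = sub.profiles_array()
        n = len(np.unique(profiles, axis=0)) if st_mode else len(sub)
        for locus in sub.locus_names:
            freqs = allele_frequencies(sub, locus, st_mode=st_mode)
            h = genetic_diversity_h(freqs.to_numpy(), n)
            hs.append(h)
            rows.append(
                {"subset": label, "locus": locus, "n": n, "n_a": len(freqs), "H": h}
            )
        rows.append(
            {
                "subset": label,
                "locus": "mean",
                "n": n,
                "n_a": np.nan,
                "H": float(np.mean(hs)),
            }
        )
    return pd.DataFrame(rows)
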