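"""Single-locus-variant (SLV) analysis: recombination vs mutation calls.

Two sequence types are SLVs when their allelic profiles differ at exactly
one locus. Each SLV pair is classified by the nucleotide distance between
the two alleles at the variant locus and by how widely those alleles are
shared across sequence types:

* R (recombination): the alleles differ by more than one nucleotide -- a
  multi-site difference is unlikely to arise as a single point mutation --
  OR they differ by one nucleotide but *both* alleles occur in two or more
  distinct STs, i.e. the putative variant is seen repeatedly in unrelated
  backgrounds.
* M (point mutation): a single-nucleotide difference where at least one of
  the two alleles is confined to a single ST (the putative novel variant).
* UNKNOWN: the nucleotide distance between the alleles is unavailable.

"Occurs multiple times" is evaluated at the ST level, not the isolate
level: an allele carried by one ST of many isolates still counts once, so
clonal oversampling cannot promote a mutation call to recombination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import AlleleCatalog, SequenceTypeTable

logger = logging.getLogger("uzonmlsa")

CALL_RECOMBINATION = "R"
CALL_MUTATION = "M"
CALL_UNKNOWN = "UNKNOWN"


@dataclass
class SLVRecord:
    st_a: int
    st_b: int
    variant_locus: str
    allele_a: int
    allele_b: int
    same_spring: bool
    nt_diff: Optional[int] = None
    call: str = CALL_UNKNOWN


def find_slvs(st_table: SequenceTypeTable) -> list[SLVRecord]:
    """All unordered ST pairs whose profiles differ at exactly one locus.

    ``same_spring`` is True when the two STs' spring provenance sets
    intersect. Calls are left pending (UNKNOWN).
    """
    if len(st_table) < 2:
        raise ValueError("need >= 2 sequence types")
    profiles = st_table.profiles_array()
    records: list[SLVRecord] = []
    types = st_table.types
    for i in range(len(types)):
        diffs = profiles[i + 1 :] != profiles[i]
        for off in np.nonzero(diffs.sum(axis=1) == 1)[0]:
            j = i + 1 + off
            locus_pos = int(np.nonzero(diffs[off])[0][0])
            a, b = types[i], types[j]
            st_lo, st_hi = (a, b) if a.st <= b.st else (b, a)
            records.append(
                SLVRecord(
                    st_a=st_lo.st,
                    st_b=st_hi.st,
                    variant_locus=st_table.locus_names[locus_pos],
                    allele_a=st_lo.profile[locus_pos],
                    allele_b=st_hi.profile[locus_pos],
                    same_spring=bool(a.springs & b.springs),
                )
            )
    records.sort(key=lambda r: (r.st_a, r.st_b))
    return records


def allele_nt_distance(catalog: AlleleCatalog, allele_a: int, allele_b: int) -> Optional[int]:
    """Nucleotide distance between two alleles, or None when unavailable.

    Computed from sequences (Hamming over non-missing columns) when the
    catalog has them, otherwise looked up in its sparse distance table.
    """
    d = catalog.distance(allele_a, allele_b)
    if allele_a != allele_b and d == 0:
        logger.warning(
            "%s: alleles %d and %d have identical sequences under distinct indices",
            catalog.locus.name,
            allele_a,
            allele_b,
        )
    return d


def classify_slv(record: SLVRecord, st_table: SequenceTypeTable) -> str:
    """Apply the mutation/recombination rule to one SLV record."""
    if record.nt_diff is None:
        return CALL_UNKNOWN
    if record.nt_diff > 1:
        return CALL_RECOMBINATION
    pos = st_table.locus_names.index(record.variant_locus)
    occ = st_table.allele_st_occurrences(pos)
    if occ.get(record.allele_a, 0) >= 2 and occ.get(record.allele_b, 0) >= 2:
        return CALL_RECOMBINATION
    return CALL_MUTATION


def slv_report(
    st_table: SequenceTypeTable,
    catalogs: Mapping[str, AlleleCatalog],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full SLV table (sorted by ST pair) and the R/M/UNKNOWN tallies.

    ``catalogs`` maps locus name -> AlleleCatalog; loci absent from the
    mapping yield UNKNOWN calls.
    """
    records = find_slvs(st_table) if len(st_table) >= 2 else []
    rows = []
    tallies = {CALL_RECOMBINATION: 0, CALL_MUTATION: 0, CALL_UNKNOWN: 0}
    for rec in records:
        cat = catalogs.get(rec.variant_locus)
        rec.nt_diff = (
            allele_nt_distance(cat, rec.allele_a, rec.allele_b) if cat else None
        )
        rec.call = classify_slv(rec, st_table)
        tallies[rec.call] += 1
        rows.append(
            {
                "st_a": rec.st_a,
                "st_b": rec.st_b,
                "variant_locus": rec.variant_locus,
                "allele_a": rec.allele_a,
                "allele_b": rec.allele_b,
                "nt_diff": np.nan if rec.nt_diff is None else rec.nt_diff,
                "same_spring": rec.same_spring,
                "call": rec.call,
            }
        )
    columns = [
        "st_a",
        "st_b",
        "variant_locus",
        "allele_a",
        "allele_b",
        "nt_diff",
        "same_spring",
        "call",
    ]
    return pd.DataFrame(rows, columns=columns), tallies
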