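"""Allele calling, sequence typing and per-locus heterogeneity statistics.

Alleles are defined by exact string identity of the aligned fragment: two
sequences are the same allele iff they are the same string. Missing data
('N', '-') therefore never merges alleles; ambiguity is assumed to have
been resolved upstream (re-sequencing). The diversity statistics, in
contrast, treat 'N' and '-' as missing and use pairwise deletion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .model import AlleleCatalog, IsolateTable, Locus, SequenceType, SequenceTypeTable

_MISSING = (b"N", b"-")


def _char_matrix(sequences: Sequence[str]) -> np.ndarray:
    """(n, L) matrix of single-byte characters."""
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"sequences must have equal length, got lengths {sorted(lengths)}")
    return np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(
        len(sequences), -1
    )


def call_alleles(
    sequences: Mapping[str, str] | Sequence[str], locus: Locus
) -> tuple[AlleleCatalog, list[int]]:
    """Assign a dense 1-based allele index to each distinct sequence.

    Indices follow order of first appearance in the input. Returns the
    catalog and the per-input allele index (input order preserved).
    """
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if not seqs:
        raise ValueError(f"{locus.name}: no sequences to call alleles from")
    catalog: dict[str, int] = {}
    calls: list[int] = []
    for seq in seqs:
        seq = seq.upper()
        if len(seq) != locus.aligned_length:
            raise ValueError(
                f"{locus.name}: sequence length {len(seq)} != aligned_length "
                f"{locus.aligned_length}"
            )
        if seq not in catalog:
            catalog[seq] = len(catalog) + 1
        calls.append(catalog[seq])
    return AlleleCatalog(locus, sequences={i: s for s, i in catalog.items()}), calls


def assign_sequence_types(table: IsolateTable) -> SequenceTypeTable:
    """Group isolates by exact allelic-profile equality into sequence types.

    STs are numbered 1..k by order of first appearance.
    """
    types: dict[tuple[int, ...], SequenceType] = {}
    for iso in table.isolates:
        if iso.profile not in types:
            types[iso.profile] = SequenceType(len(types) + 1, iso.profile)
        types[iso.profile].members.append((iso.id, iso.spring, iso.year))
    return SequenceTypeTable(table.loci, list(types.values()))


def variable_sites(sequences: Sequence[str]) -> int:
    """Number of alignment columns with >= 2 distinct non-missing characters (S)."""
    mat = _char_matrix([s.upper() for s in sequences])
    missing = np.isin(mat, _MISSING)
    s = 0
    for col, miss in zip(mat.T, missing.T):
        observed = np.unique(col[~miss])
        if observed.size >= 2:
            s += 1
    return s


def nucleotide_diversity(sequences: Sequence[str]) -> float:
    """Average pairwise p-distance, Pi (per site, pairwise deletion).

    Mean over all unordered sequence pairs of (#differences / #comparable
    sites). A pair with zero comparable sites is an error.
    """
    seqs = [s.upper() for s in sequences]
    if len(seqs) < 2:
        raise ValueError("nucleotide diversity needs >= 2 sequences")
    mat = _char_matrix(seqs)
    missing = np.isin(mat, _MISSING)
    total = 0.0
    n = len(seqs)
    for i, j in itertools.combinations(range(n), 2):
        comparable = ~missing[i] & ~missing[j]
        n_sites = int(comparable.sum())
        if n_sites == 0:
            raise ValueError(f"sequence pair ({i}, {j}) has no comparable sites")
        total += np.sum(mat[i, comparable] != mat[j, comparable]) / n_sites
    return total / (n * (n - 1) / 2)


def translate(seq: str, frame_offset: int = 0, genetic_code_id: int = 11) -> str:
    """Translate an aligned nucleotide string codon by codon.

    The trailing partial codon is dropped; any codon containing a character
    outside {A,C,G,T} translates to the missing residue 'X'. Stop codons
    become '*'.
    """
    try:
        table = CodonTable.unambiguous_dna_by_id[genetic_code_id]
    except KeyError:
        raise ValueError(f"unknown genetic code id: {genetic_code_id}") from None
    seq = seq.upper()[frame_offset:]
    residues = []
    for k in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[k : k + 3]
        if set(codon) - set("ACGT"):
            residues.append("X")
        elif codon in table.stop_codons:
            residues.append("*")
        else:
            residues.append(table.forward_table[codon])
    return "".join(residues)


def variable_amino_acids(
    sequences: Sequence[str], frame_offset: int = 0, genetic_code_id: int = 11
) -> int:
    """Count variable residue columns in the translated alignment.

    'X' (codon containing missing/ambiguous nucleotides) is treated as
    missing, with the same column rule as :func:`variable_sites`.
    """
    if sequences and len(sequences[0]) - frame_offset < 3:
        raise ValueError("alignment too short to contain a complete codon")
    proteins = [translate(s, frame_offset, genetic_code_id) for s in sequences]
    mat = _char_matrix(proteins)
    missing = mat == b"X"
    count = 0
    for col, miss in zip(mat.T, missing.T):
        if np.unique(col[~miss]).size >= 2:
            count += 1
    return count


def concatenate_loci(
    table: IsolateTable, catalogs: Mapping[str, AlleleCatalog]
) -> dict[str, str]:
    """Per-isolate concatenated sequence, in the table's locus order."""
    out: dict[str, str] = {}
    for iso in table.isolates:
        parts = []
        for locus, allele in zip(table.loci, iso.profile):
            cat = catalogs.get(locus.name)
            if cat is None or allele not in cat.sequences:
                raise KeyError(
                    f"no sequence for locus {locus.name} allele {allele} "
                    f"(isolate {iso.id})"
                )
            parts.append(cat.sequences[allele])
        out[iso.id] = "".join(parts)
    return out


@dataclass
class LocusSummary:
    locus: str
    aligned_length: int
    n_a: int
    s: int
    pi_per_100: float
    variable_aa: int


def locus_summary(
    alignments: Mapping[str, Mapping[str, str]],
    loci: Sequence[Locus],
) -> pd.DataFrame:
    """Per-locus heterogeneity table: n_a, S, Pi per 100 sites, variable aa.

    ``alignments`` maps locus name -> (isolate id -> aligned sequence).
    """
    rows = []
    for locus in loci:
        seqs = list(alignments[locus.name].values())
        _, calls = call_alleles(seqs, locus)
        rows.append(
            LocusSummary(
                locus=locus.name,
                aligned_length=locus.aligned_length,
                n_a=max(calls),
                s=variable_sites(seqs),
                pi_per_100=100.0 * nucleotide_diversity(seqs),
                variable_aa=variable_amino_acids(
                    seqs, locus.frame_offset, locus.genetic_code_id
                ),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
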