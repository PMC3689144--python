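"""Core data model for multilocus sequence analysis (MLSA) datasets.

The central objects mirror how MLST/MLSA studies organise their data:
per-locus allele catalogs (allele index -> aligned sequence), isolates
carrying an allelic profile (one allele index per locus), and sequence
types (STs) -- the distinct allelic profiles observed in the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Characters accepted in aligned nucleotide sequences. '-' and 'N' are
#: treated as missing data by the diversity statistics (pairwise deletion);
#: they still participate in exact-string allele identity.
ALLOWED_CHARS = frozenset("ACGTN-")

#: Sentinel for an unknown sampling year (e.g. provenance that a published
#: table only resolves to "either year").
YEAR_UNKNOWN = 0


def hamming_distance(seq_a: str, seq_b: str) -> int:
    """Number of differing positions, ignoring columns where either
    sequence has missing data ('N' or '-')."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    missing = np.isin(a, (b"N", b"-")) | np.isin(b, (b"N", b"-"))
    return int(np.sum((a != b) & ~missing))


@dataclass(frozen=True)
class Locus:
    """A sequenced gene fragment.

    frame_offset is the 0-based position of the first complete codon and
    genetic_code_id the NCBI translation table (11 = bacterial).
    """

    name: str
    aligned_length: int
    frame_offset: int = 0
    genetic_code_id: int = 11

    def __post_init__(self) -> None:
        if self.aligned_length <= 0:
            raise ValueError(f"locus {self.name}: aligned_length must be > 0")
        if not 0 <= self.frame_offset < 3:
            raise ValueError(f"locus {self.name}: frame_offset must be in {{0,1,2}}")


class AlleleCatalog:
    """Registry of the distinct alleles observed at one locus.

    Allele indices are dense and 1-based (MLST convention). Sequences are
    optional: a catalog may instead (or additionally) carry a sparse table
    of nucleotide distances between allele pairs, as published SLV tables
    provide when the raw sequences are not bundled.
    """

    def __init__(
        self,
        locus: Locus,
        sequences: Optional[Mapping[int, str]] = None,
        distance_table: Optional[Mapping[tuple[int, int], int]] = None,
    ):
        self.locus = locus
        self.sequences: dict[int, str] = dict(sequences or {})
        self._distances: dict[tuple[int, int], int] = {}
        if self.sequences:
            idx = sorted(self.sequences)
            if idx != list(range(1, len(idx) + 1)):
                raise ValueError(f"{locus.name}: allele indices must be dense 1..n_a, got {idx}")
            for i, seq in self.sequences.items():
                if len(seq) != locus.aligned_length:
                    raise ValueError(
                        f"{locus.name} allele {i}: length {len(seq)} != locus length "
                        f"{locus.aligned_length}"
                    )
            seqs = list(self.sequences.values())
            if len(set(seqs)) != len(seqs):
                raise ValueError(f"{locus.name}: allele sequences must be pairwise distinct")
        if distance_table:
            for (a, b), d in distance_table.items():
                if d < 0:
                    raise ValueError("negative allele distance")
                self._distances[(min(a, b), max(a, b))] = int(d)
            self._check_distance_consistency()

    def _check_distance_consistency(self) -> None:
        for (a, b), d in self._distances.items():
            if a in self.sequences and b in self.sequences:
                h = hamming_distance(self.sequences[a], self.sequences[b])
                if h != d:
                    raise ValueError(
                        f"{self.locus.name}: distance table says d({a},{b})={d} "
                        f"but sequences differ at {h} sites"
                    )

    @property
    def n_alleles(self) -> int:
        if self.sequences:
            return len(self.sequences)
        seen = {i for pair in self._distances for i in pair}
        return len(seen)

    def sequence(self, index: int) -> str:
        try:
            return self.sequences[index]
        except KeyError:
            raise KeyError(f"{self.locus.name}: no sequence for allele {index}") from None

    def distance(self, a: int, b: int) -> Optional[int]:
        """Nucleotide distance between two alleles, or None if unknown.

        Sequences take precedence; a sparse distance table is the fallback.
        """
        if a == b:
            return 0
        if a in self.sequences and b in self.sequences:
            return hamming_distance(self.sequences[a], self.sequences[b])
        return self._distances.get((min(a, b), max(a, b)))

    def distance_entries(self) -> dict[tuple[int, int], int]:
        return dict(self._distances)


@dataclass(frozen=True)
class Isolate:
    id: str
    spring: str
    year: int
    profile: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(a < 1 for a in self.profile):
            raise ValueError(f"isolate {self.id}: allele indices must be >= 1")


class IsolateTable:
    """Isolates with subpopulation labels and fixed-order allelic profiles."""

    def __init__(self, loci: Sequence[Locus], isolates: Iterable[Isolate]):
        self.loci: list[Locus] = list(loci)
        self.isolates: list[Isolate] = list(isolates)
        ids = [iso.id for iso in self.isolates]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate isolate id: {dup}")
        l = len(self.loci)
        for iso in self.isolates:
            if len(iso.profile) != l:
                raise ValueError(
                    f"isolate {iso.id}: profile length {len(iso.profile)} != {l} loci"
                )

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def __len__(self) -> int:
        return len(self.isolates)

    def locus_index(self, name: str) -> int:
        try:
            return self.locus_names.index(name)
        except ValueError:
            raise KeyError(f"unknown locus: {name}") from None

    def profiles_array(self) -> np.ndarray:
        """(n_isolates, n_loci) integer matrix of allele indices."""
        return np.array([iso.profile for iso in self.isolates], dtype=np.int64)

    def subset(self, spring: Optional[str] = None, year: Optional[int] = None) -> "IsolateTable":
        kept = [
            iso
            for iso in self.isolates
            if (spring is None or iso.spring == spring) and (year is None or iso.year == year)
        ]
        return IsolateTable(self.loci, kept)

    def groups(self, by: Sequence[str] = ("spring",)) -> dict[tuple, "IsolateTable"]:
        """Partition into subpopulations by ('spring',), ('year',) or both."""
        out: dict[tuple, list[Isolate]] = {}
        for iso in self.isolates:
            key = tuple(getattr(iso, attr) for attr in by)
            out.setdefault(key, []).append(iso)
        return {k: IsolateTable(self.loci, v) for k, v in sorted(out.items(), key=lambda kv: str(kv[0]))}


@dataclass
class SequenceType:
    st: int
    profile: tuple[int, ...]
    #: (isolate id, spring, year) for every member isolate
    members: list[tuple[str, str, int]] = field(default_factory=list)

    @property
    def isolate_ids(self) -> list[str]:
        return [m[0] for m in self.members]

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def provenance(self) -> set[tuple[str, int]]:
        return {(s, y) for _, s, y in self.members}

    @property
    def springs(self) -> set[str]:
        return {s for _, s, _ in self.members}


class SequenceTypeTable:
    """The distinct allelic profiles (sequence types) of an isolate set."""

    def __init__(self, loci: Sequence[Locus], types: Iterable[SequenceType]):
        self.loci = list(loci)
        self.types: list[SequenceType] = list(types)
        profiles = [t.profile for t in self.types]
        if len(set(profiles)) != len(profiles):
            raise ValueError("sequence type profiles must be pairwise distinct")

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def __len__(self) -> int:
        return len(self.types)

    def __iter__(self):
        return iter(self.types)

    def by_st(self, st: int) -> SequenceType:
        for t in self.types:
            if t.st == st:
                return t
        raise KeyError(f"no sequence type {st}")

    def total_isolates(self) -> int:
        return sum(t.count for t in self.types)

    def profiles_array(self) -> np.ndarray:
        return np.array([t.profile for t in self.types], dtype=np.int64)

    def allele_st_occurrences(self, locus_pos: int) -> dict[int, int]:
        """For one locus: allele index -> number of distinct STs carrying it."""
        occ: dict[int, int] = {}
        for t in self.types:
            a = t.profile[locus_pos]
            occ[a] = occ.get(a, 0) + 1
        return occ

    def expand(self) -> IsolateTable:
        """Inverse of ST grouping: one isolate per recorded member."""
        isolates = [
            Isolate(iso_id, spring, year, t.profile)
            for t in self.types
            for iso_id, spring, year in t.members
        ]
        return IsolateTable(self.loci, isolates)


class DistanceMatrix:
    """Labelled symmetric distance matrix stored in condensed form."""

    def __init__(self, labels: Sequence[str], condensed: np.ndarray):
        self.labels = list(labels)
        n = len(self.labels)
        condensed = np.asarray(condensed, dtype=float)
        if condensed.shape != (n * (n - 1) // 2,):
            raise ValueError(
                f"condensed vector has length {condensed.size}, expected C({n},2)"
            )
        if np.any(condensed < 0):
            raise ValueError("distances must be non-negative")
        self.condensed = condensed

    def __len__(self) -> int:
        return len(self.labels)

    def _pair_index(self, i: int, j: int) -> int:
        if i > j:
            i, j = j, i
        n = len(self.labels)
        return n * i - i * (i + 1) // 2 + (j - i - 1)

    def get(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        if i == j:
            return 0.0
        return float(self.condensed[self._pair_index(i, j)])

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(self.condensed)

    def submatrix(self, indices: Sequence[int]) -> "DistanceMatrix":
        sq = self.square()[np.ix_(indices, indices)]
        from scipy.spatial.distance import squareform

        return DistanceMatrix(
            [self.labels[i] for i in indices], squareform(sq, checks=False)
        )

    @classmethod
    def from_square(cls, labels: Sequence[str], square: np.ndarray) -> "DistanceMatrix":
        from scipy.spatial.distance import squareform

        square = np.asarray(square, dtype=float)
        if not np.allclose(square, square.T):
            raise ValueError("matrix is not symmetric")
        return cls(labels, squareform(square, checks=False))
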