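"""Readers and writers for the on-disk formats.

Formats: FASTA for per-locus alignments and allele catalogs; TSV
(tab-separated, UTF-8, '#' comment lines) for allelic-profile tables,
distance matrices and sparse allele-distance tables; JSON for run
manifests. TSV is the only tabular dialect accepted.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    ALLOWED_CHARS,
    AlleleCatalog,
    DistanceMatrix,
    Isolate,
    IsolateTable,
    Locus,
)

logger = logging.getLogger("uzonmlsa")

#: Float formatting used in all result tables.
FLOAT_FMT = "%.6f"
NA_TOKEN = "NA"


class AlignmentError(ValueError):
    """Raised when an input alignment violates its invariants."""


def read_locus_alignment(path: str | Path, locus_name: Optional[str] = None) -> dict[str, str]:
    """Read one locus alignment from FASTA.

    Returns an insertion-ordered mapping record id -> uppercased sequence.
    All records must have equal length; characters outside {A,C,G,T,N,-}
    are rejected; duplicate ids are an error.
    """
    path = Path(path)
    name = locus_name or path.stem
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{name}: no FASTA records in {path}")
    out: dict[str, str] = {}
    length = len(records[0].seq)
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise AlignmentError(
                f"{name}: record '{rec.id}' has length {len(seq)}, expected {length}"
            )
        bad = set(seq) - ALLOWED_CHARS
        if bad:
            raise AlignmentError(
                f"{name}: record '{rec.id}' contains invalid characters {sorted(bad)}"
            )
        if rec.id in out:
            raise AlignmentError(f"{name}: duplicate record id '{rec.id}'")
        out[rec.id] = seq
    return out


def write_locus_alignment(sequences: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in sequences.items():
            fh.write(f">{rec_id}\n{seq}\n")


def write_allele_catalogs(catalogs: Sequence[AlleleCatalog], path: str | Path) -> None:
    """Write catalogs as one FASTA, ids formatted '<locus>_allele<N>'."""
    with open(path, "w") as fh:
        for cat in catalogs:
            for idx in sorted(cat.sequences):
                fh.write(f">{cat.locus.name}_allele{idx}\n{cat.sequences[idx]}\n")


def read_allele_catalogs(path: str | Path, loci: Sequence[Locus]) -> dict[str, AlleleCatalog]:
    """Read back a catalog FASTA written by :func:`write_allele_catalogs`.

    ``loci`` supplies the accepted locus names (and frame/genetic-code
    settings); the aligned length is taken from the sequences themselves,
    since profile tables carry no length information.
    """
    by_locus: dict[str, dict[int, str]] = {loc.name: {} for loc in loci}
    for rec in SeqIO.parse(str(path), "fasta"):
        name, _, idx = rec.id.rpartition("_allele")
        if name not in by_locus:
            raise AlignmentError(f"catalog record '{rec.id}' names unknown locus '{name}'")
        by_locus[name][int(idx)] = str(rec.seq).upper()
    loci_by_name = {loc.name: loc for loc in loci}
    out = {}
    for name, seqs in by_locus.items():
        if not seqs:
            continue
        template = loci_by_name[name]
        locus = Locus(
            name,
            len(next(iter(seqs.values()))),
            template.frame_offset,
            template.genetic_code_id,
        )
        out[name] = AlleleCatalog(locus, sequences=seqs)
    return out


def read_profile_table(path: str | Path, loci: Optional[Sequence[Locus]] = None) -> IsolateTable:
    """Read an MLST-style allelic-profile table.

    Expected TSV header: ``isolate_id  spring  year  <locus1> ... <locusL>``.
    Locus order is taken from the header. Allele indices must be positive
    integers. Parse errors name the offending line.
    """
    path = Path(path)
    rows: list[list[str]] = []
    header: Optional[list[str]] = None
    header_lineno = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                header_lineno = lineno
                continue
            rows.append([lineno, fields])  # type: ignore[list-item]
    if header is None:
        raise ValueError(f"{path}: empty file, no header")
    required = ["isolate_id", "spring", "year"]
    if header[:3] != required:
        raise ValueError(
            f"{path}:{header_lineno}: header must start with {required}, got {header[:3]}"
        )
    locus_names = header[3:]
    if not locus_names:
        raise ValueError(f"{path}:{header_lineno}: no locus columns in header")
    if loci is not None:
        by_name = {loc.name: loc for loc in loci}
        missing = [n for n in locus_names if n not in by_name]
        if missing:
            raise ValueError(f"{path}: unknown loci in header: {missing}")
        loci_list = [by_name[n] for n in locus_names]
    else:
        loci_list = [Locus(n, aligned_length=1) for n in locus_names]

    isolates: list[Isolate] = []
    seen: set[str] = set()
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise ValueError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        iso_id, spring, year_s = fields[0], fields[1], fields[2]
        if iso_id in seen:
            raise ValueError(f"{path}:{lineno}: duplicate isolate_id '{iso_id}'")
        seen.add(iso_id)
        try:
            year = int(year_s)
            profile = tuple(int(a) for a in fields[3:])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer value ({exc})") from None
        if any(a < 1 for a in profile):
            raise ValueError(f"{path}:{lineno}: allele indices must be >= 1")
        isolates.append(Isolate(iso_id, spring, year, profile))
    if not isolates:
        logger.warning("%s: profile table has no data rows", path)
    return IsolateTable(loci_list, isolates)


def write_profile_table(table: IsolateTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("isolate_id\tspring\tyear\t" + "\t".join(table.locus_names) + "\n")
        for iso in table.isolates:
            fh.write(
                f"{iso.id}\t{iso.spring}\t{iso.year}\t"
                + "\t".join(str(a) for a in iso.profile)
                + "\n"
            )


def read_allele_distances(path: str | Path) -> dict[str, dict[tuple[int, int], int]]:
    """Read a sparse allele-distance TSV: locus, allele_a, allele_b, nt_diff."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["locus", "allele_a", "allele_b", "nt_diff"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: dict[str, dict[tuple[int, int], int]] = {}
    for row in df.itertuples(index=False):
        a, b = int(row.allele_a), int(row.allele_b)
        out.setdefault(row.locus, {})[(min(a, b), max(a, b))] = int(row.nt_diff)
    return out


def write_allele_distances(
    distances: Mapping[str, Mapping[tuple[int, int], int]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tallele_a\tallele_b\tnt_diff\n")
        for locus in sorted(distances):
            for (a, b), d in sorted(distances[locus].items()):
                fh.write(f"{locus}\t{a}\t{b}\t{d}\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square labelled distance matrix (TSV, labels as first row+column)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    labels = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != labels:
        raise ValueError(f"{path}: row labels do not match column labels")
    return DistanceMatrix.from_square(labels, df.to_numpy(dtype=float))


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.square(), index=dm.labels, columns=dm.labels)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_results(df: pd.DataFrame, path: str | Path) -> None:
    """Write an analysis table as TSV: floats at 6 decimals, NaN as 'NA'."""
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep=NA_TOKEN)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN])


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(
    path: str | Path,
    command: str,
    parameters: Mapping,
    seed: Optional[int],
    input_paths: Sequence[str | Path] = (),
) -> None:
    """Record what produced a set of outputs (JSON sidecar)."""
    from . import __version__

    manifest = {
        "command": command,
        "parameters": {k: v for k, v in sorted(parameters.items())},
        "seed": seed,
        "version": __version__,
        "inputs": {str(p): file_sha256(p) for p in input_paths},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
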