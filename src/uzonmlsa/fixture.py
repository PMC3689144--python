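"""The bundled Uzon Caldera *Thermoanaerobacter uzonensis* MLSA dataset.

The package ships the published summary of that survey: the 49 sequence
types with their eight-locus allelic profiles and isolate counts per hot
spring and year, the aligned fragment length of each locus, and the
nucleotide distances between the allele pairs involved in single-locus
variants. The raw sequences live in GenBank (Entrez PopSet) and are not
required here; where an analysis needs allele-level nucleotide distances
the sparse published table is used instead.

GenBank PopSet accessions for the underlying sequences (optional inputs):
16S rRNA 301133600; pyrG 306992496; gyrB 310780896; rplB 304564022;
recG 306992180; recA 304564400; rpoB 304561479; lepA 302120473;
leuS 301133848.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

from .model import (
    AlleleCatalog,
    IsolateTable,
    Locus,
    SequenceType,
    SequenceTypeTable,
    YEAR_UNKNOWN,
)

#: Locus order of the allelic profiles (fixed, alphabetical as published).
UZON_LOCI_ORDER = ("gyrB", "lepA", "leuS", "pyrG", "recA", "recG", "rplB", "rpoB")


@dataclass
class UzonFixture:
    isolates: IsolateTable
    sequence_types: SequenceTypeTable
    #: per-locus sparse allele-distance catalogs (no sequences)
    allele_distances: dict[str, AlleleCatalog]

    @property
    def loci(self) -> list[Locus]:
        return self.isolates.loci


def _data_path(name: str):
    return importlib.resources.files("uzonmlsa.data").joinpath(name)


def load_uzon_loci() -> list[Locus]:
    with importlib.resources.as_file(_data_path("uzon_loci.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    by_name = {r.locus: Locus(r.locus, int(r.aligned_length)) for r in df.itertuples()}
    return [by_name[n] for n in UZON_LOCI_ORDER]


def load_uzon_fixture() -> UzonFixture:
    """Load the packaged dataset: 106 isolates in 49 sequence types.

    Isolates are expanded from the ST summary; ids are synthetic
    (``ST<st>_<spring><year>_<k>``) since the survey's strain names are not
    in the summary tables. STs recovered from the same spring in both
    sampling years without a published per-year split carry
    ``year = 0`` (unknown); per-year subsets of such springs are therefore
    not exactly reconstructible and callers should group by spring alone
    when year-resolved counts matter.
    """
    loci = load_uzon_loci()
    with importlib.resources.as_file(_data_path("uzon_sequence_types.tsv")) as p:
        df = pd.read_csv(p, sep="\t", comment="#")

    types: dict[int, SequenceType] = {}
    for row in df.itertuples(index=False):
        st = int(row.st)
        profile = tuple(int(getattr(row, loc)) for loc in UZON_LOCI_ORDER)
        spring, year, n = str(row.spring), int(row.year), int(row.n_isolates)
        if st not in types:
            types[st] = SequenceType(st, profile)
        elif types[st].profile != profile:
            raise ValueError(f"fixture: inconsistent profile for ST {st}")
        start = types[st].count
        year_tag = "unkYear" if year == YEAR_UNKNOWN else str(year)
        types[st].members.extend(
            (f"ST{st}_{spring}{year_tag}_{start + k + 1:02d}", spring, year)
            for k in range(n)
        )

    st_table = SequenceTypeTable(loci, [types[k] for k in sorted(types)])
    isolates = st_table.expand()

    with importlib.resources.as_file(_data_path("uzon_allele_distances.tsv")) as p:
        dist_df = pd.read_csv(p, sep="\t", comment="#")
    loci_by_name = {loc.name: loc for loc in loci}
    dist: dict[str, dict[tuple[int, int], int]] = {}
    for row in dist_df.itertuples(index=False):
        a, b = int(row.allele_a), int(row.allele_b)
        dist.setdefault(str(row.locus), {})[(min(a, b), max(a, b))] = int(row.nt_diff)
    catalogs = {
        name: AlleleCatalog(loci_by_name[name], distance_table=entries)
        for name, entries in dist.items()
    }
    return UzonFixture(isolates, st_table, catalogs)
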