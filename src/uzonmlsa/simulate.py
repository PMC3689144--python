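"""Forward-time haploid multi-deme simulator for MLSA-style datasets.

The model is a haploid Wright-Fisher population subdivided into demes
(hot springs). Each individual carries one allele per locus; alleles are
actual nucleotide strings so the whole analysis stack -- allele calling,
nucleotide distances, diversity -- can be exercised end to end. Every
generation, in this order:

1. **Resampling** -- each deme is replaced by ``deme_size`` multinomial
   draws (with replacement) of whole genotypes from itself.
2. **Migration** -- each individual is, with probability ``m``, replaced by
   a copy of a random individual from a random *other* deme.
3. **Recombination** -- at each locus, each individual, with probability
   ``r``, replaces its allele with that of a random individual of the same
   deme (allele swapping; the MLST-scale analogue of homologous
   recombination).
4. **Mutation** -- at each locus, each individual, with probability ``mu``,
   receives a brand-new allele (infinite-alleles): its current sequence
   with ``k`` random substitutions, k = 1 + (shifted geometric, mean 1),
   re-drawn until the string has never been seen at that locus.

Clonal expansion is applied at sampling time: the most common sequence
type in the pooled sample is oversampled by ``clone_boost``, which mimics
an 'epidemic' clone -- it inflates isolate-level linkage statistics while
leaving the deduplicated ST-level ones untouched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as uio
from .alleles import call_alleles
from .model import AlleleCatalog, Isolate, IsolateTable, Locus

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    n_demes: int = 1
    deme_size: int = 100
    generations: int = 400
    n_loci: int = 8
    locus_length: int = 400
    #: per-locus, per-individual, per-generation new-allele probability
    mu: float = 0.01
    #: per-locus, per-individual, per-generation allele-swap probability
    r: float = 0.0
    #: per-individual, per-generation migration probability
    m: float = 0.0
    #: oversampling factor for the modal sequence type (1 = none)
    clone_boost: int = 1
    sample_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mu", "r", "m"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_demes", "deme_size", "generations", "n_loci", "locus_length",
                     "clone_boost", "sample_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sample_size > self.deme_size:
            raise ValueError("sample_size cannot exceed deme_size")


@dataclass
class SimulationTruth:
    """Ground-truth bookkeeping of what the simulator actually did."""

    mutation_events: int = 0
    recombination_events: int = 0
    migration_events: int = 0
    #: per-locus number of distinct alleles ever created
    alleles_created: list[int] = field(default_factory=list)
    #: per-locus number of distinct alleles present in the final sample
    sample_allele_counts: list[int] = field(default_factory=list)
    #: final allele frequencies: locus -> deme label -> {allele: freq}
    final_frequencies: dict[str, dict[str, dict[int, float]]] = field(default_factory=dict)


@dataclass
class SimulationResult:
    table: IsolateTable
    catalogs: dict[str, AlleleCatalog]
    truth: SimulationTruth
    config: SimulationConfig


def _new_allele(
    rng: np.random.Generator,
    parent: np.ndarray,
    seen: set[bytes],
    k_mean_extra: float = 1.0,
) -> np.ndarray:
    """Mutate ``parent`` into a never-seen sequence (k >= 1 substitutions)."""
    length = parent.size
    # k = 1 + (geometric number of extra substitutions, mean k_mean_extra)
    p_stop = 1.0 / (1.0 + k_mean_extra)
    for _ in range(100):
        k = min(int(rng.geometric(p_stop)), length)
        child = parent.copy()
        pos = rng.choice(length, size=k, replace=False)
        child[pos] = (child[pos] + 1 + rng.integers(0, 3, size=k)) % 4
        key = child.tobytes()
        if key not in seen:
            seen.add(key)
            return child
    raise RuntimeError("could not generate a novel allele (sequence space exhausted)")


def simulate(config: SimulationConfig, out_dir: Optional[str | Path] = None) -> SimulationResult:
    """Run the simulation and return the sampled dataset plus ground truth.

    With ``out_dir`` the sampled dataset is also written to disk (one FASTA
    alignment per locus, a profile TSV, the truth as JSON, and a run
    manifest), in the formats the readers in :mod:`uzonmlsa.io` accept.
    Output is deterministic for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    n_demes, deme_size = config.n_demes, config.deme_size
    truth = SimulationTruth()

    # per-locus allele store: genomes hold integer allele ids
    allele_seqs: list[list[np.ndarray]] = []
    seen_sets: list[set[bytes]] = []
    pop = np.zeros((config.n_loci, n_demes, deme_size), dtype=np.int64)
    for _ in range(config.n_loci):
        founder = rng.integers(0, 4, size=config.locus_length).astype(np.uint8)
        allele_seqs.append([founder])
        seen_sets.append({founder.tobytes()})

    for _ in range(config.generations):
        # 1. Wright-Fisher resampling of whole genotypes, per deme
        parents = rng.integers(deme_size, size=(n_demes, deme_size))
        for l in range(config.n_loci):
            pop[l] = np.take_along_axis(pop[l], parents, axis=1)
        # 2. migration
        if n_demes > 1 and config.m > 0:
            migrants = np.argwhere(rng.random((n_demes, deme_size)) < config.m)
            truth.migration_events += len(migrants)
            for d, i in migrants:
                src = int(rng.integers(n_demes - 1))
                src += src >= d
                j = int(rng.integers(deme_size))
                pop[:, d, i] = pop[:, src, j]
        # 3. recombination (allele swapping within deme)
        if config.r > 0:
            for l in range(config.n_loci):
                mask = rng.random((n_demes, deme_size)) < config.r
                truth.recombination_events += int(mask.sum())
                donors = rng.integers(deme_size, size=(n_demes, deme_size))
                donated = np.take_along_axis(pop[l], donors, axis=1)
                pop[l][mask] = donated[mask]
        # 4. mutation (infinite alleles, realized on sequences)
        if config.mu > 0:
            for l in range(config.n_loci):
                events = np.argwhere(rng.random((n_demes, deme_size)) < config.mu)
                truth.mutation_events += len(events)
                for d, i in events:
                    parent = allele_seqs[l][pop[l, d, i]]
                    child = _new_allele(rng, parent, seen_sets[l])
                    allele_seqs[l].append(child)
                    pop[l, d, i] = len(allele_seqs[l]) - 1

    truth.alleles_created = [len(seqs) for seqs in allele_seqs]
    loci = [
        Locus(f"locus{l + 1:02d}", config.locus_length) for l in range(config.n_loci)
    ]
    for l, locus in enumerate(loci):
        truth.final_frequencies[locus.name] = {}
        for d in range(n_demes):
            vals, counts = np.unique(pop[l, d], return_counts=True)
            truth.final_frequencies[locus.name][f"deme{d + 1}"] = {
                int(v): float(c) / deme_size for v, c in zip(vals, counts)
            }

    # sample without replacement from each deme
    sampled: list[tuple[str, str, tuple[int, ...]]] = []  # (id, spring, raw alleles)
    for d in range(n_demes):
        picks = rng.choice(deme_size, size=config.sample_size, replace=False)
        for k, i in enumerate(sorted(picks)):
            sampled.append(
                (
                    f"deme{d + 1}_i{k + 1:03d}",
                    f"deme{d + 1}",
                    tuple(int(pop[l, d, i]) for l in range(config.n_loci)),
                )
            )

    # clonal expansion of the modal sequence type (sampling-time oversampling)
    if config.clone_boost > 1:
        raw_profiles = [s[2] for s in sampled]
        uniq, counts = np.unique(np.array(raw_profiles), axis=0, return_counts=True)
        modal = tuple(int(a) for a in uniq[int(np.argmax(counts))])
        donors = [s for s in sampled if s[2] == modal]
        extra = len(donors) * (config.clone_boost - 1)
        for k in range(extra):
            src = donors[k % len(donors)]
            sampled.append((f"{src[0]}_clone{k + 1:03d}", src[1], modal))

    # call alleles locus by locus (dense 1-based indices, order of appearance)
    decode = lambda arr: "".join(_BASES[arr].astype(str))  # noqa: E731
    catalogs: dict[str, AlleleCatalog] = {}
    columns: list[list[int]] = []
    for l, locus in enumerate(loci):
        seqs = [decode(allele_seqs[l][s[2][l]]) for s in sampled]
        catalog, calls = call_alleles(seqs, locus)
        catalogs[locus.name] = catalog
        columns.append(calls)
        truth.sample_allele_counts.append(catalog.n_alleles)

    isolates = [
        Isolate(iso_id, spring, 1, tuple(columns[l][row] for l in range(config.n_loci)))
        for row, (iso_id, spring, _) in enumerate(sampled)
    ]
    table = IsolateTable(loci, isolates)
    result = SimulationResult(table, catalogs, truth, config)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        uio.write_profile_table(table, out_dir / "profiles.tsv")
        for l, locus in enumerate(loci):
            seqs = {iso.id: catalogs[locus.name].sequences[iso.profile[l]] for iso in isolates}
            uio.write_locus_alignment(seqs, out_dir / f"{locus.name}.fasta")
        uio.write_allele_catalogs(list(catalogs.values()), out_dir / "catalog.fasta")
        with open(out_dir / "truth.json", "w") as fh:
            truth_dict = asdict(truth)
            json.dump(truth_dict, fh, indent=2, sort_keys=True, default=str)
            fh.write("\n")
        uio.write_run_manifest(
            out_dir / "manifest.json",
            command="simulate",
            parameters=asdict(config),
            seed=config.seed,
        )
    return result


def make_regimes() -> dict[str, SimulationConfig]:
    """Canned configurations for the qualitative population structures.

    * ``clonal`` -- no recombination: strong linkage disequilibrium, the
      index of association should be significantly positive.
    * ``panmictic_recombining`` -- one deme with frequent allele swapping:
      I^S_A should scatter around zero.
    * ``epidemic`` -- recombining background plus a 20-fold oversampled
      clone: isolate-level I^S_A exceeds the deduplicated ST-level value.
    * ``island_low_migration`` -- several demes with rare migration:
      subpopulations differentiate (positive F_ST, decreasing in m).
    """
    base = dict(deme_size=100, generations=400, n_loci=8, locus_length=400, mu=0.01)
    return {
        "clonal": SimulationConfig(n_demes=1, r=0.0, sample_size=50, **base),
        "panmictic_recombining": SimulationConfig(n_demes=1, r=0.5, sample_size=50, **base),
        "epidemic": SimulationConfig(
            n_demes=1, r=0.5, clone_boost=20, sample_size=50, **base
        ),
        "island_low_migration": SimulationConfig(
            n_demes=4, r=0.1, m=0.002, sample_size=20, **base
        ),
    }
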