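# uzonmlsa

A multilocus sequence analysis (MLSA) toolkit for bacterial population
structure, built around the Uzon Caldera *Thermoanaerobacter uzonensis*
dataset: 106 isolates from seven Kamchatka geothermal springs, typed at
eight protein-coding loci (*gyrB, lepA, leuS, pyrG, recA, recG, rplB,
rpoB*; 8003 nt of concatenated sequence). The package ships that dataset's
sequence-type summary as a ready-to-analyse fixture and implements the full
analysis stack on top of it, usable with any MLST/MLSA-style data:

* **Allele calling & sequence typing** — dense 1-based allele indices by
  exact string identity of aligned fragments; sequence types (STs) by exact
  profile equality.
* **Sequence heterogeneity** — segregating sites *S*, nucleotide diversity
  π (pairwise deletion), variable amino-acid residues, allele counts
  *n*<sub>a</sub>.
* **Genetic diversity** — unbiased *H* = (*n*/(*n*−1))(1 − Σ*p*<sub>i</sub>²),
  per locus, population-wide or per subpopulation.
* **Linkage disequilibrium** — the standardized index of association
  *I*<sup>S</sup><sub>A</sub> = (*V*<sub>D</sub>/*V*<sub>E</sub> − 1)/(*l* − 1),
  where *V*<sub>D</sub> is the variance of the pairwise locus-mismatch
  distribution and *V*<sub>E</sub> = Σ<sub>j</sub> *h*<sub>j</sub>(1 − *h*<sub>j</sub>)
  its expectation under free recombination, with Monte-Carlo significance.
* **Single-locus variants** — enumeration of ST pairs differing at exactly
  one locus and classification of each as recombination (R) or point
  mutation (M) from the variant alleles' nucleotide distance and how widely
  they recur among STs.
* **Differentiation** — pairwise *F*<sub>ST</sub> between subpopulations by
  haplotypic AMOVA on pairwise sequence differences, with permutation
  significance; Mantel-type Spearman isolation-by-distance test.
* **Simulation** — a forward-time haploid multi-deme Wright–Fisher model
  with infinite-alleles mutation on real sequences, within-deme allele
  swapping (recombination), migration and sampling-time clonal expansion,
  for end-to-end validation of every statistic against known truth.

## Worked example

```sh
$ python examples/reproduce_survey.py
106 isolates in 49 sequence types (largest held by 11 isolates)

per-locus genetic diversity H (unbiased):
  gyrB  H = 0.32
  ...
  pyrG  H = 0.93
  mean  H = 0.62

dominant alleles:
  gyrB allele 1: 82.1% of isolates
  recA allele 1: 79.2% of isolates
  rplB allele 3: 67.9% of isolates

I^S_A over all isolates: 0.086
I^S_A over unique STs:   0.028
```

Diversity differs sharply between loci (*gyrB* nearly monomorphic, *pyrG*
with 25 alleles and *H* = 0.93). The isolate-level
*I*<sup>S</sup><sub>A</sub> of 0.086 is small but significantly positive;
deduplicating to the 49 unique STs drops it to 0.028. That drop is the
signature of an *epidemic* population structure: a recombining population
in which particular clones (e.g. the 11-isolate ST23) have risen to high
frequency. `examples/classify_slvs.py` prints the 11 single-locus-variant
pairs (7 attributed to recombination, 4 to mutation), and
`examples/simulate_epidemic.py` / `examples/fst_island_model.py`
demonstrate the same signatures on simulated data with known parameters.

The same analyses are available from the shell:

```sh
uzonmlsa simulate --regime epidemic --seed 42 --out-dir sim/
uzonmlsa linkage --profiles sim/profiles.tsv --resamples 1000 --seed 17 --out linkage.tsv
uzonmlsa slv --profiles sim/profiles.tsv --catalog sim/catalog.fasta --out slv.tsv
uzonmlsa fst --profiles sim/profiles.tsv --catalog sim/catalog.fasta --out fst.tsv
uzonmlsa uzon-repro   # recompute the bundled dataset's reference statistics
```

Every command writes a JSON manifest (parameters, seed, input checksums,
package version) next to its output.

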