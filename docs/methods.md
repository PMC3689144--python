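# Methods

This note records the statistical models, conventions and design choices
the package implements, and what the bundled data and simulator can and
cannot establish.

## Data model

An MLSA dataset is a set of isolates, each carrying one allele index per
locus (the *allelic profile*), plus per-locus allele catalogs mapping each
index to an aligned nucleotide fragment. Alleles are defined by **exact
string identity**: two fragments are the same allele iff they are equal as
strings. Missing data (`N`, `-`) therefore never merges alleles — the
assumption is that ambiguous base calls were resolved upstream (by
re-sequencing), so string inequality reflects real sequence difference.
Diversity statistics, in contrast, treat `N`/`-` as missing with pairwise
deletion. Allele indices are dense and 1-based, assigned in order of first
appearance; sequence types (STs) are numbered the same way. The ST
partition of a dataset is invariant under isolate reordering (tested).

The bundled Uzon Caldera dataset encodes the published ST summary: 49 STs,
106 isolates, per-spring/year counts, plus a *sparse* allele-distance table
(nucleotide differences between the allele pairs involved in single-locus
variants). Two caveats are inherent to the source tables and are encoded
rather than guessed:

* STs 36 and 38 were recovered from Thermophilny in both 2005 and 2006 and
  the per-year split of their 11 + 7 isolates is not recorded; those
  members carry `year = 0` (unknown), so per-year Thermophilny subsets are
  not exactly reconstructible (per-spring subsets are).
* The published total for Thermophilny 2006 is 19 isolates in the count
  tables but 18 in the running text; the tables are followed.
* The published summary reports 4 unique STs for the seven Arkashin 2006
  isolates, but the ST table itself yields five distinct profiles for them
  (ST1–4 and ST23); ST-level statistics for that subset therefore cannot
  match the published entry and are not treated as reference values.

## Genetic diversity

Per-locus diversity is the unbiased estimator

    H = (n/(n−1)) · (1 − Σ p_i²),

the exact probability that two isolates drawn **without replacement**
carry different alleles (this identity is tested by enumeration). H is
computed over isolates by default; an ST mode recomputes it over
deduplicated profiles for clonality-robust contrasts. Nucleotide diversity
π is the mean over unordered pairs of (differences / compared sites) with
pairwise deletion and no multiple-hit correction (a p-distance; at the
within-species divergences involved, < 2%, the correction is negligible).
Whether the original analyses used pairwise or complete deletion for gap
columns is not stated; pairwise deletion was chosen and is the documented
behaviour. Translation uses the bacterial code (table 11) and frame offset
0 by default, both configurable per locus; codons containing missing
characters translate to a missing residue.

## Standardized index of association

For n profiles over l loci, K is the vector of locus-mismatch counts over
all C(n,2) pairs. The statistic is

    I^S_A = (V_D / V_E − 1) / (l − 1),

with **V_D the sample variance of K (denominator C(n,2) − 1)** and
**V_E = Σ_j h_j (1 − h_j) with unbiased h_j**. With unbiased h the identity
E[K] = Σ_j h_j holds exactly, and under independent within-locus
permutations E[Σ(K−K̄)²] = C(n,2) · Σ h_j(1−h_j), so the estimator is
centred at zero under free recombination up to the (C(n,2)−1)/C(n,2)
factor. The convention pair is locked by a regression test on a
seven-isolate subset of the bundled data whose 21 pairs can be enumerated
by hand (mismatch multiset {0×6, 1×3, 7×12}): the adopted pair gives
0.841; population-variance and/or biased-h alternatives give 0.794, 0.805
and 0.760 and are asserted *not* to be in use. Significance is Monte
Carlo: each locus column is permuted independently (allele frequencies
preserved, associations destroyed), with the add-one estimator
P = (hits + 1)/(resamples + 1), so P is never zero and is deterministic
given a seed. Subsets with fewer than three profiles are reported as NA by
the table-level driver (the threshold is configurable); the statistic
itself is computable at n = 3.

## Single-locus variants

Two STs are an SLV when their profiles differ at exactly one locus.
Classification of each SLV:

* **R** if the two variant alleles differ at > 1 nt, or differ at exactly
  1 nt while **both** alleles occur in ≥ 2 distinct STs;
* **M** if they differ at 1 nt and at least one allele is confined to a
  single ST (the putative novel variant);
* **UNKNOWN** when no nucleotide distance is available.

The underlying idea (single, unique nucleotide changes are point
mutations; multi-site or recurrent changes are imports) requires an
ancestral/variant polarity that allele tables do not provide; the
confined-to-one-ST reading is the interpretation adopted here, chosen
because it is the simplest symmetric rule and reproduces every published
call for the bundled dataset (verified row by row in the regression
suite). "Occurs multiple times" is evaluated at the ST level, not the
isolate level, so clonal oversampling cannot promote M to R. The rule is
symmetric in the pair.

## Pairwise F_ST and isolation by distance

F_ST between two subpopulations is estimated by haplotypic AMOVA on
pairwise nucleotide-difference counts treated as squared distances:

    SSD_total  = (1/N) Σ_{i<j} d_ij              (over both subsets)
    SSD_within = Σ_g (1/n_g) Σ_{i<j∈g} d_ij
    σ²_w = SSD_within/(N−2),   n' = (N − Σn_g²/N)/(P−1)
    σ²_a = (SSD_among/(P−1) − σ²_w)/n',   F_ST = σ²_a/(σ²_a+σ²_w)

Negative estimates are reported as computed, not clamped. When the data
carry no variation at all (σ²_a + σ²_w = 0) F_ST is defined as 0. For
balanced designs the estimator reduces *exactly* to
(π_between − π_within)/π_between, which the tests verify to 1e-9 against a
direct mean-distance computation. Significance permutes individuals
between the two subsets (sizes preserved), add-one corrected — a
permutation test, which is what "randomized resampling" significance
testing of F_ST amounts to in standard AMOVA software. Subsets of size < 2
give NA. The published pairwise F_ST values for the real dataset require
the GenBank sequence concatenates and are out of the fixture's reach;
the estimator is instead pinned by exact toy cases (0 for identical
monomorphic demes, 1 for fixed differences, the balanced-design identity)
and by the island-model simulation, where mean F_ST decreases
monotonically in the migration rate.

Isolation by distance is a Mantel-type permutation test on Spearman's rank
correlation between condensed genetic and geographic distance matrices;
the significance level is reported as the percentage of label permutations
with rho ≥ observed (add-one corrected). The spring-to-spring geographic
distances are not published, so the real-data correlation is not
reproducible here; the test is validated by the self-correlation case
(rho = 1) and by null calibration (median significance ≈ 50% over 500
runs on independent random matrices).

## Simulator

Haploid Wright–Fisher with demes, default parameters:

| parameter | default | meaning |
|---|---|---|
| `deme_size` | 100 | individuals per deme (N) |
| `generations` | 400 | ≈ 4N: near mutation–drift equilibrium from a monomorphic start |
| `n_loci` / `locus_length` | 8 / 400 nt | an MLSA-scale scheme |
| `mu` | 0.01 | per locus/individual/generation new-allele probability; θ = 2Nμ = 2 gives equilibrium per-locus diversity ≈ 0.67, matching the MLSA range (mean H 0.62) |
| `r` | 0 | per locus/individual/generation within-deme allele-swap probability |
| `m` | 0 | per individual/generation migration probability |
| `clone_boost` | 1 | sampling-time oversampling factor of the modal ST |
| `sample_size` | 50 | isolates sampled per deme without replacement |

Event order within a generation is fixed and results depend on it:
resampling → migration → recombination → mutation. Mutation is
infinite-alleles realized on sequences: each event applies k = 1 +
(geometric, mean 1) substitutions and re-draws until the string is novel
at that locus, so allele indices and allele strings are in bijection and
allele calling on simulator output recovers the ground-truth counts
exactly. Recombination is whole-allele swapping, the natural granularity
at MLST fragment scale. Clonal expansion happens at sampling time (the
modal ST's sample count is multiplied), which by construction inflates
isolate-level but not ST-level linkage statistics. Everything is driven
by one `numpy` generator seeded from the config, so identical configs give
byte-identical output files.

The canned regimes encode the qualitative contrasts of interest — clonal
(r = 0), panmictic-recombining (r = 0.5), epidemic (r = 0.5 with a 20×
clone), island with low migration — and are calibrated in the acceptance
suite: the panmictic regime's mean I^S_A over 20 seeds lies within ±0.02
of zero, the clonal regime is significant at P < 0.05 in ≥ 18/20 seeds,
and the epidemic regime shows isolate-level > ST-level I^S_A in ≥ 18/20
seeds. Problem sizes used in tests (N = 100, 400 generations, 20-seed
replication; two-deme N = 60 islands for the migration sweep) were chosen
to make those contrasts statistically decisive at desk scale.

What the simulator does **not** emulate: within-locus recombination
(breakpoints inside a fragment), selection, spatially explicit dispersal,
sequencing error, or unequal deme sizes. Passing calibrations therefore
show that the statistics respond correctly to known mutation,
recombination, migration and clonal expansion — not that real hot-spring
populations satisfy the model's neutrality or equilibrium assumptions.

## Numerical conventions

* TSV (tab-separated, UTF-8, `#` comments) is the only tabular dialect;
  floats are written at 6 decimals with `NA` for missing.
* All permutation P values use the add-one estimator.
* Comparison reports round half-even to the reference's printed precision;
  data files keep full precision.
* Reported F_ST, I_A, I^S_A may be negative; NaN/NA marks undefined cases
  (monomorphic loci, subsets below minimum size), never silently 0.
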