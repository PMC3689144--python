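import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import random_sequences
from uzonmlsa import (
    Isolate,
    IsolateTable,
    Locus,
    assign_sequence_types,
    call_alleles,
    concatenate_loci,
    nucleotide_diversity,
    variable_amino_acids,
    variable_sites,
)
from uzonmlsa.alleles import locus_summary, translate


class TestCallAlleles:
    def test_indices_by_first_appearance(self):
        cat, calls = call_alleles(["AAA", "AAA", "AAT"], Locus("x", 3))
        assert cat.sequences == {1: "AAA", 2: "AAT"}
        assert calls == [1, 1, 2]

    def test_all_identical_gives_single_allele(self):
        cat, calls = call_alleles(["ACG"] * 5, Locus("x", 3))
        assert cat.n_alleles == 1 and calls == [1] * 5

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError, match="no sequences"):
            call_alleles([], Locus("x", 3))

    def test_missing_data_does_not_merge_alleles(self):
        # exact string identity defines alleles: N never matches A
        cat, calls = call_alleles(["AAN", "AAA"], Locus("x", 3))
        assert cat.n_alleles == 2


class TestSequenceTypes:
    def _table(self, profiles, springs=None):
        springs = springs or ["s"] * len(profiles)
        loci = [Locus(f"L{j}", 1) for j in range(len(profiles[0]))]
        return IsolateTable(
            loci,
            [Isolate(f"i{k}", springs[k], 2006, tuple(p)) for k, p in enumerate(profiles)],
        )

    def test_uzon_partition(self, uzon):
        st_table = assign_sequence_types(uzon.isolates)
        counts = sorted((t.count for t in st_table), reverse=True)
        assert len(st_table) == 49
        assert counts[0] == 11
        assert sum(1 for c in counts if c == 1) == 35

    def test_numbering_by_first_appearance(self):
        st_table = assign_sequence_types(self._table([(1, 2), (3, 4), (1, 2)]))
        assert [(t.st, t.profile) for t in st_table] == [(1, (1, 2)), (2, (3, 4))]
        assert st_table.types[0].count == 2

    @given(st.permutations(list(range(8))))
    @settings(max_examples=20, deadline=None)
    def test_partition_invariant_under_isolate_order(self, order):
        profiles = [(1, 1), (2, 1), (1, 1), (2, 2), (3, 1), (2, 1), (1, 1), (9, 9)]
        base = assign_sequence_types(self._table(profiles))
        perm = assign_sequence_types(self._table([profiles[i] for i in order]))
        as_partition = lambda tt: {  # noqa: E731
            frozenset(t.isolate_ids) for t in tt
        }
        base_ids = {frozenset(f"i{k}" for k, p in enumerate(profiles) if p == t.profile)
                    for t in base}
        perm_ids = {frozenset(f"i{k}" for k, i in enumerate(order) if profiles[i] == t.profile)
                    for t in perm}
        assert {t.profile for t in base} == {t.profile for t in perm}
        assert base_ids == as_partition(base) and perm_ids == as_partition(perm)


class TestVariableSites:
    def test_trivial_cases(self):
        assert variable_sites(["AAA", "AAA"]) == 0
        assert variable_sites(["AAA", "AAT", "AAC"]) == 1

    def test_missing_data_ignored_per_column(self):
        # column 2: only one non-missing character -> not variable
        assert variable_sites(["AAN", "AA-", "AAA"]) == 0
        assert variable_sites(["AAN", "AAT", "AAC"]) == 1

    def test_matches_brute_force_recount(self, rng):
        seqs = random_sequences(rng, 20, 100, missing_frac=0.05)
        brute = 0
        for col in zip(*seqs):
            observed = {c for c in col if c not in "N-"}
            brute += len(observed) >= 2
        assert variable_sites(seqs) == brute

    def test_additive_over_disjoint_loci(self, rng):
        a = random_sequences(rng, 10, 40)
        b = random_sequences(rng, 10, 60)
        concat = [x + y for x, y in zip(a, b)]
        assert variable_sites(concat) == variable_sites(a) + variable_sites(b)


class TestNucleotideDiversity:
    def test_identical_pair_is_zero(self):
        assert nucleotide_diversity(["ACGT", "ACGT"]) == 0.0

    def test_single_difference(self):
        assert nucleotide_diversity(["AAAA", "AAAT"]) == pytest.approx(0.25)

    def test_matches_brute_force_pair_loop(self, rng):
        seqs = random_sequences(rng, 10, 100, missing_frac=0.05)
        total = 0.0
        pairs = 0
        for a, b in itertools.combinations(seqs, 2):
            comp = [(x, y) for x, y in zip(a, b) if x not in "N-" and y not in "N-"]
            total += sum(x != y for x, y in comp) / len(comp)
            pairs += 1
        assert nucleotide_diversity(seqs) == pytest.approx(total / pairs, abs=1e-12)

    def test_zero_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="no comparable sites"):
            nucleotide_diversity(["AN", "NA"])

    def test_invariant_under_relabeling(self, rng):
        seqs = random_sequences(rng, 8, 50)
        shuffled = list(reversed(seqs))
        assert nucleotide_diversity(seqs) == pytest.approx(nucleotide_diversity(shuffled))


class TestVariableAminoAcids:
    def test_identical_sequences(self):
        assert variable_amino_acids(["ATGGCT", "ATGGCT"]) == 0

    def test_synonymous_substitution_not_counted(self):
        # GCT and GCC both encode Ala: 1 variable nt site, 0 variable residues
        assert variable_sites(["GCT", "GCC"]) == 1
        assert variable_amino_acids(["GCT", "GCC"]) == 0

    def test_nonsynonymous_counted(self):
        assert variable_amino_acids(["GCT", "GAT"]) == 1  # Ala vs Asp

    def test_matches_translate_then_recount(self, rng):
        seqs = random_sequences(rng, 12, 99, missing_frac=0.02)
        proteins = [translate(s) for s in seqs]
        brute = 0
        for col in zip(*proteins):
            observed = {c for c in col if c != "X"}
            brute += len(observed) >= 2
        assert variable_amino_acids(seqs) == brute

    def test_translation_agrees_with_biopython_on_clean_codons(self, rng):
        from Bio.Seq import Seq

        seqs = random_sequences(rng, 5, 60)
        for s in seqs:
            ours = translate(s).replace("*", "*")
            ref = str(Seq(s).translate(table=11))
            assert ours == ref

    def test_invalid_code_and_short_alignment(self):
        with pytest.raises(ValueError, match="genetic code"):
            variable_amino_acids(["ATGGCT"], genetic_code_id=99999)
        with pytest.raises(ValueError, match="complete codon"):
            variable_amino_acids(["AT"], frame_offset=0)


class TestConcatenate:
    def _setup(self, lengths):
        loci = [Locus(f"L{j}", n) for j, n in enumerate(lengths)]
        rng = np.random.default_rng(1)
        cats = {}
        for loc in loci:
            seqs = random_sequences(rng, 3, loc.aligned_length)
            cats[loc.name], _ = call_alleles(seqs, loc)
        return loci, cats

    def test_length_is_sum_of_locus_lengths(self):
        loci, cats = self._setup([3, 4])
        table = IsolateTable(loci, [Isolate("i1", "s", 0, (1, 2))])
        assert len(concatenate_loci(table, cats)["i1"]) == 7

    def test_identical_profiles_identical_concatenates(self):
        loci, cats = self._setup([5, 5])
        table = IsolateTable(
            loci, [Isolate("a", "s", 0, (2, 1)), Isolate("b", "t", 0, (2, 1))]
        )
        conc = concatenate_loci(table, cats)
        assert conc["a"] == conc["b"]

    def test_mlsa_scheme_concatenate_is_8003_nt(self, uzon):
        lengths = [loc.aligned_length for loc in uzon.loci]
        loci, cats = self._setup(lengths)
        table = IsolateTable(loci, [Isolate("i1", "s", 0, tuple([1] * 8))])
        assert len(concatenate_loci(table, cats)["i1"]) == 8003

    def test_missing_allele_names_locus_and_index(self):
        loci, cats = self._setup([3, 3])
        table = IsolateTable(loci, [Isolate("i1", "s", 0, (1, 9))])
        with pytest.raises(KeyError, match="L1 allele 9"):
            concatenate_loci(table, cats)


def test_locus_summary_round_trips_simulated_truth(rng):
    """On simulator output, n_a equals the simulator's ground-truth count."""
    from uzonmlsa import SimulationConfig, simulate

    cfg = SimulationConfig(deme_size=40, generations=60, n_loci=3, locus_length=60,
                           mu=0.02, sample_size=20, seed=5)
    res = simulate(cfg)
    alignments = {
        loc.name: {
            iso.id: res.catalogs[loc.name].sequences[iso.profile[j]]
            for iso in res.table.isolates
        }
        for j, loc in enumerate(res.table.loci)
    }
    df = locus_summary(alignments, res.table.loci)
    assert list(df["n_a"]) == res.truth.sample_allele_counts
    assert (df["s"] >= 0).all() and (df["pi_per_100"] >= 0).all()
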