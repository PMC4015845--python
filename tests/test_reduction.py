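"""The peptide/protein reduction cascade and confidence tiers."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedprot.ingest import PeptideObservation
from fedprot.library import FederatedLibrary, ProteinRecord
from fedprot.reduction import (
    DistributionTable,
    confidence_tier,
    distinct_peptides,
    map_peptides_to_library,
    peptide_protein_distribution,
    remove_subset_peptides,
    unique_peptide_proteins,
)
from fedprot.store import build_evidence_store

AA = "ACDEFGHIKLMNPQRSTVWY"


def _rand_pep(rng, lo=6, hi=18):
    return "".join(rng.choice(AA) for _ in range(rng.randint(lo, hi)))


class TestDistinctPeptides:
    def test_basic_and_empty(self):
        assert distinct_peptides(["AAK", "AAK", "AAR"]) == {"AAK", "AAR"}
        assert distinct_peptides([]) == set()

    def test_planted_duplicate_count(self, rng):
        base = list({_rand_pep(rng) for _ in range(863)})
        dups = [rng.choice(base) for _ in range(1000 - len(base))]
        pool = base + dups
        rng.shuffle(pool)
        assert len(distinct_peptides(pool)) == len(set(pool))  # set-size oracle
        assert len(distinct_peptides(pool)) == len(base)


class TestRemoveSubsetPeptides:
    def test_containment_removed_overlap_kept(self):
        assert remove_subset_peptides({"PEPTIDER", "TIDE"}) == {"PEPTIDER"}
        assert remove_subset_peptides({"ABCDEF", "BCDEFG"}) == {"ABCDEF", "BCDEFG"}

    def test_planted_substrings(self, rng):
        maximal = list({_rand_pep(rng, 12, 25) for _ in range(440)})
        subs = []
        for k in range(60):
            host = rng.choice(maximal)
            lo = rng.randint(1, 3)
            subs.append(host[lo:lo + rng.randint(6, len(host) - lo - 2)])
        pool = set(maximal) | set(subs)
        out = remove_subset_peptides(pool)
        # brute-force pairwise containment oracle
        expected = {p for p in pool if not any(p != q and p in q for q in pool)}
        assert out == expected

    @given(st.sets(st.text(alphabet="AKR", min_size=1, max_size=10), max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_no_contained_pair_survives(self, peptides):
        out = remove_subset_peptides(peptides)
        assert all(not (p != q and p in q) for p in out for q in out)
        # maximal elements always survive
        assert {p for p in peptides if not any(p != q and p in q for q in peptides)} <= out


class TestMapping:
    LIB = FederatedLibrary([ProteinRecord("MKVLA", ["P1"]),
                            ProteinRecord("TTTKVLTT", ["P2"])])

    def test_hit_and_miss(self):
        rows, unmapped = map_peptides_to_library({"KVL"}, self.LIB)
        assert [(p, r.primary_accession) for p, r in rows] == [("KVL", "P1"), ("KVL", "P2")]
        rows, unmapped = map_peptides_to_library({"WWW"}, self.LIB)
        assert rows == [] and unmapped == ["WWW"]

    def test_multi_offset_counted_once(self):
        lib = FederatedLibrary([ProteinRecord("AKAKAKA", ["P1"])])
        rows, _ = map_peptides_to_library({"AKA"}, lib)
        assert len(rows) == 1

    def test_total_rows_equal_bruteforce(self, rng):
        lib = FederatedLibrary(
            [ProteinRecord(_rand_pep(rng, 50, 120), [f"P{i}"]) for i in range(40)]
        )
        peps = {_rand_pep(rng, 3, 6) for _ in range(200)}
        rows, unmapped = map_peptides_to_library(peps, lib)
        expected = sum(1 for p in peps for r in lib if p in r.sequence)
        assert len(rows) == expected
        assert len(unmapped) == sum(1 for p in peps if not any(p in r.sequence for r in lib))


class TestCounts:
    def _store(self, observations, records):
        return build_evidence_store(observations, FederatedLibrary(records))

    def test_redundant_vs_distinct(self):
        store = self._store(
            [PeptideObservation("MKVLAR", "s1", spectral_count=5)],
            [ProteinRecord("WWMKVLARWW", ["P1"])],
        )
        row = store.protein_counts().iloc[0]
        assert (row.redundant_count, row.distinct_peptide_count) == (5, 1)

    def test_three_distinct_once_each(self):
        obs = [PeptideObservation(p, "s1") for p in ("MKVLAR", "TTTEEEK", "GGGHHHR")]
        store = self._store(obs, [ProteinRecord("MKVLARTTTEEEKGGGHHHR", ["P1"])])
        row = store.protein_counts().iloc[0]
        assert (row.redundant_count, row.distinct_peptide_count) == (3, 3)

    def test_counter_invariant_on_random_fixture(self, built):
        _, store = built
        df = store.protein_counts()
        assert (df.redundant_count >= df.distinct_peptide_count).all()
        assert (df.distinct_peptide_count >= df.unique_peptide_count).all()

    def test_duplicate_observation_changes_nothing_but_redundant(self):
        obs = [PeptideObservation("MKVLAR", "s1"), PeptideObservation("TTTEEEK", "s1")]
        recs = [ProteinRecord("MKVLARTTTEEEK", ["P1"])]
        before = self._store(obs, recs).protein_counts().iloc[0]
        after = self._store(obs + [PeptideObservation("MKVLAR", "s2")], recs)\
            .protein_counts().iloc[0]
        assert after.distinct_peptide_count == before.distinct_peptide_count
        assert after.unique_peptide_count == before.unique_peptide_count
        assert after.redundant_count == before.redundant_count + 1


class TestDistribution:
    def test_bins(self):
        store = build_evidence_store(
            [PeptideObservation("MKVLAR", "s1"),
             PeptideObservation("AAAEEEK", "s1"),
             PeptideObservation("CCCDDDR", "s1"),
             PeptideObservation("FFFGGGK", "s1")],
            FederatedLibrary([ProteinRecord("MKVLARWWWWWW", ["P1"]),
                              ProteinRecord("AAAEEEKCCCDDDRFFFGGGK", ["P2"])]),
        )
        table = peptide_protein_distribution(store, "distinct")
        assert dict(zip(table.bins, table.frequencies)) == {1: 1, 3: 1}
        assert table.total == 2

    def test_empty_store(self):
        store = build_evidence_store(
            [], FederatedLibrary([ProteinRecord("MKVLAR", ["P1"])])
        )
        assert peptide_protein_distribution(store).total == 0

    def test_matches_bruteforce_histogram(self, built):
        _, store = built
        counts = store.protein_counts()
        detected = counts[counts.distinct_peptide_count > 0]
        table = peptide_protein_distribution(store, "distinct")
        expected = detected.distinct_peptide_count.value_counts().to_dict()
        assert dict(zip(table.bins, table.frequencies)) == expected
        assert table.total == len(detected)


class TestUniquePeptides:
    def test_shared_only_excludes_both(self):
        store = build_evidence_store(
            [PeptideObservation("KVLAAA", "s1")],
            FederatedLibrary([ProteinRecord("MKVLAAAR", ["P1"]),
                              ProteinRecord("TKVLAAAW", ["P2"])]),
        )
        with_unique, high = unique_peptide_proteins(store)
        assert with_unique == set() and high == set()

    def test_one_unique_plus_two_shared_reaches_high_tier(self):
        lib = FederatedLibrary([
            ProteinRecord("AAAEEEKCCCDDDRUNIQUEPEPK", ["P1"]),
            ProteinRecord("AAAEEEKCCCDDDRWWW", ["P2"]),
        ])
        obs = [PeptideObservation(p, "s1")
               for p in ("AAAEEEK", "CCCDDDR", "UNIQUEPEPK")]
        with_unique, high = unique_peptide_proteins(build_evidence_store(obs, lib))
        assert with_unique == {"P1"}
        assert high == {"P1"}  # 3 distinct peptides in total

    def test_high_subset_of_with_unique(self, built):
        _, store = built
        with_unique, high = unique_peptide_proteins(store)
        assert high <= with_unique


class TestConfidenceTier:
    @pytest.mark.parametrize("count, tier",
                             [(1, "single"), (2, "double"), (3, "high"),
                              (17, "high")])
    def test_tiers(self, count, tier):
        assert confidence_tier(count) == tier

    def test_domain_error(self):
        with pytest.raises(ValueError):
            confidence_tier(0)


def test_distribution_table_from_values_conserves_total():
    t = DistributionTable.from_values("x", [1, 1, 2, "zero", 5])
    assert t.total == 5
    assert dict(zip(t.bins, t.frequencies)) == {1: 2, 2: 1, 5: 1, "zero": 1}
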