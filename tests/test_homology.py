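"""Pairwise alignment, the homology match criterion and type collapsing."""

import math
import random

import pytest
from Bio.Align import substitution_matrices

from fedprot.homology import (
    AlignmentResult,
    BlastTabularError,
    MatchCriterion,
    align_pair,
    alignment_distributions,
    all_pairs_alignments,
    collapse_types,
    import_blast_tabular,
    is_match,
    singleton_count,
    top_hit_per_query,
)
from fedprot.library import FederatedLibrary, ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
BLOSUM62 = substitution_matrices.load("BLOSUM62")


def gotoh_local_score(q, s, open_gap=11.0, extend_gap=1.0):
    """Independent affine-gap Smith-Waterman score by dynamic programming."""
    NEG = -math.inf
    n, m = len(q), len(s)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (along s)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_gap, E[i][j - 1] - extend_gap)
            F[i][j] = max(H[i - 1][j] - open_gap, F[i - 1][j] - extend_gap)
            sub = BLOSUM62[q[i - 1]][s[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestAlignPair:
    def test_self_alignment(self):
        r = align_pair("MKVLA", "MKVLA")
        assert (r.n_identities, r.mismatches, r.gap_openings) == (5, 0, 0)
        assert r.longest_perfect_run == 5
        assert r.alignment_length == 5
        assert r.query_length == 5

    def test_disjoint_alphabets_no_match_possible(self):
        r = align_pair("WWWWW", "GGGGG")
        assert r.n_identities == 0
        assert r.bitscore <= 0 or r.alignment_length == 0
        with pytest.raises(ValueError):
            align_pair("", "MKV")

    def test_single_substitution_run_is_longer_flank(self):
        left, right = "AKEHIGWNDVTRLM", "CQYFSPAKEHIGWND"
        base = left + "W" + right
        variant = left + "G" + right
        r = align_pair(base, variant)
        assert r.mismatches == 1
        assert r.n_identities == len(base) - 1
        # brute-force run scan over the (gapless) aligned pair
        runs, cur = [], 0
        for a, b in zip(base, variant):
            cur = cur + 1 if a == b else 0
            runs.append(cur)
        assert r.longest_perfect_run == max(runs) == len(right)

    def test_score_matches_gotoh_oracle_on_short_pairs(self):
        rng = random.Random(11)
        for _ in range(15):
            q = "".join(rng.choice(AA) for _ in range(rng.randint(8, 30)))
            s = "".join(rng.choice(AA) for _ in range(rng.randint(8, 30)))
            r = align_pair(q, s)
            assert r.bitscore == pytest.approx(gotoh_local_score(q, s))

    def test_identity_count_on_unambiguous_pair(self):
        q = "MKVLAREQSTWFNDHI"
        s = "MKVLAREQSTWFNDHI"[:10] + "GGGGG"
        r = align_pair(q, s)
        assert r.n_identities == 10
        assert r.bitscore == pytest.approx(gotoh_local_score(q, s))

    def test_invariants_hold_on_random_pairs(self):
        rng = random.Random(5)
        for _ in range(10):
            q = "".join(rng.choice(AA) for _ in range(40))
            s = "".join(rng.choice(AA) for _ in range(40))
            r = align_pair(q, s)
            assert r.n_identities <= r.alignment_length
            assert (r.longest_perfect_run or 0) <= r.alignment_length
            assert r.gap_openings >= 0


class TestImportBlastTabular:
    LINES = [
        "q1\ts1\t100.00\t50\t0\t0\t1\t50\t1\t50\t1e-30\t100",
        "q2\ts2\t80.00\t40\t8\t1\t1\t40\t5\t44\t0.001\t55.5",
    ]

    def test_fields_mapped(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("\n".join(self.LINES) + "\n")
        results = import_blast_tabular(p)
        assert results[0].n_identities == 50
        assert results[1].n_identities == 32  # round(80 * 40 / 100)
        assert results[1].gap_openings == 1
        assert results[1].e_value == pytest.approx(0.001)
        assert results[1].bitscore == pytest.approx(55.5)
        assert results[0].longest_perfect_run is None

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert import_blast_tabular(p) == []

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(self.LINES[0] + "\nq3\ts3\t50\n")
        with pytest.raises(BlastTabularError, match=":2"):
            import_blast_tabular(p)


def _result(frac, run, qlen=100, **kw):
    return AlignmentResult(
        "q", "s", n_identities=round(frac * qlen), alignment_length=qlen,
        mismatches=0, gap_openings=0, bitscore=50.0, query_length=qlen,
        longest_perfect_run=run, **kw,
    )


class TestIsMatch:
    def test_boundary_identity_exactly_075_fails(self):
        assert not is_match(_result(0.75, 25))

    def test_boundary_run_19_fails(self):
        assert not is_match(_result(0.80, 19))

    def test_both_satisfied(self):
        assert is_match(_result(0.80, 25))

    def test_monotone_in_both_parameters(self):
        r = _result(0.80, 25)
        for f in (0.5, 0.6, 0.7, 0.79):
            for run in (5, 10, 20, 25):
                tighter = MatchCriterion(min(f + 0.2, 1.0), run + 5)
                looser = MatchCriterion(f, run)
                if is_match(r, tighter):
                    assert is_match(r, looser)

    def test_incomplete_results_rejected(self):
        r = _result(0.9, None)
        with pytest.raises(ValueError, match="perfect-run"):
            is_match(r)
        r2 = _result(0.9, 25)
        r2.query_length = None
        with pytest.raises(ValueError, match="query_length"):
            is_match(r2)


class TestTopHit:
    def _hit(self, q, s, score, e=None):
        return AlignmentResult(q, s, 10, 20, 0, 0, score, query_length=20,
                               e_value=e, longest_perfect_run=10)

    def test_max_bitscore_wins(self):
        top = top_hit_per_query([self._hit("q", "a", 40), self._hit("q", "b", 50)])
        assert top["q"].subject_id == "b"

    def test_self_hit_omitted(self):
        assert top_hit_per_query([self._hit("q", "q", 99)]) == {}

    def test_tie_broken_by_evalue_then_subject(self):
        top = top_hit_per_query(
            [self._hit("q", "z", 50, e=1e-10), self._hit("q", "a", 50, e=1e-5)]
        )
        assert top["q"].subject_id == "z"
        top = top_hit_per_query(
            [self._hit("q", "z", 50, e=1e-10), self._hit("q", "a", 50, e=1e-10)]
        )
        assert top["q"].subject_id == "a"

    def test_enumerate_and_sort_oracle(self):
        rng = random.Random(3)
        hits = [self._hit(f"q{i % 4}", f"s{j}", rng.choice([30, 40, 50]), e=1e-8)
                for i in range(4) for j in range(6)]
        top = top_hit_per_query(hits)
        for q in {h.query_id for h in hits}:
            mine = [h for h in hits if h.query_id == q and h.subject_id != q]
            best = sorted(mine, key=lambda h: (-h.bitscore, h.e_value, h.subject_id))[0]
            assert top[q].subject_id == best.subject_id


def _family(prefix, base, n, rng):
    out = [ProteinRecord(base, [f"{prefix}1"])]
    for v in range(2, n + 1):
        seq = list(base)
        for pos in rng.sample(range(len(base) - 30), max(1, len(base) // 25)):
            seq[pos] = rng.choice([a for a in AA if a != base[pos]])
        out.append(ProteinRecord("".join(seq), [f"{prefix}{v}"]))
    return out


class TestCollapse:
    def test_no_edges_all_singletons(self):
        rng = random.Random(1)
        recs = [ProteinRecord("".join(rng.choice(AA) for _ in range(80)), [f"P{i}"])
                for i in range(5)]
        lib = FederatedLibrary(recs)
        clusters = collapse_types(lib, top_hit_per_query(all_pairs_alignments(lib)))
        assert len(clusters) == 5
        assert singleton_count(clusters) == 5

    def test_chain_closes_into_one_cluster(self):
        def hit(q, s):
            return AlignmentResult(q, s, 90, 100, 10, 0, 400.0, query_length=100,
                                   longest_perfect_run=40)
        rng = random.Random(2)
        recs = [ProteinRecord("".join(rng.choice(AA) for _ in range(100)), [f"P{i}"])
                for i in range(3)]
        lib = FederatedLibrary(recs)
        clusters = collapse_types(lib, {"P0": hit("P0", "P1"), "P1": hit("P1", "P2")})
        assert len(clusters) == 1
        assert sorted(clusters[0].members) == ["P0", "P1", "P2"]

    def test_planted_families_recovered(self):
        rng = random.Random(9)
        records = []
        for f in range(3):
            base = "".join(rng.choice(AA) for _ in range(150))
            records += _family(f"F{f}V", base, 3, rng)
        singles = [ProteinRecord("".join(rng.choice(AA) for _ in range(120)), [f"S{i}"])
                   for i in range(4)]
        lib = FederatedLibrary(records + singles)
        clusters = collapse_types(lib, top_hit_per_query(all_pairs_alignments(lib)))
        multi = [c for c in clusters if len(c) > 1]
        assert len(multi) == 3
        assert singleton_count(clusters) == 4
        for c in multi:
            assert len({m[:3] for m in c.members}) == 1  # one family prefix each

    def test_partition_property(self, built):
        report, _ = built
        assert (report.counters["protein_types"] <= report.counters["post_subset_proteins"])

    def test_tightening_never_decreases_cluster_count(self):
        rng = random.Random(9)
        records = []
        for f in range(2):
            base = "".join(rng.choice(AA) for _ in range(140))
            records += _family(f"G{f}V", base, 3, rng)
        lib = FederatedLibrary(records)
        hits = top_hit_per_query(all_pairs_alignments(lib))
        n_prev = 0
        for frac, run in [(0.5, 10), (0.75, 20), (0.9, 40), (0.99, 120)]:
            n = len(collapse_types(lib, hits, MatchCriterion(frac, run)))
            assert n >= n_prev
            n_prev = n

    def test_asymmetric_fragment_direction_still_clusters(self):
        rng = random.Random(4)
        parent_seq = "".join(rng.choice(AA) for _ in range(200))
        parent = ProteinRecord(parent_seq, ["PARENT"])
        frag = ProteinRecord(parent_seq[20:120], ["FRAG"])
        lib = FederatedLibrary([parent, frag])
        hits = top_hit_per_query(all_pairs_alignments(lib))
        # fragment-as-query matches its parent; parent-as-query does not
        assert is_match(hits["FRAG"])
        assert not is_match(hits["PARENT"])
        clusters = collapse_types(lib, hits)
        assert len(clusters) == 1
        assert clusters[0].representative == "PARENT"  # longest member


class TestAlignmentDistributions:
    def test_perfect_self_match_bins(self):
        r = align_pair("MKVLAREQSTWFNDHI", "MKVLAREQSTWFNDHI")
        tables = alignment_distributions([r])
        assert dict(zip(tables["gap_openings"].bins, tables["gap_openings"].frequencies)) == {0: 1}
        assert tables["mismatches"].bins == ["zero"]
        assert tables["percent_identity"].bins == [100]

    def test_machine_zero_bin(self):
        r = _result(0.9, 30, e_value=1e-200)
        tables = alignment_distributions([r])
        assert tables["e_value"].bins == ["machine_zero"]
        r2 = _result(0.9, 30, e_value=1e-30)
        assert alignment_distributions([r2])["e_value"].bins == [-30]

    def test_bin_totals_conserve_input_count(self):
        rng = random.Random(8)
        seqs = ["".join(rng.choice(AA) for _ in range(60)) for _ in range(10)]
        results = [align_pair(q, s) for q in seqs[:5] for s in seqs[5:]]
        assert len(results) == 25
        for table in alignment_distributions(results).values():
            assert table.total == 25
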