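"""Alignment engines, E-values, and duplication scanning."""

from functools import lru_cache
from types import SimpleNamespace

import math
import numpy as np
import pytest

from mirburst import dupscan, synthio

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 1, -2, -5, -2


def global_score(a: str, b: str) -> float:
    """Independent affine-gap global aligner (recursive with memo); gap of
    length L costs open + (L-1)*ext."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # state: 0 diag/start, 1 gap in b (consuming a), 2 gap in a
        if i == 0 and j == 0:
            return 0.0
        best = -math.inf
        if i > 0 and j > 0:
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            best = max(best, rec(i - 1, j - 1, 0) + s,
                       rec(i - 1, j - 1, 1) + s, rec(i - 1, j - 1, 2) + s)
        if i > 0:
            cost = GAP_EXT if state == 1 else GAP_OPEN
            prev = [rec(i - 1, j, 1)] if state == 1 else [
                rec(i - 1, j, 0), rec(i - 1, j, 2)]
            best = max([best] + [p + cost for p in prev])
        if j > 0:
            cost = GAP_EXT if state == 2 else GAP_OPEN
            prev = [rec(i, j - 1, 2)] if state == 2 else [
                rec(i, j - 1, 0), rec(i, j - 1, 1)]
            best = max([best] + [p + cost for p in prev])
        return best

    # proper affine accounting needs the state of the LAST column; evaluate
    # the best over end states by a small forward DP instead
    m, n = len(a), len(b)
    NEG = -math.inf
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)  # gap consuming a
    Y = np.full((m + 1, n + 1), NEG)  # gap consuming b
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        X[i, 0] = GAP_OPEN + (i - 1) * GAP_EXT
    for j in range(1, n + 1):
        Y[0, j] = GAP_OPEN + (j - 1) * GAP_EXT
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + GAP_OPEN, X[i - 1, j] + GAP_EXT,
                          Y[i - 1, j] + GAP_OPEN)
            Y[i, j] = max(M[i, j - 1] + GAP_OPEN, Y[i, j - 1] + GAP_EXT,
                          X[i, j - 1] + GAP_OPEN)
    return max(M[m, n], X[m, n], Y[m, n])


def brute_local(a: str, b: str) -> float:
    """Best global score over all substring pairs (empty pair scores 0)."""
    best = 0.0
    for i in range(len(a)):
        for j in range(i + 1, len(a) + 1):
            for k in range(len(b)):
                for l in range(k + 1, len(b) + 1):
                    best = max(best, global_score(a[i:j], b[k:l]))
    return best


def brute_glocal(q: str, t: str) -> float:
    """Best global score of the whole query vs any target substring."""
    best = -math.inf
    for k in range(len(t) + 1):
        for l in range(k, len(t) + 1):
            best = max(best, global_score(q, t[k:l]))
    return best


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestLocalAlign:
    def test_identical(self):
        h = dupscan.local_align("ACGT", "ACGT")
        assert h.score == 4 and h.identity == 1.0

    def test_best_substring(self):
        h = dupscan.local_align("ACGT", "AGGT")
        assert h.score == 2.0  # "GT"

    def test_matches_bruteforce(self, rng):
        for _ in range(200):
            a = rand_seq(rng, int(rng.integers(1, 13)))
            b = rand_seq(rng, int(rng.integers(1, 13)))
            assert dupscan.local_align(a, b).score == pytest.approx(
                brute_local(a, b)
            )

    def test_score_symmetry(self, rng):
        for _ in range(30):
            a = rand_seq(rng, int(rng.integers(4, 15)))
            b = rand_seq(rng, int(rng.integers(4, 15)))
            assert dupscan.local_align(a, b).score == dupscan.local_align(b, a).score

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            dupscan.local_align("", "ACGT")
        with pytest.raises(ValueError):
            dupscan.local_align("ACXT", "ACGT")


class TestGlocalAlign:
    def test_embedded_query(self):
        q = "ACGTAC"
        h = dupscan.glocal_align(q, "TTTT" + q + "GGGG")
        assert h.score == len(q) and h.coverage(len(q)) == 1.0
        assert (h.t_start, h.t_end) == (4, 10)

    def test_matches_enumeration(self, rng):
        for _ in range(150):
            q = rand_seq(rng, int(rng.integers(1, 7)))
            t = rand_seq(rng, int(rng.integers(len(q), 11)))
            assert dupscan.glocal_align(q, t).score == pytest.approx(
                brute_glocal(q, t)
            )

    def test_query_longer_than_target_rejected(self):
        with pytest.raises(ValueError):
            dupscan.glocal_align("ACGTACGT", "ACG")

    def test_random_target_identity_near_background(self, rng):
        """Whole-query identity against unrelated sequence sits near the
        1/4 background expectation, far below duplicate-level identity."""
        idents = []
        for _ in range(40):
            q = rand_seq(rng, 60)
            t = rand_seq(rng, 400)
            idents.append(dupscan.glocal_align(q, t).identity)
        assert 0.2 < np.mean(idents) < 0.55


class TestKarlinAltschul:
    def test_lambda_solves_equation(self):
        ka = dupscan.solve_ka(1, -2)
        resid = 0.25 * math.exp(ka.lam) + 0.75 * math.exp(-2 * ka.lam) - 1.0
        assert abs(resid) < 1e-9
        assert round(ka.lam, 2) == 1.33

    def test_evalue_monotone_in_score(self):
        ka = dupscan.solve_ka()
        es = [dupscan.evalue(s, 100, 100, ka) for s in range(1, 30)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_evalue_linear_in_search_space(self):
        ka = dupscan.solve_ka()
        assert dupscan.evalue(20, 100, 200, ka) == pytest.approx(
            2 * dupscan.evalue(20, 100, 100, ka)
        )

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            dupscan.solve_ka(1, -0.1)


class TestAllVsAll:
    def test_identical_pair_kept(self, rng):
        seq = rand_seq(rng, 100)
        hits = dupscan.allvsall_similarity({"a": seq, "b": seq})
        assert len(hits) == 1
        assert hits[0].evalue < 1e-5 and hits[0].coverage(100) == 1.0

    def test_random_pairs_rejected(self, rng):
        prec = {f"r{k}": rand_seq(rng, 100) for k in range(15)}
        assert dupscan.allvsall_similarity(prec) == []

    def test_planted_family_recovered(self, small_world):
        _, truth, _ = small_world
        prec = {r.mirna_id: r.sequence for r in truth.table.itertuples()}
        hits = dupscan.allvsall_similarity(prec)
        found = {tuple(sorted((h.query_id, h.target_id))) for h in hits}
        for fam, grp in truth.table.groupby("family"):
            ids = list(grp.mirna_id)
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    assert tuple(sorted((a, b))) in found

    def test_needs_two(self):
        with pytest.raises(ValueError):
            dupscan.allvsall_similarity({"a": "ACGT"})


class TestDivergence:
    def test_identical_zero(self):
        h = dupscan.local_align("ACGTACGTAC", "ACGTACGTAC")
        assert dupscan.divergence_rate(h) == 0.0

    def test_percentage_arithmetic(self):
        h = dupscan.AlignmentHit("a", "b", 61, 100, 87, 13, 0, 0, 100, 0, 100)
        assert dupscan.divergence_rate(h) == 13.0

    def test_hand_counted_toy_alignment(self):
        # AACGT-TT vs AAGGTATT: 1 mismatch + 1 gap column in 8 columns
        h = dupscan.glocal_align("AACGTTT", "AAGGTATT")
        assert dupscan.divergence_rate(h) == pytest.approx(
            100 * (h.mismatches + h.gap_cols) / h.aligned_cols
        )
        assert dupscan.divergence_rate(h, count_gaps=False) == pytest.approx(
            100 * h.mismatches / (h.matches + h.mismatches)
        )


class TestFamilies:
    def test_no_pairs_all_singletons(self):
        fams = dupscan.family_cluster([], ids=["a", "b", "c"])
        assert sorted(map(len, fams)) == [1, 1, 1]

    def test_planted_families_form_components(self, small_world):
        _, truth, _ = small_world
        prec = {r.mirna_id: r.sequence for r in truth.table.itertuples()}
        hits = dupscan.allvsall_similarity(prec)
        fams = dupscan.family_cluster(hits, ids=list(prec))
        comp_of = {m: i for i, f in enumerate(fams) for m in f}
        for fam, grp in truth.table.groupby("family"):
            ids = list(grp.mirna_id)
            assert len({comp_of[m] for m in ids}) == 1

    def test_consensus_of_identical_members(self):
        cons, ties = dupscan.family_consensus(
            {"a", "b"}, {"a": "ACGTACGTAA", "b": "ACGTACGTAA"}
        )
        assert cons == "ACGTACGTAA" and ties == []


class TestFlankScan:
    def test_planted_copy_distance(self, rng):
        base = rand_seq(rng, 100)
        left = rand_seq(rng, 500)
        gap = rand_seq(rng, 3000)
        right = rand_seq(rng, 500)
        genome = {"s": left + base + gap + base + right}
        call = SimpleNamespace(id="m1", scaffold="s", start=500, end=600,
                               strand="+")
        hits = dupscan.flank_scan(genome, [call], window=5000)
        assert len(hits) == 1
        assert abs(hits[0].distance - 3000) <= 1
        assert hits[0].alignment.identity >= 0.99

    def test_original_span_excluded(self, rng):
        base = rand_seq(rng, 100)
        genome = {"s": rand_seq(rng, 300) + base + rand_seq(rng, 300)}
        call = SimpleNamespace(id="m1", scaffold="s", start=300, end=400,
                               strand="+")
        hits = dupscan.flank_scan(genome, [call], window=400)
        assert all(not (h.start < 400 and 300 < h.end) for h in hits)

    def test_random_flanks_yield_nothing(self, rng):
        genome = {"s": rand_seq(rng, 4000)}
        call = SimpleNamespace(id="m1", scaffold="s", start=1900, end=2000,
                               strand="+")
        hits = dupscan.flank_scan(genome, [call], window=1900)
        assert len(hits) == 0

    def test_reverse_strand_copy_found(self, rng):
        base = rand_seq(rng, 100)
        rc = dupscan.revcomp(base)
        genome = {"s": rand_seq(rng, 200) + base + rand_seq(rng, 1000) + rc
                  + rand_seq(rng, 200)}
        call = SimpleNamespace(id="m1", scaffold="s", start=200, end=300,
                               strand="+")
        hits = dupscan.flank_scan(genome, [call], window=1500)
        assert any(h.strand == "-" and abs(h.distance - 1000) <= 1 for h in hits)


def test_compare_genomes_tabulates_per_genome(rng):
    base = rand_seq(rng, 100)
    g1 = {"s": rand_seq(rng, 300) + base + rand_seq(rng, 2000) + base
          + rand_seq(rng, 300)}
    g2 = {"s": rand_seq(rng, 3000)}  # no duplicate
    call1 = SimpleNamespace(id="m1", scaffold="s", start=300, end=400,
                            strand="+")
    call2 = SimpleNamespace(id="m1", scaffold="s", start=1400, end=1500,
                            strand="+")
    table = dupscan.compare_genomes(
        [("dup-rich", g1, [call1]), ("dup-poor", g2, [call2])], window=2_500
    )
    assert table.loc["dup-rich", "total"] >= 1
    assert table.loc["dup-poor", "total"] == 0
    assert list(table.columns[:2]) == ["[0,5000)", "[5000,10000)"]


class TestDistanceHistogram:
    def make(self, distances):
        return [
            SimpleNamespace(distance=d) for d in distances
        ]

    def test_bin_boundaries(self):
        counts, dropped = dupscan.distance_histogram(self.make([100, 4999, 5000]))
        assert list(counts[:3]) == [2, 1, 0] and dropped == 0

    def test_empty(self):
        counts, dropped = dupscan.distance_histogram([])
        assert counts.sum() == 0 and dropped == 0

    def test_conservation(self, rng):
        ds = rng.integers(0, 80_000, size=60)
        counts, dropped = dupscan.distance_histogram(self.make(list(ds)))
        assert counts.sum() + dropped == 60
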