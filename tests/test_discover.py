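"""Read mapping, candidate excision, evidence scoring, and classification."""

import numpy as np
import pytest

from mirburst import discover, fold, sio, synthio
from mirburst.discover import MiRNACall
from mirburst.sio import AnnotationInterval, AnnotationIntervals, CollapsedRead


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestMapReads:
    def test_unique_hit_at_planted_offset(self, rng):
        genome = sio.ScaffoldSet()
        genome["s"] = rand_seq(rng, 2000)
        read = genome["s"][700:722]
        maps, nd = discover.map_reads(genome, [CollapsedRead("r", read, 4)])
        fw = [m for m in maps if m.strand == "+"]
        assert len(fw) == 1 and fw[0].start == 700 and fw[0].count == 4

    def test_multimapper_discarded(self, rng):
        unit = rand_seq(rng, 22)
        genome = sio.ScaffoldSet()
        genome["s"] = ("TTTT".join([unit] * 6)) + rand_seq(rng, 100)
        maps, nd = discover.map_reads(genome, [CollapsedRead("r", unit, 3)],
                                      max_hits=5)
        assert nd == 1 and maps == []

    def test_matches_bruteforce_scan(self, rng):
        genome = sio.ScaffoldSet()
        genome["s"] = rand_seq(rng, 10_000)
        seq = genome["s"]
        reads = []
        for k in range(50):
            if k % 2:
                p = int(rng.integers(0, len(seq) - 22))
                reads.append(CollapsedRead(f"r{k}", seq[p : p + 22], 1))
            else:
                reads.append(CollapsedRead(f"r{k}", rand_seq(rng, 22), 1))
        maps, _ = discover.map_reads(genome, reads, max_hits=1000)
        got = {(m.read_id, m.start, m.strand) for m in maps}
        want = set()
        for r in reads:
            for strand, s in (("+", r.sequence), ("-", revcomp(r.sequence))):
                start = seq.find(s)
                while start != -1:
                    want.add((r.id, start, strand))
                    start = seq.find(s, start + 1)
        assert got == want

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            discover.map_reads(sio.ScaffoldSet(), [])


def make_perfect_candidate(rng, n_reads=20, copies=10):
    """A clean planted hairpin with modal 5P/3P duplex reads."""
    cfg = synthio.SimConfig(seed=3, n_scaffolds=1, scaffold_length=8_000,
                            n_mirnas=1, n_families=0, n_tissue_specific=0,
                            n_conserved=0)
    genome, truth = synthio.generate_genome(cfg)
    row = truth.table.iloc[0]
    seq = row.sequence
    s = fold.fold_mfe(seq)
    pairs = sorted(s.pairs)
    il, jl = pairs[-1]
    m5 = (row.m5_start - row.start, row.m5_end - row.start)
    m3 = (row.m3_start - row.start, row.m3_end - row.start)
    reads = []
    for k in range(n_reads):
        span = m5 if k % 5 else m3
        reads.append((span[0], span[1], copies, f"r{k}"))
    return discover.Candidate(
        scaffold=row.scaffold, start=row.start, end=row.end, strand="+",
        sequence=seq, structure=s, z=-5.0, reads=reads,
        arm5=(0, il + 1 + 3), arm3=(max(0, jl - 3), len(seq)),
    )


class TestScoring:
    def test_perfect_candidate(self, rng):
        c = make_perfect_candidate(rng)
        s = discover.score_candidate(c)
        n = sum(r[2] for r in c.reads)
        assert s.s_duplex == 2.0
        assert s.s_reads == pytest.approx(np.log2(n + 1))
        assert s.s_struct == 5.0
        assert s.total == pytest.approx(s.s_reads + s.s_duplex + s.s_struct)

    def test_scattered_reads_score_nonpositive(self, rng):
        c = make_perfect_candidate(rng)
        wlen = len(c.sequence)
        scattered = []
        for k in range(40):
            a = int(rng.integers(0, wlen - 22))
            scattered.append((a, a + 22, 1, f"x{k}"))
        s = discover.score_candidate(c, reads=scattered)
        assert s.s_reads <= 1.0  # no positional consistency bonus

    def test_unfolded_candidate_rejected(self, rng):
        c = make_perfect_candidate(rng)
        c.structure = None
        with pytest.raises(ValueError):
            discover.score_candidate(c)


class TestSignalToNoise:
    def test_null_candidates_have_unit_sn(self, rng):
        """Candidates whose reads are already uniform score the same as
        their permutations: S/N stays near 1 over the occupied range."""
        cands = []
        for k in range(30):
            c = make_perfect_candidate(rng)
            wlen = len(c.sequence)
            c.reads = [
                (a, min(wlen, a + 22), 2, f"n{k}_{j}")
                for j in range(10)
                for a in [int(rng.integers(0, wlen - 22))]
            ]
            c.score = None
            cands.append(c)
        tab = discover.signal_to_noise(cands, n_perm=40, seed=1)
        occupied = tab[(tab.n_real >= 5) & np.isfinite(tab.sn)]
        assert (occupied.sn < 3.0).all()

    def test_planted_signal_sn_increases(self, rng):
        cands = [make_perfect_candidate(rng) for _ in range(10)]
        for c in cands:
            c.score = None
        tab = discover.signal_to_noise(cands, n_perm=40, seed=2)
        cut = discover.choose_cutoff(tab, target_sn=10)
        assert cut is not None
        totals = [discover.score_candidate(c).total for c in cands]
        assert sum(t >= cut for t in totals) == len(cands)

    def test_requires_candidates(self):
        with pytest.raises(ValueError):
            discover.signal_to_noise([], n_perm=100)


class TestAnnotationFilter:
    def call(self, start, end, scaffold="s"):
        return MiRNACall("m", scaffold, start, end, "+", "A" * (end - start))

    def test_overlap_removed_with_reason(self):
        ann = AnnotationIntervals([AnnotationInterval("s", 50, 150, "+", "rRNA")])
        kept, reasons = discover.filter_annotations([self.call(100, 200)], ann)
        assert kept == [] and reasons == {"rRNA": 1}

    def test_half_open_boundary_kept(self):
        ann = AnnotationIntervals([AnnotationInterval("s", 50, 100, "+", "CDS")])
        kept, reasons = discover.filter_annotations([self.call(100, 200)], ann)
        assert len(kept) == 1 and reasons == {}

    def test_empty_annotations_identity(self):
        calls = [self.call(0, 50), self.call(60, 120)]
        kept, _ = discover.filter_annotations(calls, AnnotationIntervals())
        assert kept == calls

    def test_never_removes_non_overlapping(self, rng):
        """Interval-stabbing oracle: removal iff a >= 1 bp overlap exists."""
        calls = [self.call(int(a), int(a) + 90) for a in rng.integers(0, 5000, 40)]
        ann = AnnotationIntervals([
            AnnotationInterval("s", int(a), int(a) + 60, "+", "repeat")
            for a in rng.integers(0, 5000, 15)
        ])
        kept, _ = discover.filter_annotations(calls, ann)
        for c in calls:
            overlaps = any(iv.start < c.end and c.start < iv.end for iv in ann)
            assert (c not in kept) == overlaps


class TestHomologyClassification:
    REF = {"mir-x": "TGAGGTAGTAGGTTGTATAGTT"}

    def test_identical_is_conserved(self):
        label, fam = discover.classify_homology(self.REF["mir-x"], self.REF)
        assert label == "conserved" and fam == "mir-x"

    def test_seed_mismatch_rejected(self):
        m = list(self.REF["mir-x"])
        m[3] = "C" if m[3] != "C" else "G"  # seed position 4
        label, _ = discover.classify_homology("".join(m), self.REF)
        assert label == "lineage-specific"

    def test_three_adjacent_mismatches_rejected(self):
        m = list(self.REF["mir-x"])
        for k in (11, 12, 13):  # positions 12-14, outside the seed
            m[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[m[k]]
        label, _ = discover.classify_homology("".join(m), self.REF)
        assert label == "lineage-specific"

    def test_two_adjacent_mismatches_tolerated(self):
        m = list(self.REF["mir-x"])
        for k in (11, 12):
            m[k] = {"A": "C", "C": "A", "G": "T", "T": "G"}[m[k]]
        label, fam = discover.classify_homology("".join(m), self.REF)
        assert label == "conserved" and fam == "mir-x"

    def test_empty_reference_all_lineage(self):
        label, fam = discover.classify_homology("A" * 22, {})
        assert label == "lineage-specific" and fam is None


class TestHomologScan:
    def test_planted_conserved_found(self, small_world):
        genome, truth, _ = small_world
        refs = synthio.reference_matures(truth, genome)
        calls = discover.homolog_scan(genome, refs)
        found = set()
        for c in calls:
            for r in truth.table.itertuples():
                if (r.scaffold == c.scaffold
                        and min(r.end, c.end) - max(r.start, c.start)
                        >= 0.5 * (r.end - r.start)):
                    found.add(r.mirna_id)
        conserved = set(
            truth.table[truth.table.class_label == "conserved"].mirna_id
        )
        assert len(found & conserved) >= 0.75 * len(conserved)

    def test_mature_in_unstructured_background_dropped(self, rng):
        genome = sio.ScaffoldSet()
        mature = rand_seq(rng, 22)
        genome["s"] = rand_seq(rng, 600) + mature + rand_seq(rng, 600)
        calls = discover.homolog_scan(genome, {"fam": mature}, score_min=70)
        assert all(c.start > 650 or c.end < 550 for c in calls) or not calls

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            discover.homolog_scan(sio.ScaffoldSet(), {})


class TestMergeCalls:
    def mk(self, cid, start, end, prov):
        return MiRNACall(cid, "s", start, end, "+", "A" * (end - start),
                         provenance=prov)

    def test_disjoint_sets_union(self):
        a = [self.mk("a1", 0, 100, "sequencing")]
        b = [self.mk("b1", 500, 600, "homology")]
        merged, report = discover.merge_call_sets(a, b)
        assert len(merged) == 2 and report.n_both.iloc[0] == 0

    def test_identical_sets_all_both(self):
        a = [self.mk("a1", 0, 100, "sequencing"), self.mk("a2", 300, 400, "sequencing")]
        b = [self.mk("b1", 0, 100, "homology"), self.mk("b2", 300, 400, "homology")]
        merged, report = discover.merge_call_sets(a, b)
        assert len(merged) == 2
        assert all(c.provenance == "both" for c in merged)

    def test_partial_overlap_below_half_not_merged(self):
        a = [self.mk("a1", 0, 100, "sequencing")]
        b = [self.mk("b1", 60, 220, "homology")]
        merged, _ = discover.merge_call_sets(a, b)
        assert len(merged) == 2


def test_excise_stack_at_scaffold_edge(rng):
    """Stacks at scaffold boundaries must not index out of range."""
    genome = sio.ScaffoldSet()
    genome["s"] = rand_seq(rng, 300)
    maps = [
        discover.ReadMapping("r1", "s", 0, "+", 22, 0, 1, 5),
        discover.ReadMapping("r2", "s", 278, "+", 22, 0, 1, 5),
    ]
    cands = discover.excise_candidates(genome, maps, n_shuffles=10, seed=0)
    for c in cands:
        assert 0 <= c.start < c.end <= 300


def test_excise_requires_mappings(small_world):
    genome, _, _ = small_world
    with pytest.raises(ValueError):
        discover.excise_candidates(genome, [])
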