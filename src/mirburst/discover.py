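"""Evidence-based miRNA discovery from small-RNA read stacks.

The sequencing-based path maps collapsed reads to the genome, merges
overlapping hits into read stacks, excises candidate precursor windows by
110-nt extension on either side of each stack, folds them, and keeps windows
that look like hairpins and fold significantly better than their
dinucleotide-shuffled controls.  Candidates are scored on three signals —
read-position consistency, Dicer-duplex geometry (the 2-nt 3' overhang), and
folding stability — and a score cutoff is calibrated by the signal-to-noise
ratio over permuted read positions.  A homology path maps reference matures
onto the genome and keeps hits that fold into hairpins; the two call sets
are merged with provenance.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fold as _fold
from .sio import AnnotationIntervals, CollapsedRead, ScaffoldSet

__all__ = [
    "ReadMapping",
    "Candidate",
    "EvidenceScore",
    "MiRNACall",
    "map_reads",
    "excise_candidates",
    "score_candidate",
    "signal_to_noise",
    "choose_cutoff",
    "filter_annotations",
    "classify_homology",
    "homolog_scan",
    "merge_call_sets",
    "calls_from_candidates",
    "dedupe_candidates",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ReadMapping:
    read_id: str
    scaffold: str
    start: int  # 0-based, forward-strand coordinates
    strand: str
    length: int
    mismatches: int
    n_genomic_hits: int
    count: int = 1

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class EvidenceScore:
    """Surrogate evidence score; total is the sum of the three components."""

    s_reads: float
    s_duplex: float
    s_struct: float

    @property
    def total(self) -> float:
        return self.s_reads + self.s_duplex + self.s_struct


@dataclass
class Candidate:
    """An excised, folded precursor window with its read stack."""

    scaffold: str
    start: int  # genome coordinates of the (trimmed) window
    end: int
    strand: str
    sequence: str  # folded orientation
    structure: "_fold.SecondaryStructure"
    z: float
    reads: list = field(default_factory=list)  # (rel_start, rel_end, count, id)
    arm5: tuple[int, int] = (0, 0)  # window-relative, folded orientation
    arm3: tuple[int, int] = (0, 0)
    score: EvidenceScore | None = None

    def classify_read(self, rs: int, re: int) -> str:
        if rs >= self.arm5[0] and re <= self.arm5[1]:
            return "5p"
        if rs >= self.arm3[0] and re <= self.arm3[1]:
            return "3p"
        if rs < 0 or re > len(self.sequence):
            return "outside"
        return "loop"


@dataclass
class MiRNACall:
    id: str
    scaffold: str
    start: int
    end: int
    strand: str
    sequence: str
    mature5: tuple[int, int] | None = None  # genome coordinates
    mature3: tuple[int, int] | None = None
    star: tuple[int, int] | None = None
    mature5_seq: str | None = None
    mature3_seq: str | None = None
    score: EvidenceScore | None = None
    class_label: str = "lineage-specific"
    family: str | None = None
    provenance: str = "sequencing"

    @property
    def score_total(self) -> float | None:
        return self.score.total if self.score is not None else None


# ---------------------------------------------------------------------------
# read mapping


def _segment_hits(read: str, scaffolds: dict, max_mismatch: int):
    """Pigeonhole search: all (scaffold, start) where ``read`` matches with
    at most ``max_mismatch`` substitutions (forward orientation)."""
    L = len(read)
    nseg = max_mismatch + 1
    k = L // nseg
    hits = []
    for name, seq in scaffolds.items():
        offsets = set()
        for seg in range(nseg):
            s = seg * k
            e = L if seg == nseg - 1 else s + k
            piece = read[s:e]
            pos = seq.find(piece)
            while pos != -1:
                off = pos - s
                if 0 <= off <= len(seq) - L:
                    offsets.add(off)
                pos = seq.find(piece, pos + 1)
        for off in sorted(offsets):
            mm = sum(a != b for a, b in zip(read, seq[off : off + L]))
            if mm <= max_mismatch:
                hits.append((name, off, mm))
    return hits


def map_reads(
    genome: ScaffoldSet,
    reads: list[CollapsedRead],
    max_mismatch: int = 0,
    max_hits: int = 5,
) -> tuple[list[ReadMapping], int]:
    """Map collapsed reads to both strands of the genome.

    All hits with at most ``max_mismatch`` substitutions are reported; reads
    with more than ``max_hits`` genomic hits are discarded entirely (the
    repeat-derived multimapper rule) and tallied.  Returns
    ``(mappings, n_multimapper_reads_discarded)``.
    """
    if not genome:
        raise ValueError("genome is empty")
    mappings: list[ReadMapping] = []
    n_discarded = 0
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        found = []
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for name, off, mm in _segment_hits(s, genome, max_mismatch):
                found.append((name, off, strand, mm))
        if len(found) > max_hits:
            n_discarded += 1
            continue
        for name, off, strand, mm in found:
            mappings.append(
                ReadMapping(
                    read.id, name, off, strand, len(seq), mm, len(found),
                    read.count,
                )
            )
    return mappings, n_discarded


# ---------------------------------------------------------------------------
# candidate excision


def _drop_short_ladders(struct, min_run: int = 3):
    """Remove helices of fewer than ``min_run`` pairs (thermodynamically
    marginal under the pair-weight model) before hairpin-shape testing."""
    keep = []
    for run in _fold.ladders(struct):
        if len(run) >= min_run:
            keep.extend(run)
    return _fold.SecondaryStructure(struct.sequence, sorted(keep), struct.energy)


def _stacks(mappings):
    """Maximal runs of overlapping same-strand hits, per scaffold."""
    groups = defaultdict(list)
    for m in mappings:
        groups[(m.scaffold, m.strand)].append(m)
    stacks = []
    for (scaf, strand), ms in sorted(groups.items()):
        ms.sort(key=lambda m: (m.start, m.end))
        cur = [ms[0]]
        cur_end = ms[0].end
        for m in ms[1:]:
            if m.start < cur_end:
                cur.append(m)
                cur_end = max(cur_end, m.end)
            else:
                stacks.append((scaf, strand, cur))
                cur = [m]
                cur_end = m.end
        stacks.append((scaf, strand, cur))
    return stacks


def _hairpin_at(seq: str, span_lo: int, span_hi: int, margin: int = 5):
    """Fold a window, trim it to the hairpin ladder overlapping
    [span_lo, span_hi), and refold.

    Returns ``(sub, struct, t_lo, t_hi)`` for the trimmed window, or None
    when no ladder of >= 3 pairs overlaps the span or the trimmed structure
    is not a single stem-loop.
    """
    first = _fold.fold_mfe(seq)
    best_run = None
    for run in _fold.ladders(first):
        if len(run) < 3:
            continue
        lo, hi = run[0][0], run[0][1] + 1
        if lo < span_hi and span_lo < hi:  # ladder overlaps the span
            if best_run is None or len(run) > len(best_run):
                best_run = run
    if best_run is None:
        return None
    t_lo = max(0, min(best_run[0][0], span_lo) - margin)
    t_hi = min(len(seq), max(best_run[0][1] + 1, span_hi) + margin)
    sub = seq[t_lo:t_hi]
    struct = _drop_short_ladders(_fold.fold_mfe(sub))
    flag, _stem, _pf = _fold.is_hairpin(struct)
    if not flag:
        return None
    return sub, struct, t_lo, t_hi


def _excise_window(
    genome, scaf, strand, w_start, w_end, stack, cfg, rng, strand_maps=None
) -> Candidate | None:
    """Excise a hairpin candidate from one extension window.

    Under a maximal-pairing energy model a long window folds into large
    nested structures that bury the precursor, so the window is scanned as
    a series of nested sub-windows anchored at the read stack (largest
    first); the first sub-window whose stack-overlapping ladder refolds into
    a clean single stem-loop is taken, then the MFE criteria are applied.
    """
    scaf_len = len(genome[scaf])
    w_start, w_end = max(0, w_start), min(scaf_len, w_end)
    if w_end - w_start < 40:
        return None
    seq = genome[scaf][w_start:w_end]
    if strand == "-":
        seq = _revcomp(seq)
    wlen = len(seq)

    def to_window(m):
        if strand == "+":
            return m.start - w_start, m.end - w_start
        return w_end - m.end, w_end - m.start

    rels = [(*to_window(m), m.count, m.read_id) for m in stack]
    stack_lo = max(0, min(r[0] for r in rels))
    stack_hi = min(wlen, max(r[1] for r in rels))
    anchored_down = stack_lo <= wlen - stack_hi  # stack sits at the 5' edge

    trimmed = None
    for ext in cfg["extension_grid"]:
        if anchored_down:
            sub_lo, sub_hi = stack_lo, min(wlen, stack_hi + ext)
        else:
            sub_lo, sub_hi = max(0, stack_lo - ext), stack_hi
        if sub_hi - sub_lo < 40:
            continue
        got = _hairpin_at(seq[sub_lo:sub_hi], stack_lo - sub_lo,
                          stack_hi - sub_lo)
        if got is not None:
            sub, struct, t_lo, t_hi = got
            t_lo, t_hi = sub_lo + t_lo, sub_lo + t_hi
            trimmed = (sub, struct, t_lo, t_hi)
            break
    if trimmed is None:
        return None
    sub, struct, t_lo, t_hi = trimmed
    if struct.energy > cfg["energy_per_nt"] * len(sub):
        return None
    z = _fold.mfe_z(sub, n_shuffles=cfg["n_shuffles"], seed=rng)
    if z > cfg["mfe_z_max"]:
        return None
    pairs = sorted(struct.pairs)
    il, jl = pairs[-1]  # innermost pair of the single ladder
    slack = cfg["arm_slack"]
    g_start = w_start + t_lo if strand == "+" else w_start + (wlen - t_hi)
    g_end = w_start + t_hi if strand == "+" else w_start + (wlen - t_lo)
    # attach every same-strand read overlapping the trimmed window, not just
    # the seeding stack: both arms' stacks contribute duplex evidence
    if strand_maps is not None:
        rels = [
            (*to_window(m), m.count, m.read_id)
            for m in strand_maps
            if m.start < g_end and m.end > g_start
        ]
    cand = Candidate(
        scaffold=scaf,
        start=g_start,
        end=g_end,
        strand=strand,
        sequence=sub,
        structure=struct,
        z=z,
        reads=[(rs - t_lo, re - t_lo, c, rid) for rs, re, c, rid in rels],
        arm5=(0, il + 1 + slack),
        arm3=(max(0, jl - slack), len(sub)),
    )
    return cand


def excise_candidates(
    genome: ScaffoldSet,
    mappings: list[ReadMapping],
    extension: int = 110,
    n_shuffles: int = 30,
    mfe_z_max: float = -1.5,
    energy_per_nt: float = -0.2,
    arm_slack: int = 3,
    seed: int = 0,
) -> list[Candidate]:
    """Excise and fold candidate precursors around read stacks.

    For each stack two windows are tried — stack plus ``extension`` nt
    downstream, and ``extension`` nt upstream plus stack — mirroring the two
    possible hairpin orientations.  Windows are trimmed to the hairpin
    ladder that overlaps the stack; windows failing the single-stem-loop
    test or the folding criterion (mfe_z <= ``mfe_z_max`` and energy <=
    ``energy_per_nt`` x length) are dropped.
    """
    if not mappings:
        raise ValueError("no read mappings")
    rng = np.random.default_rng(seed)
    grid = list(range(extension, 20, -15))
    cfg = {
        "n_shuffles": n_shuffles,
        "mfe_z_max": mfe_z_max,
        "energy_per_nt": energy_per_nt,
        "arm_slack": arm_slack,
        "extension_grid": grid,
    }
    by_strand = defaultdict(list)
    for m in mappings:
        by_strand[(m.scaffold, m.strand)].append(m)
    for ms in by_strand.values():
        ms.sort(key=lambda m: m.start)
    out: list[Candidate] = []
    for scaf, strand, stack in _stacks(mappings):
        s = min(m.start for m in stack)
        e = max(m.end for m in stack)
        windows = (
            (s, e + extension) if strand == "+" else (s - extension, e),
            (s - extension, e) if strand == "+" else (s, e + extension),
        )
        for w_start, w_end in windows:
            cand = _excise_window(genome, scaf, strand, w_start, w_end, stack,
                                  cfg, rng,
                                  strand_maps=by_strand[(scaf, strand)])
            if cand is not None:
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# scoring


def _modal_product(reads):
    """Copy-weighted modal (5' end, 3' end) among a set of window-relative
    read spans; returns None for an empty set."""
    if not reads:
        return None
    end5 = defaultdict(float)
    for rs, _re, c, _i in reads:
        end5[rs] += c
    m5 = sorted(end5, key=lambda k: (-end5[k], k))[0]
    same5 = [r for r in reads if r[0] == m5]
    end3 = defaultdict(float)
    for _rs, re, c, _i in same5:
        end3[re] += c
    m3 = sorted(end3, key=lambda k: (-end3[k], k))[0]
    return m5, m3


def _partner_near(pm: dict, pos: int, radius: int = 2):
    """Pairing partner of ``pos``, adjusted along the helix diagonal if the
    exact position is unpaired."""
    for d in range(radius + 1):
        for sd in ((d,) if d == 0 else (d, -d)):
            p = pos + sd
            if p in pm:
                return pm[p] + sd
    return None


def score_candidate(c: Candidate, reads=None) -> EvidenceScore:
    """Three-component evidence score for a folded candidate.

    S_reads: log2 odds of position-consistent vs inconsistent reads, where a
    consistent read lies fully in an arm with its 5' end within +/-2 nt of
    its arm's modal 5' end.  S_duplex: +2 if the modal 5P and 3P products
    form a duplex with a 2(+/-1)-nt 3' overhang on both strands, else -2.
    S_struct: the negated folding z-score.
    """
    if c.structure is None:
        raise ValueError("candidate is not folded")
    reads = c.reads if reads is None else reads
    arms = {"5p": [], "3p": []}
    other = []
    for r in reads:
        cat = c.classify_read(r[0], r[1])
        if cat in arms:
            arms[cat].append(r)
        else:
            other.append(r)
    modal = {a: _modal_product(rs) for a, rs in arms.items()}
    n_c = n_i = 0.0
    for arm, rs in arms.items():
        m = modal[arm]
        for r in rs:
            if m is not None and abs(r[0] - m[0]) <= 2:
                n_c += r[2]
            else:
                n_i += r[2]
    for r in other:
        n_i += r[2]
    s_reads = math.log2((n_c + 1.0) / (n_i + 1.0))

    s_duplex = -2.0
    if modal["5p"] is not None and modal["3p"] is not None:
        f5, f3 = modal["5p"]
        t5, t3 = modal["3p"]
        pm = c.structure.partner_map()
        p1 = _partner_near(pm, f5)
        p2 = _partner_near(pm, t5)
        if p1 is not None and p2 is not None:
            ov_3p = (t3 - 1) - p1
            ov_5p = (f3 - 1) - p2
            if 1 <= ov_3p <= 3 and 1 <= ov_5p <= 3:
                s_duplex = 2.0
    return EvidenceScore(s_reads, s_duplex, -c.z)


def signal_to_noise(
    candidates: list[Candidate],
    n_perm: int = 100,
    seed: int = 0,
    cutoffs=None,
) -> pd.DataFrame:
    """Signal-to-noise table over score cutoffs.

    Each permutation round re-draws every read's position uniformly within
    its candidate's window (lengths and copy numbers kept) and rescores; the
    structure term is unchanged by construction.  S/N(c) = N_real(total>=c) /
    mean_perm N(total>=c), with 0/0 reported as inf.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if not candidates:
        raise ValueError("no candidates")
    rng = np.random.default_rng(seed)
    totals = np.array([score_candidate(c).total for c in candidates])
    for c, t in zip(candidates, totals):
        if c.score is None:
            c.score = score_candidate(c)
    if cutoffs is None:
        lo = math.floor(min(0.0, totals.min()))
        hi = math.ceil(totals.max()) + 0.5
        cutoffs = np.arange(lo, hi, 0.5)
    perm_counts = np.zeros((n_perm, len(cutoffs)))
    for p in range(n_perm):
        ptotals = np.empty(len(candidates))
        for ci, c in enumerate(candidates):
            wlen = len(c.sequence)
            perm_reads = []
            for rs, re, cnt, rid in c.reads:
                rl = re - rs
                hi_start = max(1, wlen - rl + 1)
                new_s = int(rng.integers(0, hi_start))
                perm_reads.append((new_s, new_s + rl, cnt, rid))
            ptotals[ci] = score_candidate(c, reads=perm_reads).total
        perm_counts[p] = (ptotals[:, None] >= cutoffs[None, :]).sum(axis=0)
    n_real = (totals[:, None] >= cutoffs[None, :]).sum(axis=0)
    mean_perm = perm_counts.mean(axis=0)
    sn = np.where(mean_perm > 0, n_real / np.where(mean_perm > 0, mean_perm, 1.0),
                  np.inf)
    return pd.DataFrame({"cutoff": cutoffs, "n_real": n_real,
                         "mean_perm": mean_perm, "sn": sn})


def choose_cutoff(table: pd.DataFrame, target_sn: float = 10.0) -> float | None:
    """Smallest cutoff whose signal-to-noise ratio reaches ``target_sn``."""
    ok = table[table.sn >= target_sn]
    if ok.empty:
        return None
    return float(ok.cutoff.iloc[0])


# ---------------------------------------------------------------------------
# filtering, classification, merging


def filter_annotations(
    calls: list[MiRNACall], annotations: AnnotationIntervals
) -> tuple[list[MiRNACall], dict[str, int]]:
    """Drop calls whose precursor overlaps any annotated CDS/ncRNA/repeat
    interval by >= 1 bp; removal reasons are tallied per category."""
    kept = []
    reasons: dict[str, int] = defaultdict(int)
    for call in calls:
        hit_cat = None
        for iv in annotations:
            if iv.scaffold == call.scaffold and iv.start < call.end and call.start < iv.end:
                hit_cat = iv.category
                break
        if hit_cat is None:
            kept.append(call)
        else:
            reasons[hit_cat] += 1
    return kept, dict(reasons)


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def classify_homology(
    mature: str,
    references: dict[str, str],
    seed_span: tuple[int, int] = (2, 8),
    min_overlap: int = 16,
) -> tuple[str, str | None]:
    """Classify a mature sequence as conserved or lineage-specific.

    Conserved iff some reference mature, compared ungapped at every sliding
    offset covering the seed, shows zero mismatches at seed positions
    (1-based ``seed_span`` on the query mature) and no mismatch run longer
    than 2 elsewhere.  The family is the best match (fewest mismatches; ties
    go to reference order).
    """
    if len(mature) < 16:
        raise ValueError("mature too short to classify")
    q = _norm(mature)
    s_lo, s_hi = seed_span[0] - 1, seed_span[1]  # 0-based half-open on query
    best = None
    for fam, ref in references.items():
        r = _norm(ref)
        for off in range(-(len(q) - min_overlap), len(r) - min_overlap + 1):
            # query position i aligns to reference position i + off
            lo = max(0, -off)
            hi = min(len(q), len(r) - off)
            if hi - lo < min_overlap or lo > s_lo or hi < s_hi:
                continue
            mism = [q[i] != r[i + off] for i in range(lo, hi)]
            if any(mism[s_lo - lo : s_hi - lo]):
                continue
            run = max_run = 0
            for k, bad in enumerate(mism):
                if bad and not (s_lo - lo <= k < s_hi - lo):
                    run += 1
                    max_run = max(max_run, run)
                else:
                    run = 0
            if max_run > 2:
                continue
            total_mm = sum(mism)
            if best is None or total_mm < best[0]:
                best = (total_mm, fam)
    if best is None:
        return "lineage-specific", None
    return "conserved", best[1]


def homolog_scan(
    genome: ScaffoldSet,
    references: dict[str, str],
    max_mm: int = 3,
    extension: int = 110,
    score_min: float = 70.0,
) -> list[MiRNACall]:
    """Homology path: map reference matures onto the genome (<= ``max_mm``
    substitutions, both strands), excise and fold extension windows, and
    keep hairpin hits whose surrogate score
    ``50 (1 - mm/len) + 50 (fraction of mature bases paired)`` reaches
    ``score_min``."""
    if not references:
        raise ValueError("reference set is empty")
    calls: list[MiRNACall] = []
    k = 0
    for fam, ref in references.items():
        seq = _norm(ref)
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            for scaf, off, mm in _segment_hits(s, genome, max_mm):
                m_start, m_end = off, off + len(s)
                best = None
                for w_start, w_end in ((m_start, m_end + extension),
                                       (m_start - extension, m_end)):
                    w_start = max(0, w_start)
                    w_end = min(len(genome[scaf]), w_end)
                    wseq = genome[scaf][w_start:w_end]
                    if strand == "-":
                        wseq = _revcomp(wseq)
                    if strand == "+":
                        rel = (m_start - w_start, m_end - w_start)
                    else:
                        rel = (w_end - m_end, w_end - m_start)
                    trimmed = _hairpin_at(wseq, rel[0], rel[1])
                    if trimmed is None:
                        continue
                    _sub, struct, t_lo, _t_hi = trimmed
                    pm = struct.partner_map()
                    paired = sum(
                        1 for p in range(rel[0] - t_lo, rel[1] - t_lo) if p in pm
                    )
                    frac = paired / len(s)
                    score = 50.0 * (1.0 - mm / len(s)) + 50.0 * frac
                    if score >= score_min and (best is None or score > best[0]):
                        best = (score, w_start, w_end)
                if best is not None:
                    k += 1
                    calls.append(
                        MiRNACall(
                            id=f"hom{k}",
                            scaffold=scaf,
                            start=best[1],
                            end=best[2],
                            strand=strand,
                            sequence=genome[scaf][best[1] : best[2]],
                            mature5=(m_start, m_end),
                            mature5_seq=genome[scaf][m_start:m_end]
                            if strand == "+"
                            else _revcomp(genome[scaf][m_start:m_end]),
                            class_label="conserved",
                            family=fam,
                            provenance="homology",
                        )
                    )
    return calls


def _overlap(a: MiRNACall, b: MiRNACall) -> float:
    """Reciprocal overlap fraction (of the larger span)."""
    if a.scaffold != b.scaffold:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    return inter / max(a.end - a.start, b.end - b.start)


def merge_call_sets(
    seq_calls: list[MiRNACall], homolog_calls: list[MiRNACall]
) -> tuple[list[MiRNACall], pd.DataFrame]:
    """Merge sequencing and homology calls: loci overlapping >= 50%
    reciprocally become one call with provenance "both" (sequencing fields
    kept); the rest keep their provenance.  Also returns an overlap report.
    """
    merged: list[MiRNACall] = []
    used = set()
    n_both = 0
    for sc in seq_calls:
        partner = None
        for hi, hc in enumerate(homolog_calls):
            if hi in used:
                continue
            if _overlap(sc, hc) >= 0.5:
                partner = hi
                break
        if partner is not None:
            used.add(partner)
            n_both += 1
            hc = homolog_calls[partner]
            sc.provenance = "both"
            if sc.class_label == "lineage-specific":
                sc.class_label = hc.class_label
                sc.family = hc.family
        merged.append(sc)
    for hi, hc in enumerate(homolog_calls):
        if hi not in used:
            merged.append(hc)
    report = pd.DataFrame(
        {
            "n_sequencing": [len(seq_calls)],
            "n_homology": [len(homolog_calls)],
            "n_both": [n_both],
            "n_union": [len(merged)],
        }
    )
    return merged, report


def dedupe_candidates(candidates: list[Candidate]) -> list[Candidate]:
    """Collapse candidates covering the same locus, keeping the highest
    score.

    Duplicates arise from the two excision windows of one stack, from the
    5P and 3P stacks of one precursor, and from reverse-strand shadows (a
    hairpin's 3' arm is the reverse complement of its 5' arm, so arm reads
    map to both strands of the locus).  Two candidates are duplicates when
    their loci overlap by >= 20 bp (either strand) and they either cover
    >= 50% of the smaller span or explain >= 50% of the smaller candidate's
    read mass (shared collapsed-read ids, copy-weighted).
    """
    for c in candidates:
        if c.score is None:
            c.score = score_candidate(c)

    def read_mass(c):
        mass: dict[str, float] = {}
        for _rs, _re, cnt, rid in c.reads:
            mass[rid] = mass.get(rid, 0.0) + cnt
        return mass

    order = sorted(candidates, key=lambda c: -c.score.total)
    masses = {id(c): read_mass(c) for c in order}
    kept: list[Candidate] = []
    for c in order:
        dup = False
        for k in kept:
            if k.scaffold != c.scaffold:
                continue
            inter = min(k.end, c.end) - max(k.start, c.start)
            if inter < 20:
                continue
            if inter / min(k.end - k.start, c.end - c.start) >= 0.5:
                dup = True
                break
            mc, mk = masses[id(c)], masses[id(k)]
            shared = sum(min(v, mk[r]) for r, v in mc.items() if r in mk)
            denom = min(sum(mc.values()), sum(mk.values()))
            if denom > 0 and shared / denom >= 0.5:
                dup = True
                break
        if not dup:
            kept.append(c)
    return kept


def calls_from_candidates(
    candidates: list[Candidate],
    references: dict[str, str] | None = None,
) -> list[MiRNACall]:
    """Turn scored candidates into miRNA calls: modal arm products become
    the mature annotations, and homology against the reference set assigns
    conserved/lineage-specific classes."""
    calls = []
    for k, c in enumerate(candidates, start=1):
        arms = {"5p": [], "3p": []}
        for r in c.reads:
            cat = c.classify_read(r[0], r[1])
            if cat in arms:
                arms[cat].append(r)
        spans = {}
        seqs = {}
        for arm, rs in arms.items():
            m = _modal_product(rs)
            if m is None:
                continue
            rel = (m[0], m[1])
            seqs[arm] = c.sequence[rel[0] : rel[1]]
            if c.strand == "+":
                spans[arm] = (c.start + rel[0], c.start + rel[1])
            else:
                spans[arm] = (c.end - rel[1], c.end - rel[0])
        label, family = "lineage-specific", None
        if references:
            for arm in ("5p", "3p"):
                if arm in seqs and len(seqs[arm]) >= 16:
                    label, family = classify_homology(seqs[arm], references)
                    if label == "conserved":
                        break
        calls.append(
            MiRNACall(
                id=f"mirburst{k}",
                scaffold=c.scaffold,
                start=c.start,
                end=c.end,
                strand=c.strand,
                sequence=c.sequence,
                mature5=spans.get("5p"),
                mature3=spans.get("3p"),
                mature5_seq=seqs.get("5p"),
                mature3_seq=seqs.get("3p"),
                score=c.score or score_candidate(c),
                class_label=label,
                family=family,
                provenance="sequencing",
            )
        )
    return calls
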