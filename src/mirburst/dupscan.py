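"""miRNA duplication scanning.

All-vs-all precursor similarity (Smith–Waterman local alignment with affine
gaps and Karlin–Altschul E-values), divergence-rate statistics, family
clustering with majority-rule consensus, and GLSEARCH-style glocal (query
global, target local) scanning of genomic flanking regions with edge-to-edge
distance binning.

Scoring scheme (defaults): match +1, mismatch -2, gap open -5, gap extend
-2, where a gap of length L costs ``open + (L-1) * extend``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AlignmentHit",
    "KAParams",
    "DuplicationHit",
    "local_align",
    "glocal_align",
    "solve_ka",
    "evalue",
    "allvsall_similarity",
    "divergence_rate",
    "family_cluster",
    "family_consensus",
    "flank_scan",
    "distance_histogram",
    "compare_genomes",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_COMP = str.maketrans("ACGTUN", "TGCAAN")
_NEG = np.float32(-1e9)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class AlignmentHit:
    """One pairwise alignment with per-column accounting."""

    query_id: str
    target_id: str
    score: float
    aligned_cols: int
    matches: int
    mismatches: int
    gap_cols: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    evalue: float | None = None

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_cols if self.aligned_cols else 0.0

    def coverage(self, length: int, which: str = "query") -> float:
        span = (self.q_end - self.q_start) if which == "query" else (
            self.t_end - self.t_start
        )
        return span / length if length else 0.0


@dataclass(frozen=True)
class KAParams:
    """Karlin–Altschul parameters for an ungapped scoring scheme."""

    lam: float  # nats per score unit
    K: float = 0.35
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass
class DuplicationHit:
    """A similar copy found in the flank of an original precursor."""

    original_id: str
    scaffold: str
    start: int  # genome coordinates, 0-based half-open
    end: int
    strand: str
    alignment: AlignmentHit
    distance: int  # edge-to-edge bp to the original precursor


def _encode(seq: str, name: str = "sequence") -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-DNA character {exc.args[0]!r} in {name}")


def _dp(q, t, match, mismatch, gap_open, gap_extend, local):
    """Row-vectorised affine-gap DP.

    Returns score matrix H and vertical-gap matrix F (float32; integer-valued
    scores are exact).  Horizontal gaps use the single-opening closed form,
    valid because gap_open <= gap_extend <= 0 makes merged gaps optimal.
    """
    if not (gap_open <= gap_extend <= 0):
        raise ValueError("require gap_open <= gap_extend <= 0")
    m, n = len(q), len(t)
    H = np.empty((m + 1, n + 1), np.float32)
    F = np.full((m + 1, n + 1), _NEG, np.float32)
    H[0, :] = 0.0
    idx = np.arange(n + 1, dtype=np.float32)
    go, ge = np.float32(gap_open), np.float32(gap_extend)
    tq = t  # int8 vector
    for i in range(1, m + 1):
        Hp, Fp = H[i - 1], F[i - 1]
        Fi = np.maximum(Hp + go, Fp + ge)
        s = np.where(tq == q[i - 1], np.float32(match), np.float32(mismatch))
        base = np.empty(n + 1, np.float32)
        base[0] = 0.0 if local else Fi[0]
        base[1:] = Hp[:-1] + s
        np.maximum(base[1:], Fi[1:], out=base[1:])
        if local:
            np.maximum(base, np.float32(0.0), out=base)
        acc = np.maximum.accumulate(base - ge * idx)
        E = np.full(n + 1, _NEG, np.float32)
        E[1:] = go - ge + ge * idx[1:] + acc[:-1]
        Hi = np.maximum(base, E)
        if local:
            np.maximum(Hi, np.float32(0.0), out=Hi)
        H[i] = Hi
        F[i] = Fi
    return H, F


def _traceback(q, t, H, F, i, j, match, mismatch, gap_open, gap_extend, local):
    """Reconstruct one optimal path ending at H[i, j].

    Returns (matches, mismatches, gap_cols, q_start, t_start).
    """
    ma = mi = ga = 0
    while i > 0:
        h = H[i, j]
        if local and h == 0.0:
            break
        if j > 0:
            s = match if q[i - 1] == t[j - 1] else mismatch
            if h == H[i - 1, j - 1] + s:
                if q[i - 1] == t[j - 1]:
                    ma += 1
                else:
                    mi += 1
                i, j = i - 1, j - 1
                continue
        if j == 0 or h == F[i, j]:
            # vertical gap run (query chars vs gap in target)
            while i > 0:
                ga += 1
                if j == 0:
                    i -= 1
                    continue
                opened = F[i, j] == H[i - 1, j] + gap_open
                i -= 1
                if opened:
                    break
            continue
        # horizontal gap: single opening from some earlier column
        found = False
        for k in range(j - 1, -1, -1):
            if H[i, k] + gap_open + (j - 1 - k) * gap_extend == h:
                ga += j - k
                j = k
                found = True
                break
        if not found:  # pragma: no cover - defensive
            raise RuntimeError("traceback failed")
    return ma, mi, ga, i, j


def _align(qseq, tseq, match, mismatch, gap_open, gap_extend, local,
           query_id="query", target_id="target"):
    q = _encode(qseq, "query")
    t = _encode(tseq, "target")
    H, F = _dp(q, t, match, mismatch, gap_open, gap_extend, local)
    m, n = len(q), len(t)
    if local:
        flat = int(np.argmax(H))
        i, j = divmod(flat, n + 1)
        score = float(H[i, j])
        if score <= 0.0:
            return AlignmentHit(query_id, target_id, 0.0, 0, 0, 0, 0, 0, 0, 0, 0)
    else:
        i = m
        j = int(np.argmax(H[m]))
        score = float(H[m, j])
    qe, te = i, j
    ma, mi, ga, qs, ts = _traceback(
        q, t, H, F, i, j, match, mismatch, gap_open, gap_extend, local
    )
    return AlignmentHit(
        query_id, target_id, score, ma + mi + ga, ma, mi, ga, qs, qe, ts, te
    )


def local_align(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = -2,
    gap_open: float = -5,
    gap_extend: float = -2,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """Optimal Smith–Waterman local alignment of ``a`` against ``b``.

    Deterministic tie-break: among equal-scoring alignments the one with the
    smallest end coordinates is reported.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return _align(a, b, match, mismatch, gap_open, gap_extend, True,
                  query_id, target_id)


def glocal_align(
    query: str,
    target: str,
    match: float = 1,
    mismatch: float = -2,
    gap_open: float = -5,
    gap_extend: float = -2,
    query_id: str = "query",
    target_id: str = "target",
) -> AlignmentHit:
    """GLSEARCH-style alignment: the whole query against the best-matching
    local region of the target (free end gaps in the target only)."""
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    if len(query) > len(target):
        raise ValueError("query longer than target")
    return _align(query, target, match, mismatch, gap_open, gap_extend, False,
                  query_id, target_id)


def solve_ka(
    match: float = 1,
    mismatch: float = -2,
    composition=(0.25, 0.25, 0.25, 0.25),
    K: float = 0.35,
) -> KAParams:
    """Solve the Karlin–Altschul scale λ for an ungapped match/mismatch
    scheme: the unique positive root of Σ_ij p_i p_j exp(λ s_ij) = 1.

    K is a fixed documented approximation (default 0.35), absorbed into the
    configurability of downstream E-value thresholds.
    """
    p = np.asarray(composition, dtype=float)
    if not math.isclose(p.sum(), 1.0, rel_tol=1e-6):
        raise ValueError("composition must sum to 1")
    pm = float(np.sum(np.outer(p, p) * np.eye(4)))  # P(match)
    exp_score = pm * match + (1 - pm) * mismatch
    if exp_score >= 0:
        raise ValueError("scoring scheme not local-alignment valid "
                         "(non-negative expected score)")

    def f(lam):
        return pm * math.exp(lam * match) + (1 - pm) * math.exp(lam * mismatch) - 1.0

    lam = brentq(f, 1e-9, 50.0, xtol=1e-12)
    return KAParams(lam=float(lam), K=K, composition=tuple(p))


def evalue(score: float, m: int, n: int, ka: KAParams) -> float:
    """Karlin–Altschul expected number of chance hits: E = K m n e^(-λ S)."""
    return ka.K * m * n * math.exp(-ka.lam * score)


def allvsall_similarity(
    precursors: dict[str, str],
    evalue_max: float = 1e-5,
    min_coverage: float = 0.5,
    ka: KAParams | None = None,
    **scoring,
) -> list[AlignmentHit]:
    """All-vs-all local alignment of precursors; keep pairs with
    E < ``evalue_max`` and coverage of the shorter precursor > ``min_coverage``.

    Self-pairs are excluded; each kept unordered pair is reported once (the
    relation is symmetric).
    """
    if len(precursors) < 2:
        raise ValueError("need at least 2 precursors")
    if ka is None:
        ka = solve_ka(scoring.get("match", 1), scoring.get("mismatch", -2))
    ids = list(precursors)
    kept: list[AlignmentHit] = []
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            sa, sb = precursors[a], precursors[b]
            # query = shorter, so query coverage is coverage of the shorter
            if len(sa) <= len(sb):
                hit = local_align(sa, sb, query_id=a, target_id=b, **scoring)
                short_len = len(sa)
            else:
                hit = local_align(sb, sa, query_id=b, target_id=a, **scoring)
                short_len = len(sb)
            hit.evalue = evalue(hit.score, len(sa), len(sb), ka)
            if hit.evalue < evalue_max and hit.coverage(short_len) > min_coverage:
                kept.append(hit)
    return kept


def divergence_rate(hit: AlignmentHit, count_gaps: bool = True) -> float:
    """Percent non-identical columns in the alignment.

    Gap columns count as mismatched by default (configurable)."""
    if hit.aligned_cols < 1:
        raise ValueError("empty alignment")
    bad = hit.mismatches + (hit.gap_cols if count_gaps else 0)
    denom = hit.aligned_cols if count_gaps else hit.matches + hit.mismatches
    return 100.0 * bad / denom if denom else 0.0


def family_cluster(
    pairs: list[AlignmentHit], ids: list[str] | None = None
) -> list[set[str]]:
    """Connected components of the similarity graph; ``ids`` adds singleton
    families for precursors with no similar partner."""
    parent: dict[str, str] = {}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u, v):
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    for h in pairs:
        union(h.query_id, h.target_id)
    for i in ids or []:
        parent.setdefault(i, i)
    comps: dict[str, set[str]] = {}
    for u in parent:
        comps.setdefault(find(u), set()).add(u)
    return sorted(comps.values(), key=lambda s: (-len(s), min(s)))


def family_consensus(
    family: set[str], precursors: dict[str, str]
) -> tuple[str, list[int]]:
    """Majority-rule consensus over glocal alignments of family members to
    the longest member.  Ties pick the alphabetically first base and are
    reported as flagged positions."""
    members = sorted(family, key=lambda i: (-len(precursors[i]), i))
    ref_id, ref = members[0], precursors[members[0]]
    counts = [dict.fromkeys("ACGT", 0) for _ in ref]
    for rid in members:
        seq = precursors[rid]
        if rid == ref_id:
            for k, c in enumerate(ref):
                counts[k][c] += 1
            continue
        hit = glocal_align(seq, ref)
        # ungapped column assignment: walk the reported spans via a fresh
        # per-column comparison (gap columns are skipped for counting)
        _accumulate_columns(seq, ref, hit, counts)
    cons = []
    ties: list[int] = []
    for k, tab in enumerate(counts):
        top = max(tab.values())
        winners = sorted(b for b, c in tab.items() if c == top)
        if len(winners) > 1:
            ties.append(k)
        cons.append(winners[0])
    return "".join(cons), ties


def _accumulate_columns(qseq, tseq, hit, counts):
    # re-derive the aligned columns by re-running a small DP on the spans;
    # cheap because family members are precursor-sized
    sub_t = tseq[hit.t_start : hit.t_end]
    sub_q = qseq[hit.q_start : hit.q_end]
    if not sub_q or not sub_t:
        return
    path = _alignment_path(sub_q, sub_t)
    for qi, tj in path:
        if qi is not None and tj is not None:
            counts[hit.t_start + tj][sub_q[qi]] += 1


def _alignment_path(a: str, b: str, match=1, mismatch=-2, gap_open=-5,
                    gap_extend=-2):
    """Global alignment path of two short strings as (a_idx|None, b_idx|None)
    column pairs, simple affine DP with pointer recomputation."""
    q = _encode(a)
    t = _encode(b)
    H, F = _dp(q, t, match, mismatch, gap_open, gap_extend, False)
    # force global-in-target by tracing from (m, n)
    i, j = len(q), len(t)
    path = []
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if q[i - 1] == t[j - 1] else mismatch
            if H[i, j] == H[i - 1, j - 1] + s:
                path.append((i - 1, j - 1))
                i, j = i - 1, j - 1
                continue
        if i > 0 and (j == 0 or H[i, j] == F[i, j]):
            path.append((i - 1, None))
            i -= 1
            continue
        moved = False
        for k in range(j - 1, -1, -1):
            if H[i, k] + gap_open + (j - 1 - k) * gap_extend == H[i, j]:
                for col in range(j - 1, k - 1, -1):
                    path.append((None, col))
                j = k
                moved = True
                break
        if not moved:
            path.append((None, j - 1))
            j -= 1
    return path[::-1]


def flank_scan(
    genome,
    calls,
    window: int = 50_000,
    min_identity: float = 0.6,
    max_hits_per_flank: int = 50,
    **scoring,
) -> list[DuplicationHit]:
    """Scan the genomic flanks of each precursor for similar copies.

    For each call, +/- ``window`` bp of flank is extracted (clipped at
    scaffold ends) and the precursor is glocally aligned against both strands.
    Non-overlapping hits with identity >= ``min_identity`` are reported with
    edge-to-edge distances; hits overlapping the original precursor span are
    excluded.
    """
    match = scoring.get("match", 1)
    mismatch = scoring.get("mismatch", -2)
    gap_open = scoring.get("gap_open", -5)
    gap_extend = scoring.get("gap_extend", -2)
    out: list[DuplicationHit] = []
    for call in calls:
        scaf_seq = genome[call.scaffold]
        w_start = max(0, call.start - window)
        w_end = min(len(scaf_seq), call.end + window)
        region = scaf_seq[w_start:w_end]
        query = scaf_seq[call.start : call.end]
        if len(query) == 0 or len(region) < len(query):
            continue
        q = _encode(query)
        for strand in "+-":
            tgt = region if strand == "+" else revcomp(region)
            t = _encode(tgt)
            H, F = _dp(q, t, match, mismatch, gap_open, gap_extend, False)
            end_scores = H[len(q)].copy()
            end_scores[0] = _NEG
            taken: list[tuple[int, int]] = []  # spans in tgt coords
            for _ in range(max_hits_per_flank):
                j = int(np.argmax(end_scores))
                score = float(end_scores[j])
                if score <= 0.0:
                    break
                ma, mi, ga, qs, ts = _traceback(
                    q, t, H, F, len(q), j, match, mismatch, gap_open,
                    gap_extend, False,
                )
                te = j
                end_scores[max(0, ts + 1) : te + 1] = _NEG
                span = (ts, te)
                if any(span[0] < e and s < span[1] for s, e in taken):
                    continue
                # map to genome coordinates
                if strand == "+":
                    g_start, g_end = w_start + ts, w_start + te
                else:
                    g_start = w_start + (len(tgt) - te)
                    g_end = w_start + (len(tgt) - ts)
                if g_start < call.end and call.start < g_end:
                    continue  # overlaps the original precursor
                hit = AlignmentHit(
                    call.id, call.scaffold, score, ma + mi + ga, ma, mi, ga,
                    qs, len(q), ts, te,
                )
                if hit.identity < min_identity:
                    continue
                taken.append(span)
                dist = g_start - call.end if g_start >= call.end else call.start - g_end
                out.append(
                    DuplicationHit(
                        call.id, call.scaffold, g_start, g_end, strand, hit,
                        max(0, dist),
                    )
                )
    return out


def distance_histogram(
    hits: list[DuplicationHit], bin: int = 5_000, max: int = 50_000
) -> tuple[np.ndarray, int]:
    """Bin edge-to-edge distances into [0, bin), [bin, 2*bin) ... with the
    final bin closed at ``max``; distances beyond ``max`` are dropped and
    tallied.  Returns (counts, n_dropped)."""
    edges = np.arange(0, max + bin, bin)
    d = np.array([h.distance for h in hits], dtype=float)
    dropped = int((d > max).sum())
    counts, _ = np.histogram(d[d <= max], bins=edges)
    return counts, dropped


def compare_genomes(
    genome_call_pairs, window: int = 50_000, min_identity: float = 0.6,
    bin: int = 5_000, max: int = 50_000,
):
    """Run the flank scan per genome and tabulate distance histograms.

    ``genome_call_pairs`` is a list of (label, genome, calls).  Returns a
    pandas DataFrame of binned counts (rows = genomes) plus a totals column.
    """
    import pandas as pd

    rows = {}
    for label, genome, calls in genome_call_pairs:
        hits = flank_scan(genome, calls, window=window, min_identity=min_identity)
        counts, dropped = distance_histogram(hits, bin=bin, max=max)
        rows[label] = list(counts) + [dropped, len(hits)]
    cols = [f"[{k * bin},{(k + 1) * bin})" for k in range(max // bin)]
    cols += ["dropped", "total"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
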