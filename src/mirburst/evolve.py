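"""Cross-species conservation and sequence-variation analysis.

Detects locust-style miRNA precursors in a sister species' small-RNA reads
(ungapped alignment with a mismatch tolerance), calls mature-region variants
from the resulting pileups with the first/last-three-base trim that guards
against un-templated end modifications, builds the variant-by-group
contingency tables, and provides the statistical test kit used throughout
the analysis (Pearson χ² on 2x2 tables, Mann–Whitney U, two-sample
Kolmogorov–Smirnov, Pearson correlation).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "VariantCall",
    "ContingencyTable2x2",
    "StatResult",
    "Pileup",
    "cross_species_detect",
    "call_mature_variants",
    "variant_contingency",
    "chi2_2x2",
    "mwu_test",
    "ks_test",
    "pearson_corr",
]

_COMP = str.maketrans("ACGTUN", "TGCAAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass(frozen=True)
class VariantCall:
    """A substitution in a mature miRNA region, called from a cross-species
    pileup.  ``position`` is 1-based from the mature 5' end."""

    mirna_id: str
    position: int
    ref: str
    alt: str
    alt_fraction: float
    coverage: float


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = (variant, no variant)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative counts")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("empty table")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    pvalue: float
    method: str
    n: tuple[int, ...] = ()


@dataclass
class Pileup:
    """Per-position base counts over one precursor (copy-weighted)."""

    precursor_id: str
    ref_seq: str
    counts: np.ndarray = None  # (len, 4) float, columns A,C,G,T
    n_distinct_reads: int = 0

    def __post_init__(self):
        if self.counts is None:
            self.counts = np.zeros((len(self.ref_seq), 4))


_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_IDX_BASE = "ACGT"


def _ungapped_hits(read: str, target: str, max_mismatch: int):
    """All offsets where ``read`` aligns fully inside ``target`` with at most
    ``max_mismatch`` substitutions, via pigeonhole seeding."""
    L = len(read)
    if L > len(target):
        return []
    k = max(1, L // (max_mismatch + 1))
    offsets = set()
    for seg in range(max_mismatch + 1):
        s = seg * k
        e = L if seg == max_mismatch else s + k
        piece = read[s:e]
        if not piece:
            continue
        pos = target.find(piece)
        while pos != -1:
            off = pos - s
            if 0 <= off <= len(target) - L:
                offsets.add(off)
            pos = target.find(piece, pos + 1)
    hits = []
    for off in sorted(offsets):
        mm = sum(a != b for a, b in zip(read, target[off : off + L]))
        if mm <= max_mismatch:
            hits.append((off, mm))
    return hits


def cross_species_detect(
    precursors: dict[str, str],
    reads,
    max_mismatch: int = 2,
    min_reads: int = 1,
    both_strands: bool = False,
) -> tuple[set[str], dict[str, Pileup]]:
    """Align sister-species collapsed reads to precursors (ungapped, at most
    ``max_mismatch`` substitutions) and build per-precursor pileups.

    A precursor is detected iff at least ``min_reads`` distinct reads align
    within it.  Returns ``(detected_ids, pileups)``.  Alignment is
    sense-only by default: mature reads are sense-stranded relative to
    their precursor, and antisense alignment would write each arm's reads
    into the opposite arm's pileup (the arms are near reverse complements).
    """
    pileups = {pid: Pileup(pid, seq.upper()) for pid, seq in precursors.items()}
    distinct = Counter()
    for read in reads:
        seq = read.sequence.upper().replace("U", "T")
        count = getattr(read, "count", 1)
        variants = [seq] + ([_revcomp(seq)] if both_strands else [])
        # best-hit assignment: a read contributes only to the precursor(s)
        # it matches with the fewest mismatches, so paralogous family
        # members do not contaminate each other's pileups
        hits: list[tuple[int, str, str, int]] = []
        for pid, target in precursors.items():
            target = target.upper()
            for rs in variants:
                for off, mm in _ungapped_hits(rs, target, max_mismatch):
                    hits.append((mm, pid, rs, off))
        if not hits:
            continue
        best_mm = min(h[0] for h in hits)
        seen = set()
        for mm, pid, rs, off in hits:
            if mm != best_mm:
                continue
            pu = pileups[pid]
            for k, base in enumerate(rs):
                if base in _BASE_IDX:
                    pu.counts[off + k, _BASE_IDX[base]] += count
            if pid not in seen:
                seen.add(pid)
                distinct[pid] += 1
    detected = set()
    for pid, n in distinct.items():
        pileups[pid].n_distinct_reads = n
        if n >= min_reads:
            detected.add(pid)
    return detected, pileups


def call_mature_variants(
    pileup: Pileup,
    mature_span: tuple[int, int],
    trim: int = 3,
    min_af: float = 0.5,
    min_cov: float = 10,
) -> list[VariantCall]:
    """Call substitutions inside a mature region from a pileup.

    The first and last ``trim`` bases of the mature region never emit calls
    (un-templated 5'/3' modifications are frequent there).  A position is a
    variant iff its coverage is at least ``min_cov`` and the modal
    non-reference base reaches an allele fraction of at least ``min_af``.
    """
    s, e = mature_span
    calls: list[VariantCall] = []
    for pos in range(s + trim, e - trim):
        cov = pileup.counts[pos].sum()
        if cov < min_cov:
            continue
        ref = pileup.ref_seq[pos]
        ref_i = _BASE_IDX.get(ref)
        alt_counts = [
            (c, i) for i, c in enumerate(pileup.counts[pos]) if i != ref_i
        ]
        best_c, best_i = max(alt_counts)
        if best_c / cov >= min_af:
            calls.append(
                VariantCall(
                    pileup.precursor_id,
                    pos - s + 1,
                    ref,
                    _IDX_BASE[best_i],
                    float(best_c / cov),
                    float(cov),
                )
            )
    return calls


def variant_contingency(
    variant_ids: set[str],
    detected: set[str],
    class_labels: dict[str, str],
    expression_groups: dict[str, str],
) -> dict[str, ContingencyTable2x2]:
    """Build the two contrasts of the conservation analysis.

    ``class_vs_class``: conserved vs lineage-specific, columns = (variant,
    no variant), over detected miRNAs.  ``expression_within_lineage``:
    moderate/high vs low expression among detected lineage-specific miRNAs.
    """
    for mid in detected:
        if mid not in class_labels:
            raise ValueError(f"detected miRNA {mid!r} lacks a class label")

    def tally(ids):
        v = sum(1 for i in ids if i in variant_ids)
        return v, len(ids) - v

    cons = [i for i in detected if class_labels[i] == "conserved"]
    lin = [i for i in detected if class_labels[i] == "lineage-specific"]
    a, b = tally(cons)
    c, d = tally(lin)
    tables = {"class_vs_class": ContingencyTable2x2(a, b, c, d)}
    hi = [i for i in lin if expression_groups.get(i) == "moderate/high"]
    lo = [i for i in lin if expression_groups.get(i) == "low"]
    if set(hi) & set(lo):
        raise ValueError("overlapping expression group membership")
    if hi or lo:
        a, b = tally(hi)
        c, d = tally(lo)
        tables["expression_within_lineage"] = ContingencyTable2x2(a, b, c, d)
    return tables


def chi2_2x2(t: ContingencyTable2x2, yates: bool = False) -> StatResult:
    """Pearson χ² test of independence on a 2x2 table (df = 1).

    statistic = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); a zero margin gives
    statistic 0 and p 1.  Yates' correction subtracts n/2 from |ad - bc|
    (floored at 0) when enabled.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return StatResult(0.0, 1.0, "chi2", (a + b, c + d))
    delta = abs(a * d - b * c)
    if yates:
        delta = max(0.0, delta - n / 2)
    stat = n * delta**2 / margins
    p = float(stats.chi2.sf(stat, df=1))
    return StatResult(float(stat), p, "chi2_yates" if yates else "chi2", (a + b, c + d))


def _mwu_u(x: np.ndarray, y: np.ndarray) -> float:
    # U for sample x: number of (x_i, y_j) pairs with x_i > y_j, ties 0.5
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mwu_test(x, y, exact_max: int = 8) -> StatResult:
    """Two-sided Mann–Whitney U test.

    Exact null enumeration when both samples have at most ``exact_max``
    observations and there are no ties; otherwise a normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    u = _mwu_u(x, y)
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled, return_counts=True)[1]
    has_ties = (ties > 1).any()
    if n <= exact_max and m <= exact_max and not has_ties:
        # enumerate all assignments of the pooled ranks to sample x
        ranks = np.argsort(np.argsort(pooled)) + 1
        total = 0
        extreme = 0
        lo = hi = 0
        for combo in itertools.combinations(range(n + m), n):
            rsum = sum(ranks[k] for k in combo)
            uu = rsum - n * (n + 1) / 2
            total += 1
            if uu <= u:
                lo += 1
            if uu >= u:
                hi += 1
        p = min(1.0, 2 * min(lo, hi) / total)
        return StatResult(u, float(p), "mwu_exact", (n, m))
    mu = n * m / 2
    nn = n + m
    tie_term = ((ties**3 - ties).sum()) / (nn * (nn - 1)) if nn > 1 else 0.0
    sigma2 = n * m / 12 * ((nn + 1) - tie_term)
    if sigma2 <= 0:
        return StatResult(u, 1.0, "mwu_normal", (n, m))
    z = (abs(u - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2 * stats.norm.sf(max(0.0, z))))
    return StatResult(u, p, "mwu_normal", (n, m))


def ks_test(x, y) -> StatResult:
    """Two-sample Kolmogorov–Smirnov test; D = sup |ECDF_x - ECDF_y|, with
    the asymptotic Kolmogorov distribution for the p-value."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError("need at least 2 observations per sample")
    grid = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, grid, side="right") / n
    cdf_y = np.searchsorted(y, grid, side="right") / m
    d = float(np.abs(cdf_x - cdf_y).max())
    en = np.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return StatResult(d, min(1.0, p), "ks", (n, m))


def pearson_corr(x, y) -> StatResult:
    """Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    r, p = stats.pearsonr(x, y)
    return StatResult(float(r), float(p), "pearson", (len(x),))
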