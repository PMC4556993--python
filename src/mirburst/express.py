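"""Expression quantification and expression-based validation statistics.

Counts reads into miRNA calls, normalises to transcripts per million (TPM),
classifies expression groups, calls tissue-specific miRNAs by a one-vs-
aggregate exact test, measures 5'/3' processing precision, and analyses the
response of RNA classes to a global miRNA-biogenesis knockdown.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import evolve

__all__ = [
    "ExpressionMatrix",
    "PrecisionRecord",
    "quantify",
    "tpm",
    "expression_group",
    "tissue_specificity",
    "end_precision",
    "precision_curve",
    "knockdown_analysis",
]


@dataclass
class ExpressionMatrix:
    """Non-negative counts (rows = RNAs, columns = samples) with per-sample
    library sizes; library size may exceed the column sum (unassigned
    reads)."""

    counts: pd.DataFrame
    lib_sizes: pd.Series = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0)
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if (self.lib_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    def tpm(self) -> pd.DataFrame:
        return tpm(self)


@dataclass(frozen=True)
class PrecisionRecord:
    """Processing precision of one mature arm: the copy-weighted fraction of
    its reads whose 5' (p5) or 3' (p3) end coincides exactly with the
    annotated mature end."""

    mirna_id: str
    arm: str
    p5: float
    p3: float
    n_reads: float


def quantify(calls, mappings_per_sample: dict[str, list]) -> ExpressionMatrix:
    """Count mapped reads into calls per sample.

    A read is compatible with a call if its 5' end falls within +/-2 nt of
    one of the call's mature 5' ends (same scaffold and strand); counts are
    copy-number sums, and a read compatible with k calls contributes 1/k of
    its copies to each.
    """
    ids = [c.id for c in calls]
    samples = list(mappings_per_sample)
    mat = pd.DataFrame(0.0, index=ids, columns=samples)
    lib = {}
    for sample, mappings in mappings_per_sample.items():
        if not mappings:
            raise ValueError(f"sample {sample!r} has no mapped reads")
        # group multi-hits of one read so fractional assignment is per read
        per_read = defaultdict(list)
        for m in mappings:
            per_read[m.read_id].append(m)
        total = 0.0
        seen = set()
        for m in mappings:
            if m.read_id not in seen:
                seen.add(m.read_id)
                total += m.count
        for rid, ms in per_read.items():
            compat = set()
            for m in ms:
                end5 = m.start if m.strand == "+" else m.end - 1
                for c in calls:
                    if c.scaffold != m.scaffold or c.strand != m.strand:
                        continue
                    for span in (c.mature5, c.mature3):
                        if span is None:
                            continue
                        mat5 = span[0] if c.strand == "+" else span[1] - 1
                        if abs(end5 - mat5) <= 2:
                            compat.add(c.id)
            if compat:
                share = ms[0].count / len(compat)
                for cid in compat:
                    mat.loc[cid, sample] += share
        lib[sample] = total
    return ExpressionMatrix(mat, pd.Series(lib))


def tpm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts per million: count / library size x 1e6."""
    return matrix.counts / matrix.lib_sizes * 1e6


def expression_group(tpm_means: pd.Series, cutoff: float = 10.0) -> pd.Series:
    """Label rows 'moderate/high' when mean TPM strictly exceeds ``cutoff``,
    else 'low'."""
    return pd.Series(
        np.where(tpm_means > cutoff, "moderate/high", "low"),
        index=tpm_means.index,
    )


def tissue_specificity(
    matrix: ExpressionMatrix, fdr: float = 0.05, min_fold: float = 4.0
) -> pd.DataFrame:
    """Call tissue-specific miRNAs by a one-vs-aggregate contrast.

    For each (miRNA, tissue), the count in that tissue's library is compared
    against the aggregate count over all other libraries with Fisher's exact
    conditional test on the 2x2 table of (assigned, unassigned) reads.
    Benjamini–Hochberg correction is applied across all tests; a pair is
    flagged iff q < ``fdr``, the normalised fold change is >= ``min_fold``,
    and the direction is "higher in tissue".
    """
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    rows = []
    for mid in counts.index:
        for t in counts.columns:
            a = counts.loc[mid, t]
            lib_t = matrix.lib_sizes[t]
            b = lib_t - a
            others = [c for c in counts.columns if c != t]
            c_ = counts.loc[mid, others].sum()
            lib_o = matrix.lib_sizes[others].sum()
            d = lib_o - c_
            table = np.rint([[a, b], [c_, d]]).astype(int)
            _odds, p = stats.fisher_exact(table, alternative="two-sided")
            rate_t = (a + 0.5) / lib_t
            rate_o = (c_ + 0.5) / lib_o
            rows.append(
                {
                    "mirna_id": mid,
                    "tissue": t,
                    "count": a,
                    "fold": rate_t / rate_o,
                    "pvalue": p,
                }
            )
    res = pd.DataFrame(rows)
    res["qvalue"] = stats.false_discovery_control(res.pvalue, method="bh")
    res["flag"] = (
        (res.qvalue < fdr) & (res.fold >= min_fold) & (res.fold > 1.0)
    )
    return res


def end_precision(call, arm_mappings: dict[str, list]) -> list[PrecisionRecord]:
    """Processing precision per arm of one call.

    ``arm_mappings`` maps arm ('5p'/'3p') to the ReadMappings assigned to
    that arm.  p5 is the copy-weighted fraction of reads whose 5' end equals
    the annotated mature 5' end; p3 analogous.  Arms without reads are
    omitted (with the pipeline logging a warning upstream).
    """
    records = []
    for arm, span in (("5p", call.mature5), ("3p", call.mature3)):
        ms = arm_mappings.get(arm, [])
        if span is None or not ms:
            continue
        if call.strand == "+":
            a5, a3 = span[0], span[1]
        else:
            a5, a3 = span[1], span[0]
        w = exact5 = exact3 = 0.0
        for m in ms:
            r5 = m.start if m.strand == "+" else m.end
            r3 = m.end if m.strand == "+" else m.start
            w += m.count
            if r5 == a5:
                exact5 += m.count
            if r3 == a3:
                exact3 += m.count
        if w > 0:
            records.append(
                PrecisionRecord(call.id, arm, exact5 / w, exact3 / w, w)
            )
    return records


def precision_curve(records: list[PrecisionRecord], which: str = "p5") -> pd.DataFrame:
    """Percentile-ordered precision series: the most precisely processed
    miRNA sits at percentile 1, the least precise at percentile 100."""
    vals = sorted((getattr(r, which) for r in records), reverse=True)
    n = len(vals)
    if n == 0:
        return pd.DataFrame({"percentile": [], which: []})
    pct = [1 + round(99 * k / max(1, n - 1)) for k in range(n)]
    return pd.DataFrame({"percentile": pct, which: vals})


def knockdown_analysis(
    control: pd.DataFrame, knockdown: pd.DataFrame
) -> dict:
    """Per-row log2 fold changes of a knockdown vs control library, by RNA
    class.

    Inputs are frames with 'class' and 'count' columns on matched row ids
    (library sizes in ``attrs['lib_size']``; column sums otherwise).  The
    knockdown library is scaled to the control's library size and a
    pseudocount of 1 is added to both sides.  Returns per-row log2FC, class
    means, Mann–Whitney tests of each class against miRNA, and an ECDF table
    per class.
    """
    if not control.index.equals(knockdown.index):
        raise ValueError("row ids must match between control and knockdown")
    lib_c = control.attrs.get("lib_size", float(control["count"].sum()))
    lib_k = knockdown.attrs.get("lib_size", float(knockdown["count"].sum()))
    kd_adj = knockdown["count"] * (lib_c / lib_k)
    log2fc = np.log2((kd_adj + 1.0) / (control["count"] + 1.0))
    out = pd.DataFrame({"class": control["class"], "log2fc": log2fc})
    class_means = out.groupby("class")["log2fc"].mean()
    tests = {}
    mir = out.loc[out["class"] == "miRNA", "log2fc"].values
    for cls in sorted(set(out["class"]) - {"miRNA"}):
        vals = out.loc[out["class"] == cls, "log2fc"].values
        if len(vals) < 3 or len(mir) < 3:
            tests[cls] = None  # too few rows; test skipped
            continue
        tests[cls] = evolve.mwu_test(mir, vals)
    grid = np.linspace(out.log2fc.min(), out.log2fc.max(), 101)
    ecdf = {
        cls: np.searchsorted(np.sort(g.values), grid, side="right") / len(g)
        for cls, g in out.groupby("class")["log2fc"]
    }
    ecdf_table = pd.DataFrame(ecdf, index=grid)
    return {
        "log2fc": out,
        "class_means": class_means,
        "mwu_vs_mirna": tests,
        "ecdf": ecdf_table,
    }
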