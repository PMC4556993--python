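"""Synthetic genomes, read libraries, and count tables with planted truth.

Every downstream stage of the pipeline is testable against the ground truth
this module records: hairpin precursors planted in random genomic background,
tandem duplicate families with controlled divergence and spacing, a mutated
sister-species genome, tissue-biased expression profiles, and a global
miRNA-knockdown count table.

What the generator emulates (and what it does not) is documented in
docs/methods.md.  Headline defaults follow the biology the pipeline targets:
22-nt matures, a ~4:1 5P:3P arm read ratio, precise 5' / imprecise 3' read
ends, a mean knockdown log2 fold change of -1.04 for miRNAs, and tandem
duplicates spaced mostly under 5 kb within 0–50 kb.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sio import FastqRead, ScaffoldSet

__all__ = [
    "SimConfig",
    "TruthTable",
    "generate_genome",
    "generate_reads",
    "generate_expression",
    "mutate_sister",
    "simulate_knockdown",
    "make_class_counts",
    "generate_tissue_profiles",
    "reference_matures",
]

_BASES = np.array(list("ACGT"))
_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _rng(seed: int, tag: str) -> np.random.Generator:
    """Per-operation generator: deterministic, independent across stages."""
    return np.random.default_rng([seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with the defaults that define it.

    ``family_spacing_bp`` is (distribution, parameter): ``("exp", scale)``
    draws exponential spacings clipped to [100, 50000] (mode < 5 kb), and
    ``("uniform", hi)`` draws uniformly on [100, hi].
    """

    seed: int = 0
    n_scaffolds: int = 4
    scaffold_length: int = 150_000
    n_mirnas: int = 60
    n_families: int = 6
    family_size: int = 3
    family_spacing_bp: tuple = ("exp", 5_000)
    family_divergence: float = 0.13
    mature_len: int = 22
    loop_len: int = 15
    flank_len: int = 16
    arm_ratio_5p_3p: float = 4.0
    p5_precision: float = 0.9
    p3_precision: float = 0.5
    reads_per_library: int = 20_000
    background_fraction: float = 0.3
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    sister_mut_rate: float = 0.01
    kd_log2fc_mean: float = -1.04
    kd_log2fc_sd: float = 0.3
    tissue_names: tuple = ("testes", "brain", "pronotum", "antennae", "fat_body")
    n_tissue_specific: int = 10
    n_conserved: int = 12
    expression_sigma: float = 0.8

    def __post_init__(self):
        for name in ("family_divergence", "p5_precision", "p3_precision",
                     "background_fraction", "sister_mut_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mature_len < 16:
            raise ValueError("mature_len must be >= 16")
        if self.loop_len < 3:
            raise ValueError("loop_len must be >= 3")
        if self.arm_ratio_5p_3p <= 0:
            raise ValueError("arm_ratio_5p_3p must be positive")
        if self.n_tissue_specific > self.n_mirnas:
            raise ValueError("n_tissue_specific exceeds n_mirnas")

    @property
    def precursor_len(self) -> int:
        return 2 * (self.flank_len + self.mature_len) + self.loop_len


@dataclass
class TruthTable:
    """Ground truth for planted precursors.

    ``table`` has one row per precursor with its locus, mature spans (genome
    coordinates, 0-based half-open), family id, class label, and tissue flag;
    ``variants`` (filled by :func:`mutate_sister`) records sister-species
    substitutions inside mature spans.
    """

    table: pd.DataFrame
    variants: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["mirna_id", "arm", "position_in_mature", "ref", "alt"]
        )
    )

    def __len__(self):
        return len(self.table)

    def mature_spans(self):
        """Yield (mirna_id, arm, scaffold, start, end) for every mature."""
        for _, row in self.table.iterrows():
            yield row.mirna_id, "5p", row.scaffold, row.m5_start, row.m5_end
            yield row.mirna_id, "3p", row.scaffold, row.m3_start, row.m3_end


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _build_precursor(rng: np.random.Generator, cfg: SimConfig):
    """One hairpin: flank5 + mature5P + loop + rc(flank5 + mature5P).

    The 3P mature is the reverse complement of the 5P mature shifted 2 nt
    toward the 5' flank, leaving the canonical 2-nt 3' overhang on both
    strands of the modelled Dicer duplex.  The loop is poly-C and the last
    four mature bases are A/T-only, so the loop cannot base-pair with itself
    or with the stem-loop junction — planted precursors are clean single
    stem-loops under the folding model (see docs/methods.md).
    """
    fl, ml, ll = cfg.flank_len, cfg.mature_len, cfg.loop_len
    flank5 = _random_seq(rng, fl)
    tail = min(4, ml)
    mature5 = _random_seq(rng, ml - tail) + "".join(
        np.array(["A", "T"])[rng.integers(0, 2, size=tail)]
    )
    loop = "C" * ll
    arm5 = flank5 + mature5
    seq = arm5 + loop + _revcomp(arm5)
    m5 = (fl, fl + ml)
    m3_start = fl + ml + ll + 2
    m3 = (m3_start, m3_start + ml)
    return seq, m5, m3


_PAIR_CHOICES = ["AT", "TA", "GC", "CG", "GT", "TG"]


def _mutate_hairpin(
    rng: np.random.Generator,
    seq: str,
    cfg: SimConfig,
    rate: float,
    compensate: float = 0.9,
    boost: float = 1.25,
) -> str:
    """Structure-preserving divergence for family copies.

    Stem positions mutate mostly as compensatory pair replacements (both
    bases of a pair swapped for a different complementary pair), the rest as
    one-sided mismatches — emulating the purifying selection that keeps
    duplicated precursors folding.  ``boost`` rescales the firing rate so the
    realised per-base divergence tracks ``rate``.  The poly-C loop is left
    untouched.
    """
    L = len(seq)
    arm = cfg.flank_len + cfg.mature_len
    out = list(seq)
    fire = min(1.0, rate * boost)
    for i in range(arm):
        j = L - 1 - i
        if rng.random() < fire:
            if rng.random() < compensate:
                cur = out[i] + out[j]
                opts = [p for p in _PAIR_CHOICES if p != cur]
                p = opts[rng.integers(len(opts))]
                out[i], out[j] = p[0], p[1]
            else:
                k = i if rng.random() < 0.5 else j
                choices = [b for b in "ACGT" if b != out[k]]
                out[k] = choices[rng.integers(3)]
    return "".join(out)


def _draw_spacing(rng: np.random.Generator, spec) -> int:
    kind, param = spec
    if kind == "exp":
        return int(np.clip(rng.exponential(param), 100, 50_000))
    if kind == "uniform":
        return int(rng.integers(100, param + 1))
    raise ValueError(f"unknown spacing spec {spec!r}")


def generate_genome(config: SimConfig) -> tuple[ScaffoldSet, TruthTable]:
    """Plant hairpin precursors (singletons plus tandem families) in i.i.d.
    uniform-ACGT background scaffolds; record every locus in the truth table.
    """
    rng = _rng(config.seed, "genome")
    plen = config.precursor_len
    # assemble the planted units: families first, then singletons
    units = []  # list of (family_id | None, [precursor specs])
    n_in_families = config.n_families * config.family_size
    if n_in_families > config.n_mirnas:
        raise ValueError("families exceed n_mirnas")
    for f in range(config.n_families):
        base_seq, m5, m3 = _build_precursor(rng, config)
        members = []
        for k in range(config.family_size):
            seq = base_seq if k == 0 else _mutate_hairpin(
                rng, base_seq, config, config.family_divergence
            )
            spacing = 0 if k == 0 else _draw_spacing(rng, config.family_spacing_bp)
            members.append((seq, m5, m3, spacing))
        units.append((f"fam{f + 1}", members))
    for s in range(config.n_mirnas - n_in_families):
        seq, m5, m3 = _build_precursor(rng, config)
        units.append((None, [(seq, m5, m3, 0)]))

    scaffolds = ScaffoldSet()
    backgrounds = {}
    for k in range(config.n_scaffolds):
        backgrounds[f"scaffold{k + 1}"] = list(
            _random_seq(rng, config.scaffold_length)
        )

    rows = []
    mirna_idx = 0
    cursor = {name: 1_000 for name in backgrounds}
    names = list(backgrounds)
    next_scaffold = 0
    for fam_id, members in units:
        total_span = sum(plen + sp for _, _, _, sp in members) + 2_000
        # first scaffold with room, round-robin start
        placed = False
        for probe in range(config.n_scaffolds):
            name = names[(next_scaffold + probe) % config.n_scaffolds]
            if cursor[name] + total_span < config.scaffold_length:
                placed = True
                break
        next_scaffold += 1
        if not placed:
            raise ValueError(
                f"scaffold too short for requested plantings (need {total_span} bp "
                f"more on {name})"
            )
        pos = cursor[name]
        prev_end = None
        for seq, m5, m3, spacing in members:
            pos = pos + spacing if prev_end is None else prev_end + spacing
            start, end = pos, pos + plen
            backgrounds[name][start:end] = list(seq)
            mirna_idx += 1
            rows.append(
                {
                    "mirna_id": f"mir{mirna_idx}",
                    "scaffold": name,
                    "start": start,
                    "end": end,
                    "strand": "+",
                    "m5_start": start + m5[0],
                    "m5_end": start + m5[1],
                    "m3_start": start + m3[0],
                    "m3_end": start + m3[1],
                    "family": fam_id or f"single{mirna_idx}",
                    "sequence": seq,
                }
            )
            prev_end = end
        cursor[name] = prev_end + 2_000

    table = pd.DataFrame(rows)
    if len(table):
        conserved = rng.choice(len(table), size=min(config.n_conserved, len(table)),
                               replace=False)
        table["class_label"] = "lineage-specific"
        table.loc[table.index[conserved], "class_label"] = "conserved"
        flags = rng.choice(len(table), size=config.n_tissue_specific, replace=False)
        table["tissue_specific"] = False
        table["tissue"] = ""
        for k, idx in enumerate(flags):
            table.loc[table.index[idx], "tissue_specific"] = True
            table.loc[table.index[idx], "tissue"] = config.tissue_names[
                k % len(config.tissue_names)
            ]
    else:
        table = pd.DataFrame(
            columns=[
                "mirna_id", "scaffold", "start", "end", "strand", "m5_start",
                "m5_end", "m3_start", "m3_end", "family", "sequence",
                "class_label", "tissue_specific", "tissue",
            ]
        )
    for name, chars in backgrounds.items():
        scaffolds[name] = "".join(chars)
    return scaffolds, TruthTable(table)


def generate_expression(truth: TruthTable, config: SimConfig) -> pd.Series:
    """Log-normal per-miRNA relative abundances (the simulated transcriptome)."""
    rng = _rng(config.seed, "expression")
    vals = rng.lognormal(mean=0.0, sigma=config.expression_sigma, size=len(truth))
    return pd.Series(vals, index=truth.table.mirna_id.values, name="abundance")


def generate_reads(
    genome: ScaffoldSet,
    truth: TruthTable,
    config: SimConfig,
    expression: pd.Series,
    library: str = "lib",
    n_hotspots: int = 40,
) -> list[FastqRead]:
    """Draw one small-RNA library from the planted truth.

    Arm reads follow the abundance table with a 5P:3P split of
    ``arm_ratio_5p_3p``; 5' ends are exact with probability ``p5_precision``
    (else jittered by ±1–2 nt) and 3' ends with ``p3_precision`` (else ±1–3
    nt).  ``background_fraction`` of reads are genomic fragments of 18–30 nt,
    half drawn from a pool of degradation "hotspot" loci so that decoy read
    stacks survive copy-number collapsing.  The 3' adapter is appended and
    qualities are constant Q30.
    """
    if len(expression) == 0:
        raise ValueError("empty expression table")
    rng = _rng(config.seed, f"reads:{library}")
    tbl = truth.table.set_index("mirna_id")
    probs = (expression / expression.sum()).reindex(tbl.index).fillna(0.0).values
    p5p = config.arm_ratio_5p_3p / (1.0 + config.arm_ratio_5p_3p)
    scaffold_names = list(genome)
    lengths = np.array([len(genome[s]) for s in scaffold_names], dtype=float)
    scaffold_p = lengths / lengths.sum()
    hotspots = []
    for _ in range(n_hotspots):
        s = rng.choice(len(scaffold_names), p=scaffold_p)
        L = int(rng.integers(18, 31))
        pos = int(rng.integers(0, lengths[s] - L))
        hotspots.append((scaffold_names[s], pos, L))

    reads: list[FastqRead] = []
    for ridx in range(config.reads_per_library):
        if rng.random() < config.background_fraction:
            if hotspots and rng.random() < 0.5:
                name, pos, L = hotspots[rng.integers(len(hotspots))]
            else:
                s = rng.choice(len(scaffold_names), p=scaffold_p)
                name = scaffold_names[s]
                L = int(rng.integers(18, 31))
                pos = int(rng.integers(0, lengths[s] - L))
            seq = genome[name][pos : pos + L]
        else:
            mi = rng.choice(len(tbl), p=probs)
            row = tbl.iloc[mi]
            arm = "5p" if rng.random() < p5p else "3p"
            s0, e0 = (row.m5_start, row.m5_end) if arm == "5p" else (
                row.m3_start, row.m3_end
            )
            if rng.random() >= config.p5_precision:
                s0 += int(rng.choice([-2, -1, 1, 2]))
            if rng.random() >= config.p3_precision:
                e0 += int(rng.choice([-3, -2, -1, 1, 2, 3]))
            seq = genome.fetch(row.scaffold, s0, e0)
        full = seq + config.adapter
        reads.append(FastqRead(f"{library}_r{ridx + 1}", full, "?" * len(full)))
    return reads


def mutate_sister(
    genome: ScaffoldSet, truth: TruthTable, config: SimConfig
) -> tuple[ScaffoldSet, TruthTable]:
    """Apply i.i.d. substitutions at ``sister_mut_rate`` to every scaffold;
    substitutions falling inside truth mature spans are recorded as variant
    truth with their 1-based position in the mature."""
    rng = _rng(config.seed, "sister")
    sister = ScaffoldSet()
    subs: dict[tuple[str, int], tuple[str, str]] = {}
    for name, seq in genome.items():
        chars = list(seq)
        hits = np.nonzero(rng.random(len(seq)) < config.sister_mut_rate)[0]
        for k in hits:
            old = chars[k]
            if old not in "ACGT":
                continue
            choices = [b for b in "ACGT" if b != old]
            new = choices[rng.integers(3)]
            chars[k] = new
            subs[(name, int(k))] = (old, new)
        sister[name] = "".join(chars)
    rows = []
    for mid, arm, scaf, s, e in truth.mature_spans():
        for (name, pos), (old, new) in subs.items():
            if name == scaf and s <= pos < e:
                rows.append(
                    {
                        "mirna_id": mid,
                        "arm": arm,
                        "position_in_mature": pos - s + 1,
                        "ref": old,
                        "alt": new,
                    }
                )
    variants = pd.DataFrame(
        rows, columns=["mirna_id", "arm", "position_in_mature", "ref", "alt"]
    )
    return sister, TruthTable(truth.table.copy(), variants)


_KNOWN_CLASSES = {"miRNA", "snoRNA", "tRNA", "rRNA"}


def make_class_counts(
    config: SimConfig,
    n_mirna: int = 350,
    n_other: int = 120,
    mean_count: float = 300.0,
) -> pd.DataFrame:
    """Baseline expression for the knockdown experiment: rows with a
    ``class`` column in {miRNA, snoRNA, tRNA, rRNA} and a ``count`` column
    drawn from a log-normal around ``mean_count``."""
    rng = _rng(config.seed, "class_counts")
    rows = []
    for cls, n in [("miRNA", n_mirna)] + [
        (c, n_other) for c in ("snoRNA", "tRNA", "rRNA")
    ]:
        vals = rng.lognormal(math.log(mean_count), 0.7, size=n)
        for k, v in enumerate(vals):
            rows.append({"id": f"{cls}_{k + 1}", "class": cls, "count": float(v)})
    return pd.DataFrame(rows).set_index("id")


def simulate_knockdown(
    counts: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a global miRNA-biogenesis knockdown.

    miRNA rows are scaled by 2^x with x ~ Normal(kd_log2fc_mean, sd); other
    classes by 2^y with y ~ Normal(0, sd); both libraries are then Poisson
    resampled.  Both returned frames carry the same ``lib_size`` attribute:
    the modelled small-RNA classes are a minor fraction of total library
    depth, so the knockdown does not shift the normaliser.
    """
    unknown = set(counts["class"]) - _KNOWN_CLASSES
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if (counts["count"] < 0).any():
        raise ValueError("negative counts")
    rng = _rng(config.seed, "knockdown")
    base = counts["count"].values.astype(float)
    is_mir = (counts["class"] == "miRNA").values
    x = rng.normal(config.kd_log2fc_mean, config.kd_log2fc_sd, size=len(base))
    y = rng.normal(0.0, config.kd_log2fc_sd, size=len(base))
    scale = np.where(is_mir, 2.0**x, 2.0**y)
    ctrl = rng.poisson(base).astype(float)
    kd = rng.poisson(base * scale).astype(float)
    lib = float(max(base.sum() * 10, 1.0))
    ctrl_df = pd.DataFrame({"class": counts["class"], "count": ctrl}, index=counts.index)
    kd_df = pd.DataFrame({"class": counts["class"], "count": kd}, index=counts.index)
    ctrl_df.attrs["lib_size"] = lib
    kd_df.attrs["lib_size"] = lib
    return ctrl_df, kd_df


def generate_tissue_profiles(
    truth: TruthTable, config: SimConfig, specific_fold: float = 25.0
) -> pd.DataFrame:
    """miRNA × tissue count matrix: flagged miRNAs get ``specific_fold``-fold
    mean counts in their tissue (>= 20-fold vs every other tissue); all other
    cells follow a shared Gamma–Poisson."""
    rng = _rng(config.seed, "tissue")
    tissues = list(config.tissue_names)
    tbl = truth.table
    lam = rng.gamma(shape=2.0, scale=150.0, size=len(tbl))
    mat = np.empty((len(tbl), len(tissues)), dtype=float)
    for j, _t in enumerate(tissues):
        mat[:, j] = rng.poisson(lam)
    for i, row in enumerate(tbl.itertuples()):
        if row.tissue_specific:
            j = tissues.index(row.tissue)
            mat[i, j] = rng.poisson(lam[i] * specific_fold)
    return pd.DataFrame(mat, index=tbl.mirna_id.values, columns=tissues)


def reference_matures(truth: TruthTable, genome: ScaffoldSet) -> dict[str, str]:
    """The miRBase-style reference mature set: 5P matures of every planted
    conserved miRNA, keyed like 'ref-mir7-5p'."""
    refs = {}
    for row in truth.table.itertuples():
        if row.class_label == "conserved":
            seq = genome[row.scaffold][row.m5_start : row.m5_end]
            refs[f"ref-{row.mirna_id}-5p"] = seq
    return refs
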