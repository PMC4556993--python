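"""Sequence I/O and small-RNA read processing.

Covers the standard-format plumbing (FASTA, FASTQ, BED, GFF3) plus the
read-level steps every small-RNA library goes through before discovery:
quality filtering, 3'-adapter trimming, collapsing to unique sequences with
copy numbers, and length profiling.

Coordinate conventions: 0-based half-open everywhere in memory; BED input is
0-based half-open; GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "ScaffoldSet",
    "CollapsedRead",
    "AnnotationIntervals",
    "FastqRead",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "filter_reads",
    "trim_adapter",
    "collapse_reads",
    "length_distribution",
    "read_bed",
    "write_gff3",
]

_ALPHABET = set("ACGTN")


class ScaffoldSet(dict):
    """Named uppercase DNA sequences; the genome under analysis.

    A thin ``dict`` of ``name -> sequence`` with alphabet validation.
    """

    def __setitem__(self, name: str, seq: str) -> None:
        seq = seq.upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(f"scaffold {name!r} has non-DNA characters: {sorted(bad)}")
        super().__setitem__(name, seq)

    def fetch(self, name: str, start: int, end: int) -> str:
        """Extract [start, end) from a scaffold, clipped to its bounds."""
        seq = self[name]
        return seq[max(0, start) : min(len(seq), end)]


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence and the number of times it was observed."""

    id: str
    sequence: str
    count: int


@dataclass(frozen=True)
class AnnotationInterval:
    scaffold: str
    start: int
    end: int
    strand: str
    category: str


@dataclass
class AnnotationIntervals:
    intervals: list[AnnotationInterval] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self):
        return len(self.intervals)


@dataclass
class FastqRead:
    id: str
    sequence: str
    quality: str  # Phred+33
    trimmed: bool = False


def read_fasta(path) -> ScaffoldSet:
    """Parse a FASTA file into a ScaffoldSet (case folded to upper)."""
    out = ScaffoldSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(scaffolds: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in scaffolds.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def read_fastq(path) -> list[FastqRead]:
    """Parse Phred+33 FASTQ; malformed records raise with the record index."""
    reads: list[FastqRead] = []
    try:
        for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                FastqRead(
                    rec.id,
                    str(rec.seq).upper(),
                    "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    ),
                )
            )
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {len(reads)}: {exc}")
    return reads


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def _is_simple_repeat(seq: str, mono_frac: float = 0.8, motif_frac: float = 0.9) -> bool:
    """Dust-like low-complexity rule: one base >= 80% of the read, or a
    1–2-nt motif tandemly covering >= 90% of it."""
    n = len(seq)
    if n == 0:
        return True
    if max(Counter(seq).values()) >= mono_frac * n:
        return True
    for k in (1, 2):
        for phase in range(k):
            run = best = 0
            motif = None
            for p in range(phase, n - k + 1, k):
                unit = seq[p : p + k]
                if unit == motif:
                    run += k
                else:
                    motif = unit
                    run = k
                best = max(best, run)
            if best >= motif_frac * n:
                return True
    return False


def trim_adapter(
    read: FastqRead,
    adapter: str,
    min_overlap: int = 6,
    max_err_rate: float = 0.1,
) -> FastqRead:
    """Remove the longest 3'-adapter prefix found at the read's 3' end.

    A prefix of length L matches if it aligns to the read suffix with at most
    ``floor(max_err_rate * L)`` mismatches and ``L >= min_overlap``.  Ties
    break toward the longer match; an untrimmed read is returned flagged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    for L in range(min(len(adapter), len(seq)), min_overlap - 1, -1):
        tail = seq[len(seq) - L :]
        prefix = adapter[:L]
        allowed = int(max_err_rate * L)
        mism = sum(a != b for a, b in zip(tail, prefix))
        if mism <= allowed:
            cut = len(seq) - L
            return FastqRead(read.id, seq[:cut], read.quality[:cut], trimmed=True)
    return FastqRead(read.id, seq, read.quality, trimmed=False)


#: discard reasons, in the order they are checked
QC_REASONS = ("length", "max_n", "quality", "simple_repeat")


def filter_reads(
    reads: list[FastqRead],
    min_phred: int = 20,
    max_n: int = 3,
    min_len: int = 18,
    max_len: int = 30,
    adapter: str | None = None,
) -> tuple[list[FastqRead], dict[str, int]]:
    """Quality-filter small-RNA reads, optionally adapter-trimming first.

    Discards reads that (in this order) fall outside [min_len, max_len] after
    trimming, contain more than ``max_n`` Ns, contain any base below
    ``min_phred``, or are simple repeats.  Each discarded read is tallied
    under exactly one reason — the first that applies.
    """
    kept: list[FastqRead] = []
    report = {r: 0 for r in QC_REASONS}
    report["kept"] = 0
    for r in reads:
        if adapter is not None:
            r = trim_adapter(r, adapter)
        if not (min_len <= len(r.sequence) <= max_len):
            report["length"] += 1
        elif r.sequence.count("N") > max_n:
            report["max_n"] += 1
        elif any(ord(q) - 33 < min_phred for q in r.quality):
            report["quality"] += 1
        elif _is_simple_repeat(r.sequence):
            report["simple_repeat"] += 1
        else:
            kept.append(r)
            report["kept"] += 1
    return kept, report


def collapse_reads(reads, min_copy: int = 3) -> list[CollapsedRead]:
    """Merge identical sequences, summing copies; drop entries observed fewer
    than ``min_copy`` times.  Order: count descending, then sequence."""
    counts: Counter = Counter()
    for r in reads:
        seq = r.sequence if isinstance(r, FastqRead) else str(r)
        counts[seq] += 1
    items = [(s, c) for s, c in counts.items() if c >= min_copy]
    items.sort(key=lambda sc: (-sc[1], sc[0]))
    return [
        CollapsedRead(f"u{k}_x{c}", s, c) for k, (s, c) in enumerate(items, start=1)
    ]


def length_distribution(reads, lo: int = 18, hi: int = 30) -> dict[int, int]:
    """Histogram of read lengths over [lo, hi]; out-of-range lengths keep
    their own bins so the histogram always sums to the read count."""
    hist = {n: 0 for n in range(lo, hi + 1)}
    for r in reads:
        seq = r.sequence if hasattr(r, "sequence") else str(r)
        hist[len(seq)] = hist.get(len(seq), 0) + 1
    return hist


_BED_CATEGORIES = {"CDS", "tRNA", "rRNA", "snRNA", "snoRNA", "repeat"}


def read_bed(path) -> AnnotationIntervals:
    """Parse a BED file (0-based half-open); column 4 is the category."""
    out = AnnotationIntervals()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                cols = line.split()
            scaf, start, end = cols[0], int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"BED interval with start >= end: {line!r}")
            category = cols[3] if len(cols) > 3 else "repeat"
            strand = cols[5] if len(cols) > 5 else "."
            out.intervals.append(AnnotationInterval(scaf, start, end, strand, category))
    return out


def write_bed(annotations: AnnotationIntervals, path) -> None:
    with open(path, "w") as fh:
        for iv in annotations:
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.category}\t0\t{iv.strand}\n"
            )


def read_gff3(path):
    """Parse miRNA calls written by :func:`write_gff3` back into
    MiRNACall objects (1-based inclusive -> 0-based half-open)."""
    from .discover import MiRNACall

    calls: dict[str, MiRNACall] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            start, end = int(cols[3]) - 1, int(cols[4])
            if cols[2] == "miRNA_primary_transcript":
                calls[attrs["ID"]] = MiRNACall(
                    attrs["ID"], cols[0], start, end, cols[6], "",
                    class_label=attrs.get("class", "lineage-specific"),
                    family=attrs.get("family"),
                    provenance=attrs.get("provenance", "sequencing"),
                )
            elif cols[2] == "miRNA":
                parent = attrs.get("Derives_from")
                if parent in calls:
                    arm = attrs["ID"].rsplit("-", 1)[-1]
                    if arm == "5p":
                        calls[parent].mature5 = (start, end)
                    elif arm == "3p":
                        calls[parent].mature3 = (start, end)
    return list(calls.values())


def write_gff3(calls, path, genome: ScaffoldSet | None = None) -> None:
    """Write miRNA calls as GFF3 (miRNA_primary_transcript + miRNA features,
    1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for call in calls:
            if genome is not None and call.end > len(genome[call.scaffold]):
                raise ValueError(
                    f"call {call.id} exceeds scaffold {call.scaffold} length"
                )
            attrs = f"ID={call.id};class={call.class_label};provenance={call.provenance}"
            if call.family:
                attrs += f";family={call.family}"
            fh.write(
                "\t".join(
                    [
                        call.scaffold,
                        "mirburst",
                        "miRNA_primary_transcript",
                        str(call.start + 1),
                        str(call.end),
                        f"{call.score_total:.2f}" if call.score_total is not None else ".",
                        call.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for arm in ("5p", "3p"):
                span = call.mature5 if arm == "5p" else call.mature3
                if span is None:
                    continue
                fh.write(
                    "\t".join(
                        [
                            call.scaffold,
                            "mirburst",
                            "miRNA",
                            str(span[0] + 1),
                            str(span[1]),
                            ".",
                            call.strand,
                            ".",
                            f"ID={call.id}-{arm};Derives_from={call.id}",
                        ]
                    )
                    + "\n"
                )
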