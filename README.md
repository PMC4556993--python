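# mirburst

Evidence-based miRNA discovery, authenticity validation, and
local-duplication analysis for repeat-rich insect genomes.

Insect genomes — locusts and their relatives in particular — carry
unexpectedly large miRNA repertoires dominated by young, lineage-specific
genes born from local (tandem) duplication.  Discovering these genes from
small-RNA sequencing is statistically delicate: a candidate is just a stack
of short reads on a genomic hairpin, and degradation fragments, repeats and
other non-coding RNAs produce convincing-looking stacks too.  `mirburst`
implements the full analysis chain for this problem, aimed at genomicists
who want every filtering rule, score and threshold explicit, testable and
calibrated:

- **Discovery** — map collapsed reads (copy ≥ 3) to the genome, excise
  110-nt extension windows around read stacks, fold them, and score each
  candidate as `S = S_reads + S_duplex + S_struct`:
  `S_reads = log2((n_c+1)/(n_i+1))` for position-consistent vs inconsistent
  reads, `S_duplex = ±2` for the 2-nt 3′-overhang Dicer-duplex geometry,
  and `S_struct = −z` where `z` is the minimum-free-energy z-score against
  dinucleotide-shuffled controls.  The score cutoff is chosen by the
  signal-to-noise ratio `N_real(S≥c)/⟨N_perm(S≥c)⟩` over 100 read-position
  permutations (smallest `c` with S/N ≥ 10).
- **Folding** — a fully specified weighted Nussinov dynamic program
  (GC/AU/GU = −3/−2/−1, minimum loop 3) with a strict single-stem-loop
  test, verified against exhaustive enumeration.
- **Homology** — reference matures mapped onto the genome and classified
  with the seed rule: conserved iff zero mismatches at mature positions
  2–8 and no mismatch run longer than 2 elsewhere.
- **Validation statistics** — processing precision percentile curves
  (fraction of reads matching the annotated 5′/3′ ends), TPM expression
  groups (`TPM > 10`, with 5/15 sensitivity variants), one-vs-aggregate
  exact tests for tissue specificity (BH-corrected), and
  biogenesis-knockdown response by RNA class (log2 fold changes,
  Mann–Whitney tests).
- **Cross-species analysis** — sister-species reads aligned to precursors
  at ≤ 2 mismatches, mature-region variants called with the first/last-3-
  base trim, and variant incidence contrasted between conservation classes
  and expression groups by Pearson χ².
- **Duplication scanning** — all-vs-all Smith–Waterman with
  Karlin–Altschul E-values (`E = K·m·n·e^{−λS}`, kept at `E < 10⁻⁵` and
  > 50% coverage), family clustering with majority-rule consensus, and
  GLSEARCH-style glocal scans of ±50-kb genomic flanks with edge-to-edge
  distances binned at 5 kb.
- **Synthetic data** (`mirburst.synthio`) — a first-class generator that
  plants hairpin precursors, tandem families with controlled divergence
  and spacing, a mutated sister genome, tissue-biased profiles, and a
  global-knockdown count table, recording complete ground truth so every
  stage's sensitivity, precision and calibration are measurable.

## Worked example

Discovery on the default synthetic study (60 planted miRNAs, four 150-kb
scaffolds, one 20,000-read library with 30% background):

```python
from mirburst import pipeline, sio, synthio

cfg = synthio.SimConfig(seed=1)
genome, truth = synthio.generate_genome(cfg)
expr = synthio.generate_expression(truth, cfg)
reads = synthio.generate_reads(genome, truth, cfg, expr)
clean, report = sio.filter_reads(reads, adapter=cfg.adapter)
collapsed = sio.collapse_reads(clean)

pcfg = pipeline.PipelineConfig(seed=1)
refs = synthio.reference_matures(truth, genome)
calls, candidates, sn, cutoff = pipeline.discover_calls(
    genome, collapsed, pcfg, refs)
perf = pipeline.evaluate_calls(calls, truth)
n_cons = sum(1 for c in calls if c.class_label == "conserved")
print(f"planted miRNAs: {len(truth)}   reads kept after QC: {report['kept']}")
print(f"unique sequences (copy >= 3): {len(collapsed)}")
print(f"hairpin candidates: {len(candidates)}   S/N-chosen cutoff: {cutoff}")
print(f"calls: {perf['n_calls']} ({n_cons} conserved)   "
      f"sensitivity: {perf['sensitivity']:.2f}   precision: {perf['precision']:.2f}")
```

prints

```
planted miRNAs: 60   reads kept after QC: 19985
unique sequences (copy >= 3): 745
hairpin candidates: 61   S/N-chosen cutoff: 5.5
calls: 59 (10 conserved)   sensitivity: 0.93   precision: 0.95
```

Of 20,000 simulated reads, 745 unique sequences survive QC and the
copy-number floor; 61 read stacks fold into hairpins passing the stability
screen; the permutation calibration places the score cutoff at 5.5, and
the 59 surviving calls recover 93% of the planted precursors with 95%
precision.  The same chain is available from the shell
(`mirburst simulate`, `qc`, `collapse`, `discover`, `run --demo`, …), and
`mirburst.pipeline.run_pipeline` runs every downstream stage — expression,
precision, tissue specificity, knockdown, cross-species variants,
duplication scan — writing GFF3 calls, TSV tables, and a JSON summary.

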