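# cellink

Sequence analysis of cellulase linker regions: the intrinsically disordered
peptides that connect a glycoside hydrolase (GH) Family 6 or 7 catalytic
domain to a Family 1 or 2 carbohydrate-binding module (CBM).

Multidomain cellulases occur in four architectures (domains listed N- to
C-terminus): eukaryotic **GH7/CBM1** and **CBM1/GH6**, and bacterial
**CBM2/GH6** and **GH6/CBM2**. Their linkers are too divergent for
alignment-based annotation, but they carry conserved *statistical*
signatures — length distributions tuned to the flanking domains,
serine/threonine-rich (O-glycosylatable) composition in eukaryotes versus
proline-rich composition in bacteria, glycine enrichment at the domain
junctions, and a striking scarcity of N-glycosylation sequons. `cellink`
is for protein bioinformaticians and enzyme engineers who want those
signatures computed reproducibly from sequence data.

## What it computes

- **Motif-anchored segmentation.** Each architecture is cut into
  CBM / linker / GH at short junction motifs with fixed offsets, e.g. for
  CBM1/GH6: trim all residues more than 6 positions N-terminal to the
  first `QCGG`; end the CBM after the `(S)QC(L)` motif; start the GH6
  5 residues N-terminal to the `(G)N(P)(F)` motif. Parenthesised positions
  are preferred-but-not-required wildcards: candidate matches are scored
  by preferred residues hit, best match wins, ties go to the earliest
  position. All rules live in `src/cellink/data/schemes.yaml`.
- **Length statistics**: mean, median, extremes, range, sample SD per
  linker set; 5-residue histograms; pooled-variance Student's *t*
  (Welch's variant behind a flag) for set contrasts.
- **Composition**: pooled residue fractions; per-linker percent content
  of a residue group against length with an OLS trend line and R².
- **Positional profiles**: each linker split into 11 approximately equal
  bins (residue *i* of length *L* falls in bin ⌊11·i/L⌋); group counts
  pooled per bin across the set and divided by pooled positions — the
  S/T, glycine and proline density along the linker.
- **Sequon statistics**: counts of N-X-S/T (X ≠ P) N-glycosylation
  sequons and of the N-P motif that precludes them.
- **Identity and trees**: all-pairs affine-gap global alignment
  (Needleman–Wunsch, GONNET matrix, gap open 10, gap extend 0.05) for
  percent-identity distributions per domain, and neighbor-joining trees on
  d = 100 − identity for outlier-clade detection.
- **Synthetic data**: a generator that emits motif-bearing proteins for
  all four architectures with truncated-normal linker lengths
  (means 30/42/35/34, SDs 7/8/13/17), class-specific compositions
  (eukaryotic ≈55% S+T, ≈15% P; bacterial ≈40% S+T, ≈35% P) and two
  outlier classes (asparagine-rich ruminal-fungal-like, glycine-rich
  proteobacterial-like), together with a ground-truth boundary table.

## Worked example

```python
from cellink import generate_dataset, batch_segment, length_stats, aa_composition
from cellink.composition import aggregate_sequons

bundle = generate_dataset("GH7_CBM1", n=79, seed=1)          # synthetic dataset
linkers, failures = batch_segment(bundle.to_dataset())        # motif-anchored cuts
stats = length_stats(linkers)
comp = aa_composition(linkers)
print(f"{linkers.n} linkers, {len(failures)} failures")
print(f"length: mean {stats.average:.1f}, median {stats.median:.0f}, "
      f"range {stats.min}-{stats.max}, sd {stats.sd:.1f}")
print(f"composition: S+T {100*comp.fraction('ST'):.1f}%, P {100*comp.fraction('P'):.1f}%")
seq = aggregate_sequons(linkers)
print(f"sequons: {seq.n_sequons} N-X-S/T, {seq.n_NP} N-P, {seq.total_N} N total")
```

prints

```
79 linkers, 0 failures
length: mean 31.5, median 31, range 17-44, sd 6.3
composition: S+T 56.5%, P 14.9%
sequons: 48 N-X-S/T, 13 N-P, 94 N total
```

A GH7/CBM1-class set of 79 proteins segments without failures; the
recovered linkers average ~30 residues with ~55% combined Ser+Thr and
~15% Pro, the eukaryotic signature. (Sequon counts in random synthetic
linkers are higher than in natural linkers, whose N's are
overwhelmingly followed by proline — see `sequon_reference_set` for the
engineered set reproducing the natural tallies.)

The same stages are available from a shell:

```bash
cellink simulate --label GH7_CBM1 --n 79 --seed 1 --out-dir work
cellink segment work/GH7_CBM1.fasta work/GH7_CBM1.metadata.tsv \
        --label GH7_CBM1 --out-prefix work/gh7
cellink stats work/gh7.linkers.fasta
cellink report --seed 1 --out-dir results    # full pipeline + manifest
```

To analyse real sequences, provide a FASTA plus a tab-separated metadata
table (`id organism genus dataset subset_flag ec_number`); the library
never fetches records itself.

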