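# Methods

## Segmentation model

Each of the four cellulase architectures is partitioned by anchoring on
short junction motifs that sit at fixed offsets from the domain
boundaries. All coordinates are 0-based half-open internally; reports use
1-based inclusive positions.

| Architecture | First cut | Second cut |
|---|---|---|
| CBM1/GH6 | CBM ends after the `(S)QC(L)` motif (signal peptide first trimmed to ≤6 residues N-terminal of the first `QCGG`) | GH6 starts 5 residues N-terminal to `(G)N(P)(F)` |
| GH7/CBM1 | GH7 ends 9 residues after the last residue of `[ST][ND]IK` | CBM1 starts 6 residues N-terminal to `QCGG` |
| CBM2/GH6 | CBM2 ends 2 residues C-terminal to the last Cys in the leading 140-residue window | GH6 starts at `RVDN`, falling back to `YVD` |
| GH6/CBM2 | GH6 ends 8 residues after the last residue of `FVML` | CBM2 starts at the first C/L/I/F at least 10 residues downstream of the GH cut |

Pattern syntax: uppercase letters are required, `[XY]` is a required
alternative, `(X)` is a wildcard *preferring* X. Junction motifs such as
`(S)QC(L)` are not absolutely conserved at their flanks, so candidate
matches are scored by the number of preferred residues hit; the
best-scoring match wins and ties resolve to the earliest position. This
replaces the by-eye disambiguation one would do on an alignment with a
deterministic rule.

Design choices where the rules were genuinely open:

- *Offset anchoring.* "Nine residues after the motif" counts from the
  motif's last residue, and the motif itself belongs to the structured
  domain (likewise the `(S)QC(L)` motif belongs to the CBM). The
  alternative readings shift every boundary by a constant and would
  surface as a systematic ±1–4 residue offset in length tables.
- *The conserved CBM2 cysteine* is operationalized as the last Cys within
  a configurable leading window (default 140 ≈ signal peptide + CBM2);
  CBM2 contains several cysteines and it is the C-terminal one that abuts
  the linker.
- *min_linker guard* (default 10) for GH6/CBM2: the rule as stated —
  "cut at the first C/L/I/F" — would otherwise fire on hydrophobic
  residues in the GH tail immediately after the cut.
- *Signal peptides* are trimmed explicitly only for CBM1/GH6 (the one
  architecture whose first anchor does not itself discard the leading
  sequence); elsewhere the first anchor makes trimming implicit.

Failures (missing anchors) are reported per record with a reason and
never silently dropped. Rules, windows and offsets live in
`src/cellink/data/schemes.yaml` and can be overridden without code
changes.

## Statistics

- Length summaries use the sample (n−1) standard deviation and the
  midpoint median; reported tables round averages to integers while
  machine-readable outputs keep full precision.
- The two-sample comparison is the classic pooled-variance two-tailed
  Student's *t* at α = 0.05; Welch's variant is available via
  `welch=True`. No multiple-testing correction is applied across the
  pairwise matrix, matching standard practice for descriptive surveys of
  this size.
- Composition-versus-length trends are ordinary least squares on
  per-linker points (x = length, y = percent content); zero-length
  linkers are excluded from ratios but retained in length statistics.
- Positional profiles assign residue *i* of a length-*L* linker to bin
  ⌊i·n_bins/L⌋ (n_bins = 11), a deterministic realization of
  "approximately equal sections" in which remainder residues land in
  later bins. Profiles are pooled counts per bin across the whole set
  divided by pooled positions — not means of per-sequence fractions — so
  every residue carries equal weight. Linkers shorter than n_bins are
  retained; they simply contribute nothing to some bins.
- The sequon scanner counts N-X-S/T with X ≠ P and, disjointly, N
  followed immediately by P. All overlapping matches count; an N too
  close to the C-terminus to complete a pattern contributes only to the
  N tally.

## Alignment and trees

Percent identities come from all-pairs affine-gap global alignment
(three-state dynamic programming via Bio.Align.PairwiseAligner) under the
GONNET matrix with gap open 10 and gap extend 0.05 — the first gapped
column of a run costs 10, each further column 0.05. The unusual
open/extend ratio is kept deliberately; both values are configurable.
Identity uses identical columns over aligned columns excluding
terminal-gap overhangs. Using pairwise alignments in place of a
progressive multiple alignment is a documented simplification: it
preserves the linker-versus-structured-domain conservation contrast
without depending on a guide tree. Trees are neighbor joining on
d = 100 − identity with negative branch lengths clamped to zero (exact on
additive matrices); outlier-clade separation is read off as the existence
of an edge bipartitioning the outliers from the rest. Exo/endo
subsetting uses EC numbers only (3.2.1.91/176 versus 3.2.1.4);
unclassified records are reported separately.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions under which every
statistic is validated: dataset sizes 79/39/25/15 (plus 5 ruminal-fungal
and 5 proteobacterial outliers), truncated-normal linker lengths with
means 30/42/35/34 and SDs 7/8/13/17 bounded by the observed minima and
maxima, eukaryotic composition S .25 / T .30 / P .15, bacterial
composition P .35 / T .30 / S .10, ruminal N .45 with S+T .05, and
proteobacterial S .30 / T .10 / G .25 (the published description of that
clade is internally inconsistent — "similar combined S/T" yet "50%
serine, 10% threonine" — and this spec is one defensible reading).

Linker residues are i.i.d. draws from the class composition apart from
two explicit mechanisms. First, a linear trend couples S+T (all classes)
and P (bacterial classes) content to length at 0.002 per residue, the
magnitude read off published length-versus-content scatter; trends pivot
at the length-biased mean length (mean + var/mean) so the *pooled*
composition of a generated set equals the class target — pivoting at the
plain mean would bias pooled content upward because long linkers
contribute more residues. Second, an optional terminal modifier swaps
S/T to glycine in the first and last of 11 bins, emulating the
glycine-rich, O-glycan-poor junctions; it is off in the default classes
and exercised via `terminal_glycine_spec`.

Structured domains are low-entropy stub templates shared per class with
5% per-record mutation (25% divergence between the GH7 exo/endo
subfamilies, 30% for outlier clades). Stub alphabets omit every residue
that could complete a spurious junction motif, which is what makes exact
boundary recovery provable rather than probabilistic. Genus pools are
sized so the core eukaryotic sets share 23 genera (|pools| 28 and 37,
overlaps 82.1% and 62.2%). The engineered sequon reference set is built
from inert sequence units (NAS / NPA / NAA / PA / A) so its tallies equal
the natural survey's counts (7 sequons, 100 N-P, 150 N) by construction.

Consequences for interpretation: passing tests show the *pipeline*
recovers the statistics it is pointed at; they do not show that real
linkers are truncated-normal (observed length distributions are visibly
non-normal and the generator is a stated simplification), that real
junction motifs are always present (real records can fail segmentation
and are reported as failures), or that stub domains resemble real folds.

## Numerical choices and problem sizes

Default analysis sizes follow the survey (168 records total); identity
stages are O(n²) alignments and can be capped per dataset via
`identity_max_n` for exploratory runs. Test-suite checks use the same
generator at sizes chosen for statistical headroom: 3-standard-error
bounds for length means at survey n, 3σ binomial bounds for pooled
compositions, 1000 fixed-length-66 linkers for profile flatness (each
bin then pools 6000 positions, binomial σ ≈ 0.0065 against a ±0.02
band), and exhaustive alignment-path enumeration on short pairs where
the path count is tractable. All randomness flows from explicit seeds;
reruns with the same seed are byte-identical.

## Known limitations

- Segmentation handles exactly the four named architectures; no HMM or
  alignment-based domain detection, and multi-CBM proteins are out of
  scope.
- Percent identity from pairwise alignments is not identical to
  MSA-derived identity; only the qualitative domain contrast is claimed.
- The boundary-inclusivity readings above are conventions; a different
  reading shifts linker lengths by small constants.
- O-glycosylation is equated with S/T presence; no site prediction is
  attempted.
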