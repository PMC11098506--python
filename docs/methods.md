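# Methods

`dmsort` analyses (and simulates) a two-bin sort-seq deep mutational
scanning (DMS) screen of the human VDAC2 β10–11 loop.  A pooled library of
single-residue variants, each clone tagged by a unique 15-nt barcode in the
3′ UTR, is expressed in cells carrying a fluorescent phenotype reporter
(GFP-BAK stabilisation, or FLAG staining for VDAC2 expression).  Cells are
sorted into low- and high-fluorescence tail gates, barcodes are amplified
and sequenced from each gate, and variant effects are read out from the
shift of per-barcode read ratios relative to wild-type barcodes.

## Library model

The scanned window is residues 165–180 (human numbering); the wild-type
amino acids default to `QMTFDTAKSKLSQNNF`, the human VDAC2 β10–11 segment
consistent with the residues the screen names (Q165, M166, T167, F168,
D169, A171, F180).  The segment is a configuration value, not an inference,
and can be overridden.  Mouse numbering is shifted by +1 in this region;
the package uses human numbering throughout and treats the mouse offset as
a display concern.

A manifest assigns each clone a barcode, a position, and one of three
exhaustive classes: `wt_syn` (wild-type or synonymous coding — both encode
wild-type protein, so they are pooled as the null class), `missense`, and
`stop` (premature stop; "truncated variants" are identified with this
class).  The default design reproduces the screen's composition: 4,920
clones — 289 wild-type/synonymous, 247 premature stops, and 4,384 missense
clones over all 16 × 19 = 304 single substitutions with a median of 11
unique barcodes per substitution.

Two design choices fill gaps the screen's description leaves open:

* **Barcodes.**  The actual barcode sequences are not published.  Barcodes
  are drawn uniformly over {A,C,G,T}^15 under a minimum pairwise Hamming
  distance (default 3), which makes single-error misassignment impossible
  and keeps mismatch-tolerant assignment provably unambiguous.  An
  infeasible request (more codewords than the constrained space admits)
  is detected by a rejection-count cap.
* **Per-substitution allocation.**  Only the median (11) is known.  The
  allocator starts from a constant 11 per substitution (a configurable
  normal spread may be added, with the middle order statistics pinned), then
  distributes the surplus over the strict upper half of the sorted counts so
  both the median and the stated totals are exact.  When a small total makes
  the target median infeasible, counts fall back to an even split.

## Generative model of a screen

One seed drives the whole chain; each stage consumes an independent spawned
stream.

1. **Clone abundances** are one symmetric Dirichlet draw (concentration
   default 10, giving the ~30% coefficient of variation typical of pooled
   libraries).  Each cell carries exactly one clone — the single-integration
   approximation justified by the screen's low multiplicity of infection
   (< 0.3).  Default `n_cells` is 1.5 × 10⁶, the stated infected-cell count
   (> 300× coverage).
2. **Phenotype**: cell log-fluorescence ~ Normal(effect(variant),
   `cell_sigma`), with `cell_sigma` = 1.0 log unit.  Effects are per-variant
   mean shifts in the same units; wild-type effects are zero by
   construction.
3. **Sorting**: the bottom and top `gate_fraction` (default 0.25 per tail,
   the standard symmetric sort-seq choice; the real gates are unpublished)
   of the fluorescence distribution; ties break by stable order.
4. **Sequencing**: per-barcode read shares are bin cell counts modulated by
   log-normal PCR jitter (`pcr_log_jitter_sd` = 0.3); `reads_per_bin`
   (default 2 × 10⁶) reads are drawn multinomially.  Each read is
   5′-anchor + barcode + 3′-anchor with i.i.d. per-base substitution errors
   (default 0.1%, a typical short-read error rate).  The default anchors are
   the screen's first-round PCR annealing sequences (the 3′ anchor
   reverse-complemented into read orientation); the true vector context
   around the barcode is unpublished, so the layout is configuration.

Depth, jitter, and noise defaults were chosen once so that null barcodes at
median abundance have comfortably detectable counts in both bins; they are
stand-ins for unreported values, not estimates of them.

What the generator does *not* model: double infections, integration-site
effects, growth/selection dynamics between infection and sorting, indels or
quality-dependent errors in reads, and index hopping.  Tests passing on
synthetic data therefore demonstrate correctness of the analysis under this
idealised noise structure, not robustness to every artefact of real
sequencing.

## Barcode extraction and counting

Extraction is anchored matching under Hamming (substitution-only)
tolerance — the barcode is fixed-length with constant flanks, so indel
handling buys nothing at this scale.  The read is scanned left to right and
the first offset where *both* anchors match within `max_anchor_mismatches`
(default 1) yields the 15 bases between them; requiring both anchors makes
the result robust to spurious near-anchor sequence upstream.  Failures are
classified (`short-read`, `no-anchor5`, `no-anchor3`) and counted, never
silently dropped: `reads_assigned + reads_unassigned = reads_seen` is an
enforced invariant of every counting run.

Candidates are assigned to the unique manifest barcode within
`max_barcode_mismatches` (default 1).  Uniqueness is guaranteed by
construction: the index refuses configurations where twice the tolerance
reaches the manifest's minimum pairwise distance (Hamming balls must be
disjoint).  Base qualities are ignored; the distance guarantee already
bounds misassignment.  Counting memoises extraction per unique read
sequence, so cost scales with distinct error patterns rather than reads.

## Statistics

* **Per-barcode enrichment**: log2(high + c) − log2(low + c) with symmetric
  pseudocount c = 0.5 (zero-count handling is unpublished; the symmetric
  pseudocount keeps scores finite and zero-centred).  An optional floor on
  total reads per barcode is off by default.
* **Variant test**: two-sided Mann–Whitney U of each substitution's barcode
  scores against the pooled wild-type/synonymous scores.  The `exact` path
  enumerates the permutation null (valid without ties); `approx` is the
  normal approximation with tie and continuity corrections; `auto` (the
  default) selects exact when there are no ties and the smaller sample has
  ≤ 10 observations — with the default design (11 barcodes vs 289 null) the
  asymptotic path is used, and whether the original analysis used exact or
  asymptotic p-values is unknown.  p-values are clipped into (0, 1] with a
  floor of 1e−300 so the log transform stays finite.
* **Direction and signed log p**: direction is the sign of the median score
  difference (mean difference on a median tie, else 0); the summary value is
  direction × (−log10 p), base 10 so star categories correspond to decades.
  Stars use strict thresholds `* < 0.05`, `** < 0.01`, `*** < 0.001`,
  `**** < 0.0001`.
* **Multiplicity**: raw p-values are reported, matching the screen's
  presentation; an optional Benjamini–Hochberg column (`q_bh`, on by
  default) is provided for convenience and never alters stars.
* Variants with fewer than 2 barcodes are flagged `low_n`, not dropped.
* The heatmap is substitutions (A…Y, then STOP) × positions 165–180 of
  signed log p; wild-type identity cells and untested variants are empty.
  The optional plot uses a diverging palette, blue negative (low-bin skew)
  to red positive (high-bin skew).
* `crosslink_fraction` implements the densitometry summary used alongside
  the screen: 100 × cross-linked intensity / summed total intensity.

## Validation strategy and problem sizes

The screen's raw sequencing is not publicly deposited, so validation
combines (a) exact reproduction of the design arithmetic (composition,
coverage) and (b) statistical properties on synthetic data:

* the exact Mann–Whitney path is checked against an independent brute-force
  enumeration of all arrangements for every sample-size pair up to 7 vs 7;
* type-I calibration runs two full-scale null screens (default design and
  depth, 640 variant tests) and requires the p < 0.05 fraction to sit in
  the 99% binomial interval around 0.05;
* sign/power recovery programs +2σ and −2σ effects on two 11-barcode
  substitutions and requires correct, significant recovery in ≥ 80% of 50
  replicate screens.

The calibration and power checks run the generative chain to per-barcode
read counts at full default depth but skip per-read sequence emission; the
read-level path is validated separately — error-free simulated bins count
back to the simulator's ground truth exactly, and a scaled end-to-end run
(thousands of reads) exercises FASTQ round-tripping, extraction-rate bounds
against a closed-form binomial probability, and byte-level determinism.
This split keeps the statistical checks at the study's scale while the
sequence-level machinery is tested where exactness, not scale, is the
point.

## Numerical notes and edge cases

* Bin sizes are ⌊gate_fraction × n⌋ per tail; the two gates never overlap.
* With all counts zero, every score is exactly 0 and tests degrade
  gracefully (tie-corrected p = 1).
* `sort_bins` on an all-tied population splits by stable input order.
* Manifest I/O validates per row and reports 1-based file line numbers;
  class labels are cross-checked against the variant fields.
* Determinism contract: identical config + seed ⇒ byte-identical manifest,
  FASTQ, and results files.
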