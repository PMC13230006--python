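# Methods

## Problem and scope

Most human introns are excised constitutively; a small annotated
subset coexists in spliced and retained isoforms. This package asks
what the *primary sequence* of an exon–intron–exon (E–I–E) unit says
about that fate. It implements the full analysis chain: event
cataloguing from transcript annotation, five groups of sequence-derived
features, and cost-sensitive models that quantify the joint and
marginal contribution of those features under length-matched controls.
Everything runs on annotation + genome + repeat + motif inputs; there
is no RNA-seq quantification, no structure prediction and no
epigenomic integration.

## Event catalog

Transcripts are decomposed into E–I–E triples, deduplicated within
each gene. A unit is a retained intron (RI) when some transcript of
the gene carries **one exon whose interval equals the unit's outer
span exactly**; near matches are never RIs. Units touched by any
alternative splice-site usage — an exon boundary strictly inside the
unit's intron or strictly inside a flanking exon, from any
span-overlapping transcript of the gene — are excluded rather than
classified. Remaining units are constitutive introns (CIs). Filters:
flanking exons must exceed 6 nt, the intron 26 nt, and the unit
sequence must be free of `N`. Internally all coordinates are 0-based
half-open; GTF and rmsk dialects are converted at the IO boundary.
Upstream/downstream refer to transcription direction, so minus-strand
units read their windows from the reverse complement.

## Feature groups

1. **Lengths** of the three intervals (nt).
2. **GC fractions** of the three intervals, computed on the exact
   intervals, not padded windows.
3. **Splice-site strength** with the canonical maximum-entropy window
   geometry: donor = last 3 exonic + first 6 intronic nt (9-mer),
   acceptor = last 20 intronic + first 3 exonic nt (23-mer), both on
   the transcribed strand. Scoring is pluggable: a table consumer for
   externally supplied score tables, and the default self-trained
   scorer — per-position log2-odds against a uniform background,
   estimated from the catalog's CI contexts with a 0.5 pseudocount.
   Scores from the two scorers are not numerically comparable.
4. **Repeat coverage**: per repeat taxon, the fraction of the intron
   covered by confidently classified elements (class/family containing
   `?` or equal to `unknown` are dropped), same-taxon overlaps merged
   before measuring. Columns default to family-level rollups
   ("SINE Alu", "LINE L1" …), the granularity at which informative
   repeat taxa are usually reported; subfamily (repName) granularity
   and explicit vocabularies are options.
5. **Wavelet descriptors of RBP binding signals** (the methodological
   core, below). 3 descriptors x L levels per RBP; at L = 6 and 130
   RBP position weight matrices this block is 2,340 columns, giving
   the published 2,397-wide matrix with 8 core and 49 repeat columns.

## Binding signals and the MODWT

Each RBP's PWMs score every k-window of the unit's transcribed E–I–E
sequence by summed log2 probability (zero entries floored at 1e-9).
The binding threshold per PWM is the **median score over all 4^k
k-mers** (exact enumeration; lower-middle order statistic for even
counts). A position is occupied when its window score *strictly
exceeds* the threshold, so ties — e.g. under a uniform PWM — yield the
zero signal. Multi-PWM RBPs are merged position-wise by logical OR.
Note that a median threshold leaves a dense background: roughly half
of all windows of random sequence pass, so the descriptors measure the
*texture* of occupancy, not rare hits.

The binary signal is decomposed with a maximal-overlap discrete
wavelet transform using the rescaled Haar pair, wavelet (1/2, −1/2)
and scaling (1/2, 1/2), circular boundary, pyramid recursion at lag
2^(l−1). The transform is undecimated (every level keeps the input
length), valid for any N ≥ 2, translation-equivariant up to circular
shifts, and O(N·L). Only detail vectors w(1..L) feed the descriptors;
the final smooth is discarded. Per level:

* relative energy `E_l = Σ w_i(l)² / Σ_k Σ w_i(k)²` (all zero when the
  total energy is zero);
* outlier fraction `O_l = mean I(|w_i(l)| > M_l + 3·MAD_l)` with
  median and MAD taken on the signed coefficients, MAD without a
  consistency constant, lower-middle median throughout;
* sparsity proxy `S_l = ‖w(l)‖₁ / ‖w(l)‖₂` (0 for a zero vector; 1
  for a one-hot vector, √n for a flat one — lower means sparser).

A subtlety worth stating: at *equal* placement density, clustering
motif hits **lowers** coarse-level S (concentration means sparsity,
and L1/L2 falls); observed constitutive-intron signals show *higher*
energy and higher S, which is the signature of binding that is both
denser and organized into loose hubs. The synthetic generator
therefore plants a joint density-plus-organization contrast, and the
tests document the equal-density inversion explicitly.

L is a parameter (default 6). Column names are `{rbp}|{E|O|S}|L{l}`
in (rbp, descriptor, level) order.

## Models

* **Class weights**: minority weight = n_majority / n_minority,
  majority weight 1 (cost-sensitive splitting).
* **Random Forest**: 1,000 trees and mtry = 100 by default (the
  published setting for 2,397 features; desk-scale runs shrink both —
  see problem sizes). Stratified 5-fold CV; held-out AUC per fold;
  permutation importance on held-out folds (AUC scoring), raw
  importance = cross-fold mean, standardized by twice the cross-fold
  standard deviation and mapped through asinh; zero dispersion is
  floored at 1e-12 so constant signals stay finite. Trees use
  `min_samples_leaf = 10`, the default minimum node size of
  probability forests in ranger-style implementations; leaf-level
  smoothing matters for AUC ranking when positives are rare.
* **Length matching**: greedy Mahalanobis nearest-neighbor matching
  without replacement on the (upstream exon, intron, downstream exon)
  length triple, covariance from the pooled table, 20 controls per
  case, with a standardized-mean-difference balance report. Matching
  runs once on the full catalog; the matched CV keeps each case and
  its controls in one fold (grouped stratified folds), because
  row-wise folds leak each test case's own matched controls into
  training and bias the matched AUC below chance.
* **LASSO selection**: columns standardized, L1-penalized logistic
  regression with the class weights, penalty chosen by internal
  cross-validated deviance (10-fold, capped by the minority count),
  then features with |β| < 1e-5 dropped and survivors ranked by |β|.
* **Scree**: re-run the forest on the top-k importance-ranked columns
  (mtry capped at k) for each requested k.
* **Correlation landscape**: for each selected feature, the max-|r|
  partner among all non-constant columns plus every partner with
  |r| ≥ 0.8; Spearman by default, Pearson available.
* **Variants**: complete, length_matched, rbp_only, repeats_only and
  repeats_only_length_matched are row/column masks over one feature
  matrix fed to the same engine.

## Synthetic study conditions

The generator emits genome FASTA, GTF (retention isoforms as
single-exon transcripts spanning the unit exactly), repeat BED, PWM
text files and a truth table, all deterministic in (config, seed).
Planted contrasts and default magnitudes (`EffectConfig`):

* 3,000 CI / 25 RI (a strong but desk-scale imbalance), plus 3+3+3
  filter-violating plants (intron = 26 nt, exon = 6 nt, an embedded N);
* log-normal lengths: exons ~ LN(ln 120, 0.3); CI introns
  ~ LN(ln 420, 0.4), RI introns ~ LN(ln 150, 0.4). 40% of CIs draw
  the RI length triple — real catalogs contain many short constitutive
  introns, and without that overlap 20:1 length matching would be
  infeasible at this imbalance;
* GC 0.45 (CI) vs 0.55 (RI introns); flanks at baseline composition;
* splice sites written as canonical consensus (GT..AG protected) and
  degraded per position with probability 0.05 (CI) vs 0.40 (RI);
* two repeat taxa (SINE Alu, LINE L1) planted per intron with
  probability 0.75 (CI) vs 0.03 (RI), element length 25% of the
  intron;
* three RBPs (one with two PWMs to exercise OR-merging); motif copies
  planted at 0.4 per 100 nt in loose clustered bursts (CI) vs 0.3 per
  100 nt scattered (RI).

A second frozen condition, `length_only_config` (5,950 CI / 40 RI),
plants *only* the length contrast — bimodal intron lengths
(LN(ln 800, 0.25) vs LN(ln 120, 0.25), 20% short CIs) with near-constant
exons — for the confounder-control experiment: the complete model
scores high from length alone while the length-matched model falls to
chance.

What the generator does **not** emulate: real intron length/GC
marginals beyond these parametric families, overlapping genes, biotype
structure, dependence between features beyond the planted ones, and
realistic PWM shapes. Passing tests therefore demonstrate that the
pipeline recovers planted structure under controlled conditions, not
that any particular biological conclusion holds on real annotation.

## Problem sizes and numerical choices

Desk-scale runs (tests and the reproduction script) use 300 trees,
and mtry = 8 for AUC-focused runs — the same ~4% column fraction the
1,000-tree / mtry-100 setting represents at full width — or mtry =
all columns for importance-focused runs; catalogs of ~3,000–6,000
units. The matched-model AUC is reported as the mean over 5 seeds
because a single seed carries ~0.08 sampling noise with 8 cases per
fold. Ties in PWM thresholding go to zero; medians are lower-middle
order statistics; the LASSO coefficient floor applies on the
standardized scale. Degenerate inputs (zero-energy signals, constant
columns, single-class labels, insufficient controls) raise or are
skipped with warnings as documented per function.

## Known limitations

* Retention is annotation-defined; condition-specific retention from
  RNA-seq is out of scope.
* The fallback splice scorer is catalog-trained and not comparable to
  published maximum-entropy scores; supply score tables for that.
* Permutation importance under heavy redundancy (wavelet blocks,
  correlated lengths) measures conditional, not marginal, relevance;
  the correlation-landscape output exists precisely to read selected
  features in that light.
* With a median k-mer threshold, binding signals are background-dense;
  descriptor contrasts between classes are driven by composition,
  density and organization jointly.
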