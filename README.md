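# retention-grammar

Sequence-level determinants of intron retention in annotated human
transcriptomes.

Most introns are removed constitutively; a minority is annotated in
both spliced and retained isoforms, implying an intrinsic,
sequence-encoded predisposition to retention. This package implements
an end-to-end, annotation-driven analysis of that predisposition for
computational biologists working with GENCODE-style GTFs: it catalogs
exon–intron–exon (E–I–E) units as retained (RI) versus constitutively
spliced (CI) introns, derives five groups of sequence features, and
quantifies their joint discriminative power with cost-sensitive models
under length-matched controls.

## The model in brief

An E–I–E unit is an upstream exon, intron, downstream exon triple. A
unit is an **RI** when some transcript of the gene contains a single
exon spanning the unit's outer boundaries exactly (retention isoform)
while others splice the intron out; units touched by alternative
splice-site usage are excluded; the rest are **CIs**. Each unit is
described by:

* interval lengths and GC fractions (6 features),
* donor/acceptor splice-site strength on the canonical 9-mer / 23-mer
  windows (2 features),
* fractional repeat coverage of the intron per repeat taxon,
* multiscale descriptors of RBP binding: each RBP's PWM hits are
  binarized at the median score of all 4^k k-mers, OR-merged, and
  decomposed with a maximal-overlap discrete wavelet transform (Haar,
  circular, L = 6 levels). Per level *l* the block records the
  relative energy E_l = Σᵢwᵢ(l)²/ΣₖΣᵢwᵢ(k)², the outlier fraction
  O_l = mean I(|wᵢ(l)| > M_l + 3·MAD_l), and the sparsity proxy
  S_l = ‖w(l)‖₁/‖w(l)‖₂ — 18 features per RBP, 2,340 for a 130-RBP
  motif panel, 2,397 in total with 49 repeat taxa.

Intron fate is then modeled with a cost-sensitive Random Forest
(class weight = majority/minority ratio, stratified 5-fold CV, AUC,
held-out permutation importance standardized by 2σ and
asinh-transformed) and an L1-penalized logistic selection, with
Mahalanobis 20:1 length matching to separate length from everything
length drags along. See `docs/methods.md` for the full account.

## Worked example

The package ships a synthetic-study generator whose defaults plant the
class contrasts the analysis expects (short, GC-rich, weak-spliced,
repeat-depleted RIs; denser/clustered CI binding signals), so the whole
pipeline runs without any downloads:

```python
from retention_grammar import build_catalog, build_feature_matrix
from retention_grammar.eie_catalog import label_counts
from retention_grammar.modeling import run_variant
from retention_grammar.synthetic_data import EffectConfig, simulate_study

study = simulate_study(EffectConfig(seed=0))
units = build_catalog(study.transcripts, study.genome)
print(label_counts(units))

fm = build_feature_matrix(units, study.genome,
                          repeats=study.repeats,
                          pwm_groups=study.pwm_groups)
print(fm.X.shape)

report = run_variant(fm, "complete", seed=0, trees=300, mtry=100)
print(f"complete: AUC {report.mean_auc:.3f} +/- {report.sd_auc:.3f}")
print(report.top_features(5))

matched = run_variant(fm, "length_matched", seed=0, trees=300, mtry=8,
                      compute_importance=False)
print(f"length-matched: AUC {matched.mean_auc:.3f}, "
      f"n = {matched.extra['matched_n']}")
```

prints

```
{'CI': 3000, 'RI': 25, 'EXCLUDED': 0}
(3025, 64)
complete: AUC 0.980 +/- 0.045
['acceptor_score', 'gc_intron', 'donor_score', 'len_up', 'gc_up']
length-matched: AUC 0.999, n = 525
```

All 3,000 planted CIs and 25 RIs are recovered (the generator's nine
filter-violating plants are dropped by the catalog filters). The
64-column matrix is 8 core + 2 repeat + 54 wavelet features. The
complete model separates the classes almost perfectly and ranks the
planted splice-site and GC contrasts at the top of this single run
(averaging importances over several seeds also surfaces the repeat and
length contrasts); the
length-matched variant keeps 25 cases + 20 matched controls each. On
this default catalog the compositional effects are strong, so matching
away length barely hurts; the dedicated length-only conditions
(`length_only_config`) show the opposite regime, where matching drops
the AUC from ~0.9 to chance.

The same pipeline is available from the shell:

```bash
retention-grammar simulate --seed 1 --out run/sim
retention-grammar extract  --genome run/sim/genome.fa --gtf run/sim/annotation.gtf --out run/ext
retention-grammar features --genome run/sim/genome.fa --catalog run/ext/catalog.tsv \
    --repeats run/sim/repeats.bed --pwms run/sim/pwms.txt --out run/feat
retention-grammar model    --features run/feat/features.tsv --groups run/feat/feature_groups.json \
    --variant complete --variant length_matched --out run/model
retention-grammar report   --model-dir run/model --out run/report.json
```

For real data, point `extract` at a genome FASTA and a GENCODE-style
GTF (optionally restricted with `--id-prefix NM_`), `features` at a
RepeatMasker rmsk/BED table and a plain-text PWM file.

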