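# tagdge

Tag-based digital gene expression (DGE) profiling, the SAGE-descended
sequencing assay in which each transcript is represented by a single 21nt
restriction tag: the NlaIII recognition site `CATG` plus the 17 bases that
MmeI releases downstream of the transcript's 3'-most `CATG`. Counting tags
counts transcripts, so a two-library experiment (e.g. two tissues or two
phenotypes, one library each) reduces differential expression to comparing
two count vectors.

`tagdge` implements the complete analysis chain for such an experiment —
and, because public raw tag data for this design is scarce, a faithful
simulator of the sequencing protocol so every stage can be exercised and
tested against known truth:

* **simulate** — reference transcripts and genome, two-condition expression
  with known fold changes, and noisy 49bp raw reads (tag + 3' adaptor) with
  substitution errors, `N` calls, empty reads, antisense and intergenic
  transcription;
* **preprocess** — the five cleaning rules (adaptor trimming, empty-read
  removal, `N` filtering, 21nt/`CATG` filtering, copy-number ≥ 2), library
  summaries with percent-of-clean-tag statistics, copy-number distributions
  and saturation (rarefaction) curves;
* **mapping** — the virtual tag library of *all* CATG+17 subsequences of
  the reference genes (both strands) and genome, exact and 1bp-mismatch
  lookup with the precedence perfect-gene > 1MM-gene > perfect-genome >
  1MM-genome > unknown, ambiguity filtering, and TPM normalization
  (count / clean tags × 10⁶);
* **de** — the exact test of Audic & Claverie for two count libraries:
  conditioned on x tags in library 1 (size N₁), the count y in library 2
  (size N₂) follows p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^(x+y+1));
  two-sided p doubles the smaller tail, Benjamini–Hochberg FDR, and calls
  at FDR ≤ 0.001 with |log₂ ratio| ≥ 1;
* **enrichment** — hypergeometric upper-tail P(X ≥ m) for m DEGs among a
  term's M genes in a universe of N annotated genes with n DEGs; Bonferroni
  correction for GO-style terms, BH Q values for pathways;
* **qpcr** — 2^−ΔΔCt relative quantification from Ct tables and
  direction-agreement / rank-correlation concordance with sequencing fold
  changes.

## Worked example

`examples/04_differential_expression.py` simulates a 1,000-gene experiment
(10⁵ tags per library, 5% DE genes at 4–16 fold, 1% sequencing error), runs
the full pipeline and screens DEGs:

```
clean tags: 83,476 (lib1) / 83,917 (lib2)
calls at FDR<=0.001, |log2 ratio|>=1: 28 up, 18 down, 954 ns
of 50 truly DE genes, 46 were called (92% sensitivity on this draw)

strongest calls (x, y = unambiguous tag counts per library):
          x     y      tpm1       tpm2  log2_ratio  fdr call
g00803  153  2162  1832.862  25763.552       3.813  0.0   up
g00530  184  1561  2204.226  18601.714       3.077  0.0   up
...
example p-value, x=10 vs y=40 at N1=N2=10^5: 2.39e-05
```

`x` and `y` are the copy-number sums of the unambiguous sense tags mapped to
each gene; `tpm` rescales them to tags per million clean tags so the two
libraries are comparable; the `log2_ratio` is log₂(tpm2/tpm1) with a small
floor so genes absent from one library stay finite; `call` applies the
screening thresholds. The other examples demonstrate simulation
(`01`), cleaning and saturation (`02`), virtual-library mapping (`03`),
planted-signal enrichment (`05`) and qPCR concordance (`06`); each prints
the numbers it computes and a line on how to read them.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full analysis from scratch at the given seed — simulation,
cleaning, library summary, copy-number bins, saturation, mapping,
differential expression, enrichment and qPCR concordance — printing the
summary of every stage and writing the results file.

## Caveats worth knowing

Expression is normalized to total clean tags (TPM), the convention of this
assay. Total-count normalization is compositional: if a highly abundant
transcript changes strongly, every other gene's *relative* abundance shifts
in the opposite direction, and the exact test will faithfully report those
relative changes. `docs/methods.md` quantifies this and the other
modelling assumptions, and states what the synthetic data does and does not
establish about real libraries.
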