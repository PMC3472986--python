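# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `tagdge`. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The assay being modelled

Digital gene expression (DGE) tag profiling sequences one 21nt tag per
transcript: cDNA bound to oligo(dT) beads is digested with NlaIII (cuts at
`CATG`), the retained 3' fragment's `CATG` end is ligated to an adaptor
whose junction creates an MmeI site, and MmeI cuts 17bp downstream, so the
released tag is `CATG` + 17nt. Sequenced 49bp reads therefore contain the
tag followed by the 3' adaptor. Because digestion proceeds from the bead,
each transcript is represented by its **3'-most** extractable `CATG` site;
the mapping index, by contrast, must contain **all** CATG+17 subsequences
of the reference (a tag observed in a read may come from an incompletely
digested or annotated isoform). This asymmetry — reads from the 3'-most
site, library from all sites — is reproduced in the simulator and mapper.

## Synthetic data generator

The generator's role is to make every downstream stage testable against
known truth. What it emulates, and the defaults chosen where the protocol
description gives no number:

* **Reference** (`generate_reference`): random A/C/G/T transcripts, default
  200–2000nt. At least 95% of genes are guaranteed an extractable tag
  (`tag_fraction=0.95`; nearly all real transcripts contain an NlaIII site,
  and the guarantee is enforced by planting an anchor where the random
  sequence lacks one). The genome concatenates the genes with random
  intergenic spacers amounting to 20% of the genome by default — enough
  intergenic sequence to exercise genome-only mapping without dominating
  the library at desk scale.
* **Expression** (`simulate_expression`): baseline relative abundances are
  log-normal with σ = 1.5. This matches the character of real tag
  libraries — a small number of transcript species at very high copy
  number and a long tail of rare ones (in published two-library data of
  this design, the 2–5-copy bin holds >half of distinct tags while
  >100-copy tags hold ~59% of the total mass). A fraction of genes
  (default 5%) receives a fold change drawn log-uniformly from [4, 16],
  inverted for a random half; condition-2 probabilities are renormalized
  and both libraries are exact multinomial draws, so counts sum exactly to
  the requested depths (desk default 10⁵ per library; the real assay runs
  ~3.4M).
* **Reads** (`simulate_reads`): per gene count, one read = 3'-most tag +
  adaptor, padded to 49nt. Substitution errors are independent per base,
  uniform over the three alternatives, no indels (tags are fixed length);
  `N` calls likewise per base. Artefact classes: adaptor-only empty reads
  (default 1% — their real-world rate is not documented), antisense reads
  (tags of the reverse-complement strand, 2%) and intergenic reads (tags
  from genomic spacers, 2%), enough to populate every mapping category.
  The adaptor itself is unpublished; the default is a fixed 28nt
  placeholder chosen aperiodic (no self-overlap), which makes trimming
  unambiguous on error-free reads.

What the generator does **not** model: PCR duplication, quality-score
structure (FASTQ output uses a constant quality), indels, isoforms sharing
3' ends, and incomplete NlaIII digestion. A green round-trip test therefore
establishes that the pipeline inverts the stated generative model — not
that it is robust to every artefact of a real flowcell.

## Cleaning rules

Raw 49nt reads become clean tags by, in order: (1) cut at the adaptor,
located by the first exact occurrence of its leading 8nt
(`min_overlap=8`); anchoring on the prefix rather than the full adaptor
keeps reads whose adaptor region carries sequencing errors, the standard
tag-seq behaviour; (2) drop reads with nothing before the adaptor (empty);
(3) drop tags containing `N`; (4) keep only tags of exactly 21nt beginning
`CATG` (reads in which the adaptor prefix was never found cannot delimit a
21nt tag and fall here); (5) drop tags whose library-wide copy number is 1,
the conventional guard against singleton sequencing errors. Rules 3–5
commute given the output of 1–2 (asserted by permutation in the tests).

Consequences worth stating: a gene whose true count is 1 is *by
construction* unrecoverable (rule 5 removes its tag), and comes back as 0;
a tag that happens to contain the adaptor's 8nt prefix internally is cut
early and lost — with a random 28nt adaptor this affects ~2 tags in 10,000.

Percentages in library summaries are computed as 100 × numerator /
denominator rounded **half-up** to two decimals, matching the printed style
of published summary tables (Python's default banker's rounding would
differ on exact halves).

## Mapping

The virtual library is a hash from 21nt tag to all loci (gene or genome,
strand, 0-based sense-strand offset of the `CATG`). 1bp-mismatch lookup
enumerates the 51 Hamming-1 neighbours of a tag (3 alternatives × 17
non-anchor positions) against the hash — exact and fast at tag scale. The
`CATG` anchor is excluded from enumeration by default because every clean
tag and every library key begins `CATG`, making anchor mismatches
unproductive; `mismatch_in_anchor=True` restores the full 63-neighbour
enumeration for libraries built from arbitrary keys.

Precedence is perfect-gene > 1MM-gene > perfect-genome > 1MM-genome >
unknown (gene evidence outranks genome evidence; perfect outranks
mismatched). Within the winning level the tag's gene set decides
multiplicity: more than one gene ⇒ ambiguous, excluded from expression. A
tag hitting the same gene on both strands counts once, as sense.
Antisense-assigned counts are tallied per gene but not added to expression
— whether published pipelines included them is unknowable, and excluding
them is the conservative choice. TPM(g) = count(g) / clean_total × 10⁶.

## Exact test and screening

Under equal expression the count y in library 2, conditioned on x in
library 1, is negative binomial: p(y|x) = C(x+y, y) q^(x+1) (1−q)^y with
q = N₁/(N₁+N₂). Tails are evaluated through the regularized incomplete
beta function (`scipy.special.betainc`), exact to ~1e-14 and O(1) up to
counts of 10⁶; the test suite cross-checks against direct log-gamma tail
summation to 1e-10. The two-sided p doubles the smaller inclusive tail,
capped at 1.

This doubled-min-tail definition is **not** symmetric under swapping the
libraries — e.g. with N₁ = N₂, (x=0, y=5) gives p = 1/16 but (x=5, y=0)
gives 1/32, because the two conditionals NB(1, ½) and NB(6, ½) weight the
observed point differently. The asymmetry is inherent to conditioning on
one library and is documented rather than hidden; tests assert the
properties that do hold (oracle equality, normalization, monotonicity in
|y − x|).

FDR is Benjamini–Hochberg step-up (via statsmodels), returned in input
order. Screening calls a gene up (down) when FDR ≤ 0.001 and log₂ ratio
≥ 1 (≤ −1). The ratio uses TPMs with a floor of 0.001 TPM so genes absent
from one library keep a large-but-finite ratio (published tables show
finite values like −14.8 for such genes, implying some floor; the exact
historical convention is unrecoverable, and the floor only affects genes
with a zero on one side).

## Enrichment

P(X ≥ m) for X ~ Hypergeometric(N, M, n), where the universe N is the set
of genes carrying ≥ 1 annotation of the relevant kind (not all reference
genes) and DEGs outside it are dropped. Exact integer enumeration is used
for N ≤ 500 (error ~1 ulp); larger universes use log-gamma summation. GO
terms are Bonferroni-corrected by the number of terms actually tested;
pathway "Q values" are BH-adjusted p-values (the named method behind
published "Q value" thresholds is unstated; BH is the standard reading).
Annotations are flat sets — no ontology-graph propagation.

## qPCR validation

ΔCt = Ct_target − Ct_reference per replicate, averaged per gene × sample;
ΔΔCt subtracts the calibrator sample; fold = 2^−ΔΔCt with amplification
efficiency assumed exactly 2 (efficiency regression is out of scope). The
replicate SD is the SD of replicate-wise folds around the calibrator mean.
Concordance reports the fraction of genes whose sequencing and qPCR log₂
fold changes share a sign (zeros agree with anything) and the Spearman
rank correlation.

## Known limitations

* **Compositionality of TPM.** Normalizing by total clean tags means the
  measured quantity is *relative* abundance. When a high-abundance gene
  changes strongly, the renormalization factor c = Σ pᵢfᵢ moves every
  other gene's relative ratio to 1/c; with heavy-tailed abundances c can
  reach ~1.6 in a 5%-DE draw, and the exact test then flags well-measured
  unchanged genes as relatively down. This is a property of the assay's
  normalization convention, faithfully reproduced; modern count-based
  methods address it with median-of-ratios or TMM size factors, which are
  deliberately out of scope here.
* **Sensitivity at conventional thresholds.** With log-normal (σ = 1.5)
  abundances, a realistic share of DE genes sits at counts too low for
  FDR ≤ 0.001 at 4-fold even with perfect recovery; sensitivity against
  the full truth table plateaus around 0.75 at 100 tags/gene mean depth.
  Deeper libraries, larger folds or relaxed thresholds raise it; the
  package reports what the stated world yields.
* One library per condition: no biological replication, hence no
  dispersion estimation — exactly the design the exact test was built for,
  and its known blind spot.
* The singleton rule erases true count-1 observations; saturation curves
  and low-end sensitivity inherit this.
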