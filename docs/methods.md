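# Methods

This note records the models, conventions and numerical choices behind
`mitocomp`, and what the synthetic benchmarks do and do not establish.

## Coordinates and gene vocabulary

Internally every feature is 0-based, half-open, on the deposited forward
strand (taken to be the J, majority strand); GenBank I/O converts exactly to
and from 1-based inclusive coordinates, and a `join` across the origin of a
circular sequence becomes a single wrapping feature.  Annotation names are
mapped onto a controlled 38-label vocabulary (13 PCGs, 22 tRNAs with
trnL1/trnL2 and trnS1/trnS2 codon-family splits, rrnL/rrnS, CR) through an
editable TSV synonym table; unmappable names become `other` rather than
aborting a run.  Duplicated labels carry a `copy_index` in annotation order.

Structural accounting treats intergenic spacers as maximal unannotated gaps
between consecutive features on the circle and overlaps as positive
intersections of consecutive features.  When the annotation tiles the circle
this yields the identity Σ(non-CR spans) − Σ(overlaps) + Σ(IGS) + CR length
= genome length, which the suite asserts on every simulated genome.  The CR
can also be located on unannotated records, either as the longest
unannotated stretch or as the stretch flanked by rrnS/trnI (the
ephemerellid arrangement); the flanked strategy wins under `auto`.

## Composition and skews

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C).  Gene-level profiles are
computed on the sense (coding) strand; the whole-genome profile on the
forward strand, by default including the CR (a switch excludes it).  IUPAC
ambiguity codes stay in the sequence but are excluded from every numerator
and denominator; each profile reports its ambiguous-base count.  A skew
whose denominator is zero is reported as 0 with a `defined=False` flag so
degenerate toy inputs do not kill batch runs.  Codon-position profiles
anchor the frame at each gene's annotated start, honouring `codon_start`.

## Codon usage and RSCU

Translation table 5 (invertebrate mitochondrial): AGA/AGG = Ser, ATA = Met,
TGA = Trp, stops TAA/TAG.  Start codons are taken verbatim from the CDS
(ATN, GTG, TTG and the CGA start of COX1 all occur); a trailing T or TA is
an incomplete stop completed by mRNA polyadenylation and is tagged as such.
Start codons and (in)complete stops are excluded from usage and RSCU counts
by default — non-ATN starts would otherwise distort rare-codon counts —
with flags to include them for sensitivity analysis.  Codons containing
ambiguity codes are dropped and tallied; in-frame internal stops warn (with
gene and offset) instead of raising, since they usually indicate annotation
slippage in deposited records.  RSCU of codon c in family F is
`count_c · |F| / Σ_F count`; zero-usage families report all-zero RSCU and
are listed separately.

## Gene order

Orders are circular sequences of signed labels with duplicates.
Normalization anchors at COX1(+) — never rearranged in this clade — after
considering both the order and its reflection, falling back to the
lexicographically minimal rotation; it is idempotent and
rotation-invariant.  Breakpoint distance counts signed circular adjacencies
of the reference absent from the order, with the adjacency (a→b)
identified with (−b→−a).  Duplicates collapse to the copy retaining a
reference-context adjacency, which makes the distance well defined under
duplication.

Event classification is a two-pass heuristic for single-gene events: every
gene whose strand or (prev, next) context changed is a candidate; a
candidate without a strand flip whose context difference vanishes when the
other candidates are deleted from both orders is a bystander (its
neighbours moved, it did not); remaining movers are classified — with
bystanders retained as landmarks — as inversion (strand only),
translocation (context only) or inverse-translocation (both), plus
duplication events for multi-copy labels.  On the ephemerellid arrangement
this reports exactly one event: a trnI inverse-translocation from
(CR, trnQ) to (rrnS, CR).

Single-event TDRL explainability enumerates every contiguous circular block
up to `max_block` genes, duplicates it in tandem, and deletes one copy of
each duplicated gene (2^b loss patterns), comparing results up to rotation.
TDRL preserves strands, so any per-gene sign difference short-circuits to
"not applicable" with the genes needing a prior inversion listed — which is
precisely the situation of the ephemerellid trnI, where duplication
evidence (tandem trnI copies) coexists with an inversion that a single TDRL
event cannot produce.  Multi-event scenarios are out of scope
(exponential); the checker is verified against exhaustive enumeration for
n ≤ 6.

## Divergence

The conserved-block filter is Gblocks-like with explicit semantics: a
column is conserved when its most frequent unambiguous residue reaches
`min_conserved_frac` of rows (and, unless `allow_gaps`, contains no gaps);
failing runs longer than `max_nonconserved_run` split blocks; blocks are
trimmed to conserved ends and dropped below `min_block_len`; gap columns
are removed unconditionally when gaps are disallowed.  Selected column
indices are recorded for reproducibility.

π is the average pairwise proportion of differing sites without the
n/(n−1) correction (DnaSP convention), after complete deletion of columns
containing gaps or ambiguity; sliding windows apply complete deletion
within each window and report NaN when nothing is comparable.  Defaults of
window 200 bp / step 20 bp over the concatenated PCG alignment are a
package choice (no canonical values exist) and are embedded in every
report.  Distances: p, JC69 (d = −¾ ln(1 − 4p/3)) and K2P
(d = −½ ln((1−2P−Q)√(1−2Q))); saturated arguments raise with the offending
proportions.  K2P is the default for distance matrices, matching the most
common toolchain default for such tables.

NG86 Ka/Ks: per-codon synonymous site fractions exclude stop-creating
changes from the per-position denominator, so S + N = 3L holds exactly for
L compared codons; multi-difference codons average (sd, nd) uniformly over
all shortest mutational pathways that avoid stops, and codon pairs whose
every pathway crosses a stop are skipped and counted.  Proportions pS, pN
are JC-corrected; the ratio is NA when Ks = 0 or a proportion reaches 3/4.
Panel-level values are means over all sequence pairs (saturated pairs
dropped), with the ratio formed as mean(Ka)/mean(Ks).

## Phylogenetics

Supermatrices concatenate gene alignments in a fixed canonical order with
gap-padding for missing taxa; P12 variants drop every third codon column of
PCG partitions and therefore require codon-flagged alignments.  Exports are
relaxed Phylip, FASTA, and RAxML-style partition files (`GENE = start-end\3`
codon sub-partitions).  ML/Bayesian inference is deliberately delegated to
external tools; the in-repo inference surface is canonical Saitou–Nei
neighbor joining with deterministic lexicographic tie-breaking and negative
branch estimates clamped to zero, verified to reconstruct additive matrices
exactly and cross-checked against an independent NJ implementation.
Monophyly on the unrooted tree is the existence of an edge bipartition
separating the taxon set from the rest.

## Synthetic panels

The generator's defaults describe an ephemerellid-like study: 12 taxa in
six genera on a fixed tree with pairwise divergences of roughly 0.1–0.25
substitutions/site, ~3725 encoded amino acids across the 13 PCGs, per-gene
ω between 0.02 (COX1) and 0.33 (ATP8), kappa 4, position-specific base
composition giving ~64–65% genome A+T with a T-rich second and A+T-rich
third position, tRNAs of 66 bp, rRNAs of 1250/800 bp, a 780 bp CR with a
planted 9-mer tandem repeat, a handful of 1–30 bp spacers, and the
conserved 4 bp ATP8–ATP6 and 7 bp ND4–ND4L overlaps (engineered via frozen
codons at the junctions so the shared bases are consistent on both
annotations; ND4L consequently carries an incomplete stop).  The gene order
is the ephemerellid arrangement — trnI inverted and translocated between
rrnS and the CR — optionally with tandem trnI copies as in *Torleya*-like
genomes; the ancestral insect order is available as an alternative
template.

Coding sequences evolve by Poisson-many proposal events per branch
(expected `t` per site): a proposed nucleotide change is drawn with
kappa-weighted, composition-biased probabilities, rejected if it creates a
stop, and accepted with probability ω when nonsynonymous.  This is not a
time-reversible rate-matrix model and branch lengths are nominal proposal
scales, not realized substitution counts; it is adequate for what the tests
ask of it (ordering and recovery: realized dN/dS tracks ω, third-position
composition tracks its target, π grows with tree scale) and cheap enough to
simulate full panels in under a second.  tRNAs, rRNAs, the CR and spacers
evolve neutrally.  There are no indels, so the generator's "true
alignments" are exact and alignment uncertainty is outside what passing
tests demonstrate about real data — as are recombination, heteroplasmy and
annotation error.  A single seed drives everything through per-gene,
per-branch derived substreams; identical configurations give byte-identical
GenBank output.

The tandem-repeat detector scans periods 1..max_period for maximal runs
with s[i] = s[i−p], reporting motif, period, copy number and span; planted
repeats are re-detected whenever the thresholds admit them.

## Problem sizes

The default test suite and the acceptance script run full-size 12-taxon
panels (≈15.5 kb genomes), 15 replicate genes per ω level for rate
recovery, exhaustive TDRL enumeration at n ≤ 6, and monophyly enumeration
at n = 8 — sizes chosen so the whole suite completes in well under a
minute while keeping every comparison at the scale the statistics need.

## Known limitations

* Single-event TDRL only; no DCJ/HP rearrangement distances.
* NG86 only (no ML dN/dS, no rate heterogeneity).
* The event classifier is a heuristic for single-gene rearrangements and
  does not adjudicate mechanism; for the ephemerellid trnI it reports the
  inversion+translocation pattern and, separately, that one TDRL event
  cannot invert — both facts, no verdict.
* tRNA secondary structure, genome annotation from raw sequence, and
  ML/Bayesian tree inference are intentionally out of scope.
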