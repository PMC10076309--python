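# Methods

## The assay being modelled

The package models a pooled multiplex amplicon-sequencing assay for
*Anopheles stephensi*: ten amplicons (ACE1_I, ACE1_II, CO1, GSTe2, ITS2,
Rdl1, Rdl2, VGSCI, VGSCII, VGSCIII/IV) of roughly 500 bp, each sample tagged
by a 6 bp inline barcode on both the forward and the reverse primer, pooled
to at most 200 amplicons per pool and sequenced 2 × 250 bp. Seven resistance
markers are catalogued: vgsc L958F (L1014F in *M. domestica* numbering,
offset +56), rdl A296S/V327I/T345S (*D. melanogaster* numbering, offset +5),
ace1 G119S and N177D, and GSTe2 V189L.

The panel shipped by `build_default_panel()` is synthetic: reference
sequences are seeded uniform random DNA, bracketed by random primers, with
the marker reference codons written in at the correct codon coordinates so
that each marker is realisable as a single-base substitution
(`marker_site()` returns it). Gene models use self-contained toy contig
coordinates; what is faithful to the real assay is the *structure* — barcode
scheme, amplicon sizes, codon numbering with ortholog offsets, marker
catalogue — not the base sequence. GSTe2 is modelled on the minus strand so
the reverse-strand annotation path is exercised by default. CO1 and ITS2
carry no gene model and annotate as non-coding; they exist for the
phylogenetics stages. Random CDS sequence may contain internal stop codons;
the effect engine simply translates and compares, so this is harmless.

## Synthetic data generator

The generator *is* the study condition, not a tuning knob. Defaults:

- `reads_per_amplicon_mean = 250`, Poisson-distributed per amplicon-sample
  unit (the assay's "250 pairs per amplicon in a 200-amplicon pool").
- `read_length = 250` (2 × 250 bp); fragment length equals amplicon length
  (no shearing in amplicon sequencing), so mates overlap mid-amplicon.
- Genotypes are drawn Hardy–Weinberg from each planted variant's population
  allele frequency, independently across sites (no linkage). Heterozygous
  fragments carry the alternate allele with probability 0.5 each.
- Base qualities follow a two-point model `(high_q=37, low_q=12,
  fraction_low=0.02)`. Substitution errors occur at `base_error_rate`
  (default 0.001) for high-quality bases and scaled up by the phred ratio
  for low-quality bases (capped at 0.75); the erroneous base is uniform over
  the other three. Low-quality bases sit below the phred-30 pileup filter,
  so they model the quality-trimmed tail of real reads.
- Indels are supported as single planted events of ≤ 10 bp (VCF-style
  anchored alleles); no indel *error* process is simulated.
- One integer seed drives one `numpy` generator stream; per-pool seeds are
  derived arithmetically so pools are independent but reproducible.

Not emulated: index hopping, chimeric reads, PCR duplicates and
amplification bias, quality-score drift along the read, strand bias.
Passing tests therefore demonstrate the correctness of the *pipeline logic*
under an idealised error model, not robustness to every real-world artefact.

## Barcodes and demultiplexing

Within a pool every barcode (forward and reverse sets together) comes from
an extended Reed–Solomon [6,3] code over GF(4): 64 words at pairwise Hamming
distance 4, drawn in seeded random order; requests beyond 64 are filled
greedily at distance ≥ 3 (a distance-3 6-mer code tops out near 90–100
words, so large cohorts span multiple pools). Distance ≥ 3 with a 1-mismatch
tolerance makes single-substitution demultiplexing exact, which the tests
verify exhaustively over all 1-edit neighbours.

A pair is assigned only when both mates' barcodes resolve (within
`max_barcode_mismatch = 1`) to the *same* sample; the amplicon comes from
the read-1 primer (≤ 2 mismatches), cross-checked against the read-2 primer
when it maps. Ties at equal distance are ambiguous → unassigned. The 3' ends
are quality-trimmed (cut at the first base under phred 20 after the last
4-base window of mean ≥ 20, then trailing sub-20 bases stripped) before the
technical prefix (barcode + primer) is removed. Assignment is per-read
deterministic, hence order-independent.

## Alignment and pileups

Reads are aligned to their amplicon reference with edlib (unit-cost
edit-distance, infix mode). Leading/trailing regions that fail to anchor on
a run of ≥ 8 exact matches are converted to soft clips; reads whose total
clip exceeds 50 bp, or whose edit distance exceeds 25 % of their length, are
discarded. Unit gap costs were chosen over affine scoring because the
simulator's indels are single planted events; minimal-edit alignments can
split an ambiguous indel around a coincidentally matching base, which the
deletion-event reconstruction partially undoes by merging equal-support
runs (a known representational limit, see Limitations).

Overlapping mate bases are reconciled into one fragment observation:
agreement keeps the higher phred; disagreement keeps the higher-phred base
with its quality capped at the phred difference. Pileups then drop
observations below phred 30 ("minimum phred quality of 30 per called
base"); depth is the retained observation count, so the depth filter is
applied after base-quality filtering. Deletion observations inherit their
fragment's minimum flanking base quality.

## Variant calling and filters

Two callers run on every pileup:

- **Frequency caller** — emits the most frequent non-reference allele
  wherever alternate depth ≥ 10 at depth ≥ 30. Site quality is the
  phred-scaled binomial tail P(≥ AD_alt error bases | DP, ē/3) with ē the
  mean per-observation error probability from the quality scores. Indel
  events (insertions keyed by position and sequence; deletions rebuilt from
  per-position support runs) are called here only, as VCF-anchored alleles.
- **Genotype-likelihood caller** — diploid likelihoods for {hom-ref, het,
  hom-alt} under a symmetric error model (P(alt read | het) = ½(1−e) +
  ½e/3), uniform prior; a site is called when the non-reference posterior
  exceeds 0.99. Site quality is the phred of P(hom-ref | data). SNVs only.

The merged union records caller provenance (`single_caller` flag on
one-caller sites, `shared_position` on multi-allelic positions). Genotypes
follow the alternate-fraction rule with boundaries inclusive to the
heterozygote: f < 0.25 hom-ref, 0.25 ≤ f ≤ 0.75 het, f > 0.75 hom-alt.
Depth thresholds are inclusive (DP ≥ 30, AD ≥ 10). The replication filter
retains a variant key only when ≥ 2 samples carry it (non-hom-ref, site
filters passing) across ≥ 2 distinct pools; dropped keys are flagged
(`singleton` / `single_pool`), never deleted, and `min_pools` is
configurable for single-pool runs. Output is hand-written VCF 4.2 (1-based)
with per-sample GT:AD:DP columns.

## Annotation and marker reporting

Variants map amplicon position → contig position → CDS position through the
gene model (multi-interval capable; panel models use single intervals),
honouring strand; codons are rebuilt and translated with the standard code.
Codon numbers are native numbering via each fragment's `codon_offset`;
ortholog labels are pure offsets (+56 vgsc, +5 rdl), verified in tests
against the published equivalences. Length-changing alleles are frameshift
unless the net change is a multiple of 3; variants straddling a CDS
boundary are flagged composite rather than dropped.

The marker report genotypes *every* sample with ≥ 30× depth at each marker
site directly from its pileup, so homozygous-reference samples enter the
denominator. Carrier percentage = (het + hom-alt)/genotyped; allele
frequency = (het + 2·hom-alt)/(2·genotyped). Denominators are always
printed beside percentages because sample drop-out at a site makes bare
percentages ambiguous.

## Population genetics

Consensus calling keeps samples with mean amplicon depth strictly above
50×, emits the majority base (lexicographic tie-break), N below 5× site
depth, and optionally IUPAC codes at heterozygous sites (default: major
allele, documented). Same-amplicon consensus sequences are equal length, so
alignment is positional; externally aligned FASTA (`sample|population`
headers) is the alternative input path. Sites with N or a gap in *any*
sequence are masked set-wide (complete deletion) before all statistics; the
pairwise-deletion alternative is not implemented.

π, Hd, θ_W and Tajima's D use the textbook formulas (D with the standard
a₁,a₂,b₁,b₂,c₁,c₂,e₁,e₂ coefficients). D is flagged undefined when S = 0
and also when the variance estimate degenerates — the coefficients c₁ and
c₂ are identically zero for n ≤ 3, so D requires n ≥ 4. Note the sample π
estimator is not exactly invariant under duplicating the whole sequence
set: self-pairs at distance 0 scale it by 2(n−1)/(2n−1); the property tests
assert this closed form.

The haplotype network collapses identical masked sequences into nodes with
population-stratified counts and returns a minimum spanning tree of the
pairwise-difference matrix (Kruskal over edges pre-sorted by weight then
node label, so ties break deterministically and lexicographically).
Alternative network constructions (TCS-style parsimony networks) are noted
as extensions, not implemented.

Trees are classical neighbour joining on raw pairwise differences (optional
Jukes–Cantor correction): minimise Q, tie-break by the lexicographically
smallest leaf labels, negative branch lengths clamped to 0 with the deficit
moved to the sister branch, terminating in the closed-form three-taxon
star. On additive distances this recovers topology and all leaf-to-leaf
path lengths exactly, which the tests check against independent
implementations (scikit-bio NJ) and constructions (dendropy random trees).
Maximum-likelihood inference and bootstrap support are out of scope.

## Problem sizes used in tests and the acceptance script

Simulations are sized for a single CPU: pool arithmetic uses one 200-unit
pool (~50,000 pairs); demultiplexing accuracy uses 24 samples × 10 amplicons
at 250 pairs (~60,000 pairs, clean and barcode-corrupted passes); genotype
recovery uses 6 samples × 2 pools at ~110× depth and 1 % error over 20 seeds
in the test suite (8 in the acceptance script); the allele-frequency
recovery cohort is 200 samples across 8 pools at ~60× depth; oracle
comparisons run 500–1,000 randomised trials. The full suite runs in about
two minutes, the acceptance script in about one.

## Known limitations

- Indel representation follows minimal-edit alignment placement; ambiguous
  events near repeats may split or shift relative to the planted
  representation (substitution calling is unaffected).
- The genotype-likelihood caller ignores mapping uncertainty and assumes
  independent observations; fragment-level reconciliation removes the
  mate-overlap double count but PCR duplicates are not modelled.
- The two-point quality model and uniform error spectrum are idealisations;
  concordance results quantify pipeline logic, not platform error handling.
- Consensus haplotypes ignore phasing: a heterozygous sample contributes
  one majority-allele sequence (or IUPAC codes), matching the assay's
  consensus-FASTA approach rather than true haplotype resolution.
- Barcode capacity per pool is bounded by 6-mer code geometry (64 words at
  distance 4, ~90–100 at distance 3); larger cohorts must span pools.
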