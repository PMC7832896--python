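# Methods

## The inference problem

A species with genetic sex determination but cytologically homomorphic sex
chromosomes leaves a detectable sequence signature: genomic regions unique
to the Y (or W) chromosome exist in one sex only. Single-enzyme RADseq
samples the genome at restriction sites, so a Y-hemizygous (W-specific)
region appears as a RAD locus whose presence/absence vector separates the
sexes perfectly. The direction of the asymmetry identifies heterogamety —
male-specific loci imply XX/XY, female-specific imply ZZ/ZW — and homology
of the genes near those loci to a well-annotated reference genome
identifies the linkage group.

The screen is deliberately a two-stage design:

* **Putative stage (strict absence).** A locus qualifies only if present in
  ≥ `min_carriers` individuals of one sex and in *zero* of the other.
  Requiring literal absence, rather than a frequency difference, keeps the
  screen assumption-free; its error tolerance is delegated entirely to the
  next stage.
* **Confirmation stage (raw-read veto).** Tag calling requires ≥ `min_depth`
  identical reads, so a locus stochastically under-sequenced in one sex is
  absent from that sex's presence vector while its reads still exist. The
  confirmation scan searches the raw demultiplexed reads of the opposite
  sex for each putative marker's allele sequences (both alleles of a
  two-allele locus — either one appearing disqualifies sex linkage) and
  vetoes on any match. Because reads and tags share the restriction-site
  anchor, the comparison is positional (prefix Hamming distance, default 0
  mismatches), not an alignment.

A marker set that survives confirmation with zero markers of the opposite
specificity is what licenses a system call; both-positive and both-zero
outcomes are reported as UNRESOLVED rather than forced.

## Synteny assignment

Confirmed markers from a species with no genome assembly are localised by a
two-step BLAST chain through the transcriptome of a related species to the
annotated genes of a reference genome. The module consumes 12-column BLAST
tabular files (it never invokes BLAST — external database versions would
make results irreproducible): per query, the best hit is the lowest
e-value, ties broken by bitscore descending then subject id; chains failing
`evalue_max` (default 1e-10) at either step are dropped; and chains are
collapsed to unique genes before testing, since the draws of the null model
are genes, not markers.

Under the null that hit genes land on chromosomes in proportion to their
annotated gene counts, the count on a chromosome with K of N annotated
genes out of n unique hits is Hypergeometric(N, K, n). We report the upper
tail P(X ≥ k) — the one-sided "more than expected" question — with expected
count nK/N. The tail is computed in log space from log-factorials
(`math.lgamma` on integer arguments) with a max-shifted exponential sum, so
p-values of order 1e-20 are exact to ~1e-12 relative error; the boundary
cases are handled symbolically (k at or below the support minimum gives
exactly 1.0, k above min(K, n) exactly 0.0). p-values are reported raw,
matching common practice for this single-question design; a
Bonferroni-across-chromosomes flag is available for the significance
column.

## The simulator

`radsexmark.simulate` generates the study conditions the pipeline is
validated under: two sexes with single-digit sample sizes, forward reads of
the form `barcode (6 bp) + SbfI overhang TGCAGG + tag core (140 bp)`, and
four locus classes — autosomal (optionally two alleles one SNP apart under
Hardy-Weinberg proportions, alternate-allele frequency 0.3), sex-limited
(reads only in the heterogametic sex), gametolog pairs (a shared allele in
everyone plus a diverged allele in the heterogametic sex), and optional
planted false positives (fixed depth 2 in the homogametic sex, full depth
in the other — the exact depth-threshold artifact the confirmation stage
exists to catch; these are exempt from dropout so the scenario is
deterministic).

Defaults: Poisson read depth with mean 20 per carried tag, per-base
substitution error 0.001 (Illumina-like), per-individual-per-locus dropout
0.02 (restriction-site polymorphism), gametolog divergence 0.05 — realised
as an exact count round(0.05 × 140) = 7 substitutions so clustering
behaviour is deterministic. Independent tag cores are drawn uniformly over
{A,C,G,T} with a minimum pairwise Hamming distance of 10 by rejection,
which makes locus clustering unambiguous at these scales. Quality strings
are constant 'I' (phred 40); the quality filter is exercised through an
optional corruption switch that injects 15-base phred-2 windows, not
through a full quality-score model.

Only forward reads are simulated: candidate loci and alleles are defined
from forward reads, and assembling reverse reads is outside the package's
scope. Not emulated: PCR duplicates, indels, fragment-length effects,
barcode synthesis errors, batch effects, or any realistic depth
distribution beyond Poisson. Consequently, passing tests demonstrate the
logic of the screen — recovery, accounting, false-positive elimination —
under controlled noise, not performance on real libraries, where depth
overdispersion and repeat content will lower sensitivity. The recovery
tests deliberately avoid depending on the depth distribution's shape.

## Parameters that matter

| parameter | default | stage | why |
|---|---|---|---|
| `min_depth` | 5 reads | tag calling | below it a sequence is noise; RADtools-era convention |
| `max_allele_mismatch` | 3 subst. | clustering | tolerates alleles/errors within a 140-bp tag; > typical error load, < gametolog divergence |
| `min_carriers` | ⌈sex size / 2⌉ | putative screen | guards against dropout-driven singletons |
| `max_mismatches` | 0 | confirmation | exact veto; raising it widens the veto net |
| `allow_barcode_mismatch` | 1 | demux | rescue without misassignment (barcodes ≥ 2 apart) |
| `quality_window` / `threshold` | 15 bp / phred 10 | demux | sliding-window mean filter |
| `evalue_max` | 1e-10 | synteny | both BLAST steps must be confident |
| `alpha` | 0.05 | synteny | significance flag only; p-values reported raw |

None of these are dictated by theory; all are stamped into every output
header so any reported count is auditable against its parameters.

## Numerical and design choices

* Single-linkage Hamming clustering (union-find over the ≤-radius pair
  graph) rather than alignment-based clustering: fixed-length anchored tags
  make Hamming exact and the result testable against brute-force connected
  components.
* The two-or-fewer-alleles locus filter is applied both per locus and per
  individual (the stricter reading); the per-individual half is toggleable.
* Locus ids are assigned after sorting clusters by smallest allele
  sequence, and marker reports are ordered by carrier count descending then
  locus id, so all outputs are byte-stable and diffable under a fixed seed.
* Demultiplexing ambiguity (a read prefix within tolerance of two barcodes)
  drops the read and counts it — never misassigns, never raises.
* The evaluator maps called markers to truth loci by allele sequence (exact
  first, then nearest within 3 mismatches, since tag calling can promote a
  high-depth error read to an allele); an unmatched marker is a hard error.
* Degenerate inputs fail loudly: empty truth tables, single-sex presence
  matrices, missing opposite-sex read files, genes absent from the
  annotation, malformed FASTQ/BLAST rows (with record/line index).

## Scales used in the validation runs

The shipped validation and acceptance runs use scaled-down analogs of a
two-species field study design: 11 males / 4 females with 25 W-specific
loci among 335 total (ZW analog), 9 / 9 with 20 Y-limited among 330 (XY
analog), ~100k reads per run. These sizes exercise every code path while
keeping a full pipeline run in seconds; the package's algorithms are
O(reads) except clustering, which is quadratic in *distinct* tag sequences
and comfortable into the tens of thousands. Real RADseq studies yield
~10⁵ loci; at that scale the clustering stage is the bottleneck and would
benefit from k-mer prefiltering, which is not implemented.

## Known limitations

* Presence/absence logic only: no coverage-dosage test (X vs autosome), no
  genotype likelihoods, no paralog detection beyond the allele-count filter.
* Exact-match confirmation can be defeated by sequencing error in the
  opposite sex's single disconfirming read (mitigated by `max_mismatches`).
* The synteny stage inherits whatever biases the upstream BLAST searches
  carry; it tests enrichment, not orthology.
* Heterogamety calls from small samples can be confounded by sex-biased
  missingness in real libraries; the permutation behaviour (no confirmed
  markers under shuffled labels) is verified on simulated data only.
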