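# Methods

`miridscreen` re-implements the computational core of a draft-insect-genome
decontamination project: screening assembly scaffolds for bacterial
contamination, calling lateral-gene-transfer (LGT) candidate regions, assembly
QC with duplicate-scaffold accounting, pooled-sequencing sliding-window
diversity statistics, and tandem-repeat/telomere copy-number analysis. A
synthetic-data generator with a recorded truth table stands in for the raw
sequencing of such a project, so that every stage has recoverable ground
truth.

## Contamination screen

Each scaffold is notionally fragmented into 1 kbp pieces and searched against
a bacterial reference database; the screen itself consumes the resulting hit
table (12 standard BLAST-tabular columns plus a database tag and a taxon
family label). Hits with bitscore strictly above 50 are recorded. Per
scaffold the screen reports:

- the number of recorded bacterial matches,
- covered bp: the length of the interval union of recorded hits,
- hit width: the distance from the leftmost hit start to the rightmost hit
  end, divided by scaffold length,
- the subject with the most matches (ties broken lexicographically and
  flagged — the tie rule is a determinism choice, the input order carries no
  information).

A scaffold is called contaminant iff its proportional hit width is **>= 0.40**
(inclusive). Hit width, not union coverage, is the classification statistic:
a scaffold whose bacterial evidence spans most of its length is bacterial even
when individual hits are sparse. The per-family summary reports, per taxon
family, the interval-union bp of that family's qualifying hits summed over
scaffolds, and the number of scaffolds affected; one scaffold can contribute
to several families, so the scaffold column may sum to more than the number
of distinct scaffolds. Union rather than raw hit-length sum is used so that
overlapping hits are not double-counted; hits without a family label are
binned as "Others". A preliminary high-identity screen is folded into this
same mechanism rather than implemented as a separate pass.

An optional toy seed-and-extend search (11-mer exact seeds on both strands,
ungapped extension at +1/−2 with an x-drop of 10) exists so that the whole
path from sequence to hit table can be exercised offline at toy scale; it is
not a general aligner and the fabricated hit tables are the primary test
route.

## LGT candidate detection

Fragments with a recorded bacterial hit are screened against a eukaryote
transcript database; a fragment is a candidate piece iff its best bacterial
bitscore is strictly above 75 **and** it has no eukaryote hit. "No eukaryote
hit" is represented as best eukaryote bitscore 0 — a search reports no
zero-score hits, so 0 encodes absence; `euk_max` permits relaxation. Maximal
runs of adjacent candidate pieces on a scaffold fuse into one candidate
(strict adjacency by default; `max_gap_fragments` tolerates missing
fragments). Each candidate is annotated with the nearest gene model wholly
left and right of its span, any overlapping gene, and transcription evidence
(mean expression depth over the span against a threshold, default 1x).

The automatic pipeline never discards a candidate: manual curation against
live databases is inherently an operator step, so the pipeline emits a
curation worksheet and ingests verdicts from a file. Flank class labels come
from GFF3 attributes, keeping the stage offline.

In the end-to-end pipeline, contaminant-classified scaffolds carrying an LGT
candidate *with gene context* (a flanking or overlapping gene model) are
exempted from removal and reported with both flags. The gene-context
requirement is load-bearing: a bare bacterial scaffold also passes the
dual-database piece rule (strong bacterial hit, no eukaryote hit), so an
unconditional exemption would empty the removal list.

## Assembly QC

Scaffold and contig N50 use the sorted-cumulative-half-total definition;
contigs are scaffold segments split at N-runs of >= 10 bp (configurable — a
common splitter default consistent with describing gaps as runs "greater than
10 bp"). Gap stripping deletes N-runs strictly longer than 10 bp and reports
the percent reduction at one decimal place.

Duplicate detection has two modes. Exact mode groups scaffolds identical to
an earlier scaffold or its reverse complement (assemblies are
strand-arbitrary). Near mode proposes candidate pairs by shared canonical
k-mer minimizers (k = 15, window 25) and verifies each pair with banded edit
distance (edlib, band = `max_edits`); a pair is reported iff edits <= 100 and
identity = 1 − edits/len(shorter) >= 0.95 by default. Edits are full
Levenshtein operations (substitutions and indels); the shorter sequence is
the identity denominator so the statistic is symmetric in pair order. Length
filtering (default 10 kbp, used before windowed diversity analyses) and the
flow-cytometry size ratio (sample/standard fluorescence times a 175 Mbp
standard) are plain arithmetic with their printed rounding conventions.

## Pool-seq diversity windows

Input is per-site read counts (classic pileup text or a 9-column counts TSV).
Optional preprocessing: thinning to a target mean coverage
(binomial/hypergeometric without-replacement sampling per site) and indel
masking (every position within +/- 5 bp of an indel-bearing site is excluded
from all accounting; 5 bp is the conventional flank of pooled-analysis indel
masking).

A site is covered iff `min_cov <= coverage <= max_cov` (defaults 4/400) and
unmasked; it is a SNP iff covered and its minor allele count (coverage minus
the major allele's reads) is at least `min_count` (default 2). Per SNP site

    pi_hat = 1 − sum_a C(c_a, 2) / C(M, 2)

over alleles a with read counts c_a at coverage M. Window pi is the sum of
pi_hat over SNP sites divided by covered sites; Watterson's theta is
S / (a1 × covered sites) with a1 = sum_{i=1}^{n−1} 1/i at n = `pool_n`
chromosomes (default 40, the pool size the study's diversity tooling was run
at, although 10 diploid females imply 20 chromosome copies — both are
exposed); Tajima's D uses the classical variance constants at n. D is
reported as NA when S = 0; windows below 0.60 covered fraction are flagged
insufficient and carry no values. Genome-wide pi and D are unweighted means
over sufficient windows (bp-weighting is a defensible alternative; unweighted
matches a per-window average table). With step = window, windows partition
the scaffold prefix and a trailing remainder is flagged partial.

### Known estimator biases (documented, not corrected)

These are classical sample estimators applied to read counts — an
approximation of pool-aware corrected estimators, not a re-derivation:

- Reads resample the pool with replacement, so E[pi_hat] = 2f(1−f) at pool
  frequency f; averaged over a neutral spectrum this shrinks pi by (n−1)/n
  (2.5% at n = 40).
- Sites where the reads happen to sample only one allele are lost from S,
  deflating Watterson's theta and pushing D slightly positive (about +0.2 at
  50x, n = 40, theta = 0.01).
- The `min_count` filter truncates the rare tail of the site-frequency
  spectrum. At 50x a true singleton-frequency allele (f = 1/40) is seen twice
  or more in only ~36% of sites, so with `min_count` = 2 the filter removes a
  large share of rare variants, biasing D strongly positive (about +0.7
  under the same conditions). The filter exists to suppress sequencing
  errors; on error-free simulated reads the recovery analyses therefore run
  with `min_count` = 1, which measures the estimator rather than the filter.
  On real data with errors, `min_count` = 2 is the appropriate default and
  D should be read relative to a matched simulated baseline.

The neutral pool simulator draws S ~ Poisson(theta × a1 × L) segregating
sites, derived counts i with probability proportional to 1/i (the standard
neutral frequency spectrum), read counts Binomial(coverage, i/n), and an
optional symmetric error rate. The simulated mean window pi recovers theta
to within ~3% and mean D is ~+0.2 (the documented biases above), verified in
the acceptance checks at theta = 0.01, n = 40, 50x, 10 x 1 Mbp.

## Repeats and telomeres

Motif counting is non-overlapping and left-to-right over the set of
rotations of the motif and of its reverse complement — deterministic and
matching the "copies in a tandem array" intuition. Copy number per haploid
genome is occurrences in reads divided by sequencing coverage (total read
bp / genome size); copies per chromosome end divides by 2 × the haploid
chromosome number (default 16, i.e. 2n = 32).

The tandem detector reports, for each period p up to 25 bp, maximal runs
with s[x] = s[x−p], at their minimal period only (computed from the KMP
border of the run), subject to >= 3 copies and >= 12 bp by default (the
detector's own thresholds; an alignment-based tandem finder's probabilistic
model is intentionally not reproduced, so degenerate arrays are
underestimated). Telomere candidates are repeat motifs within Hamming
distance 2 of the ancestral insect motif TTAGG (best over rotations and
strands, periods expanded to a common length so a homopolymer can be
compared and excluded), ranked by total genome copies. Repeat presence on
the assembly counts a scaffold iff at least one match covers >= 70% of the
repeat unit (full-motif exact matches trivially qualify; long consensus
repeats are assessed from a hit table).

## Synthetic data: what it emulates, and what it does not

The generator produces: host scaffolds (i.i.d. bases at GC 0.38, an
insect-typical composition), contaminant scaffolds from per-family
first-order Markov pools (distinct k-mer composition per family, so
composition-aware search can learn family calls), LGT inserts placed inside
host scaffolds between planted flanking genes with expression evidence iff
the insert is flagged expressed, near-duplicates with an exact number of
substitutions (optionally reverse-complemented), N-gap runs, tandem arrays,
and neutral pooled pileups. Hit tables are fabricated directly from the
truth (contaminants tiled to their truth fraction at bitscores 80–500, LGT
intervals hit without eukaryote matches, sub-threshold background noise)
because the screen is specified on hit tables — tests are therefore
aligner-independent. All generators are byte-deterministic under a seed.

What passing these tests shows: the screening rules, fusion logic,
estimators and accounting are implemented exactly, and planted truth is
recovered perfectly in the noise regimes the generator produces. What it
does not show: performance on real mixed assemblies (misassembled chimeric
scaffolds, diverged or partial bacterial homology, repeat-driven spurious
hits), real pooled reads (mapping artefacts, non-uniform coverage,
correlated errors), or alignment-sensitive tandem detection. The study's
own assembly-wide tables (overall assembly statistics, orthologue
completeness scores, per-scaffold diversity values of the real pool) depend
on its deposited reads and original toolchain and are out of desk-reach;
the synthetic recovery checks substitute for them.

For copy-number recovery experiments the background is scrubbed of
incidental motif matches (`scrub_motif`): a random background carries about
one chance match to a 5 bp motif family per 100 bp, which would otherwise
swamp a planted count of ~100; scrubbing makes the planted arrays the exact
truth. Problem sizes in the shipped checks (assemblies of tens of scaffolds
at 2–40 kbp, pools of 1 Mbp x 10 seeds, read sets at 10x over ~400 kbp) are
the package's own choice of smallest sizes at which the statistical
tolerances are meaningful.

## Numerical and degenerate-input conventions

All internal coordinates are 0-based half-open; BLAST tabular, GFF3 and
classic pileup are converted at the IO boundary. Ambiguity codes collapse to
N (screens treat them as unmatchable) rather than erroring. Reversed hit
intervals are normalized with a flag. A scaffold with no qualifying hits has
all-zero metrics and is clean. Windows with no covered sites, empty
assemblies, zero-theta simulations, inserts longer than their scaffold and
coverage targets above the current coverage raise errors naming the object.
Report floats are written at full (shortest round-tripping) precision so that
read-after-write is the identity.
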