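# Methods

## Coding-sequence extraction and translation

Genes are reconstructed from GTF `CDS` features grouped by
`gene_id`/`transcript_id`; coordinates are treated 1-based inclusive
end-to-end, so no interval arithmetic ever changes convention. For
multi-isoform genes one representative must be chosen (the annotation query
is one protein per gene); we take the transcript with the longest total CDS
length, which maximises alignable sequence, with ties broken by transcript
id for determinism. Minus-strand CDS are assembled in genomic order and
reverse-complemented as a whole, which is equivalent to per-exon
reverse-complementation in coding order. The phase column of the first
coding segment is honoured: with phase 1 or 2 the leading out-of-frame
bases are trimmed, so fragmented gene models still translate in frame.

Translation uses the standard genetic code and terminates at the first stop
codon rather than erroring on internal stops: draft genomes contain broken
and pseudogene-like models, and the pipeline must annotate around them, not
halt on them. Codons containing `N` translate to `X`; a trailing partial
codon is dropped with a warning; sequences shorter than one codon are an
error.

## Local alignment and homology search

The search stage is a deterministic, exact replacement for a heuristic
protein search at desk scale: every query is aligned against every
reference record with Smith–Waterman under affine gaps (Gotoh), BLOSUM62,
and BLAST-convention gap costs (a gap of length L costs
`gap_open + L·gap_extend`; defaults 11/1, configurable). The alignment
engine is Bio.Align.PairwiseAligner; the test suite holds an independent
plain-Python dynamic-programming oracle and requires exact score equality
on random pairs, so the engine is cross-checked, never trusted blindly.

Metrics come from the traceback of one optimal alignment: percent identity
and percent similarity are fractions of all alignment columns (gap columns
included, the BLAST convention), where a "similar" column is identical or
has a strictly positive substitution score; percent query alignment —
the quantity used to rank best hits — is the aligned query span over the
query length. Residues outside the matrix alphabet score −1 against
everything (logged once). Alignments with non-positive optimal score
return no hit; per-query hit order is score-descending with lexicographic
subject-id tie-break, so outputs are reproducible byte for byte.

Precomputed tabular hits (the 12-column `qseqid…bitscore` dialect) can be
imported instead; that dialect carries no positives column, so similarity
falls back to identity and the hit is flagged, and query coverage is
recomputed from the reported query span and the query length.

## Cleaning and GO transfer

Cleaning applies, in order: (1) any gene whose single top-scoring hit is
not plant-related is removed entirely — if the strongest signal is
bacterial or fungal, the gene's weaker plant hits are distrusted as well;
(2) remaining non-plant hits are dropped, because GO transfer draws on
plant-related matches only; (3) hits shorter than 20 aligned amino acids or
below 35% similarity are dropped. The filter is idempotent. The taxon
summary (which fraction of genes have plant / bacterial / fungal top hits)
is computed *before* cleaning, otherwise the non-plant fraction it reports
would be zero by construction.

Per gene and reference species, the best surviving hit by query coverage
(ties: score, then subject id) contributes its subject's GO set; the gene's
annotation is the union over species, which rewards terms supported by
multiple reference proteomes without double-counting (set semantics). The
gene descriptor comes from the overall best hit. eggNOG-mapper annotation
files are merged as a second evidence source (union of GO sets, per-term
source tracking); when reference metadata is available, eggNOG rows whose
seed ortholog maps to a non-plant record are skipped, mirroring the
plant-only transfer rule.

## DEG criterion and fingerprints

A fixed fold-change cut-off treats every experiment alike regardless of its
noise level. Instead the effect-size threshold adapts per contrast:
`LFcut = quantile(|lfc_raw|, 0.75)`, the upper quartile of the absolute
*non-shrunk* fold changes of all genes in the table (not only DEGs),
computed with linear-interpolation order statistics
(`h = (n−1)·0.75 + 1`) — stated explicitly because quantile conventions
differ between environments. Missing values are dropped first; fewer than
four finite values is an error. A gene is a DEG when `padj ≤ α` (default
0.05) **and** `|lfc_shrunk| ≥ LFcut`; genes with missing `padj`
(independent-filtering artifacts upstream) are never DEGs. Using the raw
fold changes for the threshold and the shrunk ones for the test keeps the
threshold scale-honest while judging genes on their moderated effects.

Core sets are plain intersections of the low- and high-concentration DEG
sets; overlap percentages are reported relative to each parent, rounded
half-up to integers (running-text precision), while concentration
recoveries round to one decimal (table precision). The positive quadrant
count ratio is `#{aᵢ·bᵢ > 0} / #{aᵢ·bᵢ ≠ 0}`: zero products carry no
directional information and are excluded from the denominator; an all-zero
product vector yields NaN rather than a fabricated ratio. Pearson
correlations use the t transform with n−2 degrees of freedom and refuse
zero-variance input. Marker extraction takes the top k (default 50) core
genes by control mean expression, ties broken by gene id.

## Overrepresentation analysis

The ORA universe defaults to the genes detected in the DE table, not the
whole genome — testing against undetectable genes inflates enrichment.
Within the universe only annotated genes enter the 2×2 margins (`n`
annotated set genes of `N` annotated universe genes; dropped counts are
reported). P-values are the upper hypergeometric tail `P(X ≥ k)`
(scipy's survival function; verified against full subset enumeration in
the tests), one-sided because only overrepresentation is biologically
asked. Terms annotating fewer than 10 or more than 500 universe genes are
skipped by default (too small to be stable, too broad to be informative;
both configurable). BH adjustment runs across the tested terms only.
Ancestor propagation over `is_a`/`part_of` (not `regulates`) from an OBO
graph is available but off by default: transferred annotations of unknown
propagation status should not be silently double-propagated.

Note that BH step-up is not idempotent — re-adjusting an adjusted vector
multiplies by `n/i` again — so adjusted p-values are computed exactly once
per result table.

## Synthetic data: what it emulates and what it does not

The generators produce, from `(parameters, seed)` alone and byte-
deterministically, a coupled study: a toy genome (multi-exon CDS on both
strands, codon-multiple lengths, random introns/spacers), a reference
database (per gene one homolog mutated by point substitutions to a target
identity, default 90%; species labels allocated by largest remainder so a
0.5% bacterial fraction over 200 genes yields exactly one bacterial
homolog; 1–3 planted GO terms per record from a 25-term pool; 20%
non-homologous, non-plant decoys), and DE tables (null genes: fold changes
`N(0, 0.3)` whose two-sided normal test gives exactly uniform p-values, the
correct null for calibration; planted DEGs: |lfc| ≥ 2 with high-
concentration effects amplified 1.5×; shrinkage emulated by
`raw·raw²/(raw²+4σ²)`; proteome direction agreeing with the transcript
with probability 0.8 at half magnitude; padj by BH). One GO term is planted
on the DE genes plus a margin of background genes so the ORA stage has a
recoverable signal with a realistic background term-size distribution.

What passing these tests shows: the mechanics — extraction, alignment,
cleaning, transfer, thresholding, counting — are correct under known truth.
What they do not show: realized performance on real data, where homology is
mosaic (domain-level, with indels and paralogy), annotations are biased and
incomplete, fold-change noise is heteroskedastic and count-driven, and
p-values come from negative-binomial models rather than normal ones. The
substitution-only mutation model in particular makes identity exactly
controllable but is kinder to the aligner than real divergence; an indel
option exists for stress tests.

Problem sizes in the shipped tests and acceptance script (50–1000 genes,
200-gene end-to-end study, 20 calibration replicates) were chosen as the
smallest scales at which the statistical checks are stable.

## Pipeline and determinism

The `pipeline` command validates a YAML config (unknown keys rejected; all
thresholds surfaced as named keys with the study defaults), runs the six
stages — extract, search, annotate, fingerprint (plus compare with ≥ 2
compounds), ora, report — and writes a manifest with package version,
parameters, and SHA-256 checksums of every input and output. The manifest
contains no timestamps, so a rerun with unchanged inputs is byte-identical
throughout, manifest included. Stage failures abort with the stage name and
the offending input; exit codes distinguish configuration errors (2) from
data errors (3).
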