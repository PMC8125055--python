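# Methods

This note documents the models, conventions and defaults behind
`napregulon`, the choices that were genuinely open, and what the
synthetic-data tests do and do not demonstrate about real data.

## Coordinates and formats

All internal coordinates are 0-based half-open on named contigs. GFF3
(1-based inclusive) is converted on read (`start−1, end`) and
reconverted on write; BED passes through unchanged; a 1-bp GFF feature
maps to a length-1 interval. Sequences are uppercased on read and any
symbol outside `A C G T N` is rejected rather than silently remapped,
because the AT statistics must be well defined. Differential-expression
input is a plain TSV contract (`gene_id`, `log2fc`, `adj_p`) with an
optional column mapping for other tools' export dialects; fitting the DE
model itself (e.g. voom/limma upstream) is out of scope — the pipeline
consumes its output table.

## Regulon model

A gene belongs to the regulon when |log₂FC| (deletion mutant vs wild
type) strictly exceeds a threshold, default log₂(3) ≈ 1.585, i.e. at
least a 3-fold change in either direction. The inequality is strict, so a
gene at exactly the threshold is excluded. Direction is encoded once,
from the protein's perspective: up in the mutant ⇒ `repressed_by_nap`,
down ⇒ `activated_by_nap`; summaries render the same count both ways
("percent activated by the NAP" equals "percent with decreased
transcription in the mutant") to avoid sign errors between phrasings.

An adjusted-p filter (≤ 0.05) is applied by default alongside the
fold-change rule. A fold-change-only rule is common in this literature,
so the filter can be disabled (`p_threshold=None` / `--no-p-filter`);
the default is the conservative choice since moderated adjusted p-values
are what DE platforms report.

Reported percentages round half away from zero (71.83 → 72, 45.97 → 46),
matching how such tables are conventionally printed.

## Direct targets and promoter windows

The putative promoter of a gene is the strand-aware window covering
`upstream` bp (default 150) adjacent to the start codon: `[start−150,
start)` for a `+` gene, `[end, end+150)` for a `−` gene (the start codon
of a minus-strand gene is at its high-coordinate end), clipped at contig
edges. A regulated gene is *direct* when any binding-site interval
overlaps this window by at least 1 bp — a binding site is an interval,
so any-overlap is the natural permissive reading; windows are half-open,
so a peak ending exactly at the window start does not count. Direct
assignment never changes regulon membership, only the mode and the list
of supporting peak ids.

## Binding-site architecture and spacing

Each site is reduced to a reference point, by default the interval
midpoint `floor((start+end)/2)` (start/end selectable). A site whose
point falls inside a gene body is intragenic (ties between overlapping
genes go to the smallest start); otherwise the flanking genes L (greatest
end ≤ point) and R (smallest start > point) determine the category:
same strands ⇒ tandem, `(+,−)` ⇒ convergent (3′ ends facing the site),
`(−,+)` ⇒ divergent (5′ ends facing the site); a missing flank at a
contig end ⇒ terminal. An `overlap` containment mode calls a site
intragenic when its whole interval touches a gene, for comparability
with annotation tools that count overlaps.

Nearest-neighbor spacing is point-to-point: on each contig, every site
contributes its distance to the closest other site, pooled across
contigs. Chromosomes are treated as linear by default; a circular flag
adds the wraparound neighbor for the first/last sites. Quartiles default
to Tukey hinges — the median splits the sorted sample into halves that
both include the median when n is odd, and Q1/Q3 are the medians of the
halves ("the middle number between the smallest number and the median") —
with linear interpolation between order statistics as the alternative
estimator, since the two differ on small samples.

The bridged-gene estimate converts a spacing quantile into genes:
`floor(Q / avg_gene_len)` with `avg_gene_len = 946` bp by default (the
average mycobacterial gene); applied to Q1 and Q3 it bounds how many
genes a bridging protein could trap between two typical neighboring
sites.

## AT landscape

Windows of `window` bp (default 500) tile each contig from offset 0 at a
`step` (default 500); a trailing fragment shorter than the window is
dropped so all windows are equal width. `at_fraction = (#A + #T) /
(window − #N)`: N bases are excluded from the denominator so masked
regions do not bias the statistic, and an all-N window has an undefined
(NaN) fraction excluded from summaries. AT-rich regions are maximal runs
of contiguous windows at or above a threshold; no numeric cutoff is
standard for "AT-rich", so the default is genome mean + 2 SD of window
AT fractions, recorded in the run manifest.

## Promoter composition

Promoters are fixed-length upstream windows, strand-corrected (reverse
complement for `−` genes) so the last position is always adjacent to the
start codon; genes whose window is clipped by a contig edge are dropped
with a warning. The background is a seeded uniform sample without
replacement of n = 50 promoters, excluding the regulated set by default
(a contaminated null weakens the contrast; toggleable). The comparison
statistic is the difference of per-promoter AT fractions; the default
test is Welch's two-sided t on those fractions, with a pooled-variance t
and a seeded label-permutation test (≥ 10,000 shuffles, add-one p
estimate `(1+k)/(1+N)`) as alternatives. Positional profiles are the
per-position AT frequency across members; their mean equals the set's
mean AT fraction. Promoter length defaults to 150 bp for consistency
with the direct-target window and is configurable.

## Surface roughness

`Ra = (1/n) Σ|z_i − mean(z)|` over one line's height samples — the
standard arithmetic-mean-deviation roughness parameter, using the line
mean as reference. An optional least-squares detrend handles tilted
scans; it is off by default since plain Ra is the named convention. A
cell's Ra is the unweighted mean over its (3–4) lines, weights being
unstated conventions when line counts differ. Strains are compared on
per-cell Ra with a two-sided pooled-SD t-test (df = n₁+n₂−2); the
degenerate all-equal case returns t = 0, p = 1 by convention.

For zero-mean Gaussian noise of scale σ, E[Ra] = σ·√(2/π); the test
suite verifies convergence to this closed form within 2% at 10⁴ samples,
and the generator inverts it (σ = target Ra / √(2/π)) to plant per-cell
Ra targets.

At the default group parameters (Ra 3.33 ± 1.81 vs 4.68 ± 1.25 nm, 50
cells per group) the exact power of the pooled t at the stringent
α = 0.0005 significance bar is ≈ 0.77 (noncentral-t closed form, which
the simulation-based test reproduces): a single experiment at these
parameters will usually — but not always — clear that bar.

## Synthetic data: what it emulates, and what it does not

The generators produce desk-scale inputs with the statistical structure
the analysis assumes — defaults: one 200-kb contig at 67% GC with eight
non-overlapping 3-kb islands at 65% AT; 200 non-overlapping genes of
mean length 946 bp (Gaussian, SD 250, ≥ 200 bp) with ≥ 1-bp intergenic
gaps and Bernoulli(½) strands; 30 direct + 10 indirect regulated genes
with |log₂FC| ~ U(2.2, 5) (90% positive, emulating a predominantly
repressive silencer) over a noise floor truncated at |log₂FC| ≤ 1.2; one
peak planted wholly inside each direct target's promoter window;
150 background peaks preferentially placed in intergenic gaps (80%) and
biased toward island-overlapping gaps (70% of those), never touching a
regulated gene's promoter window; and Gaussian roughness profiles
(3–4 lines × 256 samples per cell, 50 cells per group). Regulated genes
are chosen so their promoter windows are pairwise disjoint, which makes
the planted direct/indirect labels unambiguous. Every generator is a
pure function of its parameters and seed; a master seed derives fixed
per-component child seeds (numpy `SeedSequence` spawn keys), so
regenerating one file never shifts the others, and `truth.json` records
everything needed to score every stage.

Deliberately not emulated: read-level data (no FASTQ, no fragment-length
model), operon structure, elevated AT content in the promoters of
regulated genes (the composition test is instead validated on promoter
sets constructed with an exact planted AT contrast), correlated
gene/island placement, and hypoxia kinetics. Consequently, passing the
end-to-end tests shows the integration logic is correct under the
assumed structure — exact recovery of planted targets, correct
architecture fractions, calibrated tests — not that any particular
biological effect size will be observed in real data.

## Numerical and degenerate-input conventions

Empty regulon ⇒ all-zero summary. Fewer than 2 peaks on every contig ⇒
spacing error. All-clipped promoter windows ⇒ error (partial clipping ⇒
warning + drop). Identical groups ⇒ t = 0, p = 1. Text outputs are
written with round-trip float formatting (`%.17g` where exact identity
matters), and DE tables are parsed with round-trip float precision so
write-then-read is the identity. Quartile/percentage tie-breaks are as
above. All randomness flows through numpy Generators seeded explicitly;
reruns with the same config are byte-identical (the run manifest echoes
every parameter and seed).

## Problem sizes

The default synthetic scale (200-kb contig, 200 genes, 180 peaks, 100
cells) runs the full pipeline in a few seconds; the heaviest test (100
seeded roughness replicates for the power check) runs in a few seconds
as well. These sizes were chosen as the smallest at which the binomial
tolerances used in the tests are comfortably met.
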