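# Methods

## The measurement

SAGE quantifies a transcriptome as a multinomial sample of short tags: each
mRNA molecule contributes (ideally) one 10-nt tag read immediately 3′ of the
3′-most anchoring-enzyme recognition site (NlaIII, site `CATG`, for the
libraries this package targets). A library is then a tag → count table, and
a gene panel annotated with virtual tags can be matched against it without
any sequencing data. The quantity of interest is the panel's **cumulative
tags-per-million**

    Sum = Σ_{t ∈ panel tags} tpm[t],      tpm[t] = count[t] / N_reliable × 10⁶,

whose /10⁶ fraction is the panel's share of the library's transcriptome.
`N_reliable` is the library total after removing the noninformative (A)₁₀
tag, which arises from poly-A tails rather than any transcript. Derived
statistics per library: Average = Sum / 173 (the full panel size, undetected
genes included — this is what makes the Average column of a summary table
algebraically consistent with its Sum column), Max and the gene carrying it,
and dominance = Max / Sum.

## Tag annotation conventions

- The tag is the 10 nt strictly 3′ of the recognition site, excluding the
  site itself.
- Sequences are used in mRNA sense orientation only; SAGE tags derive from
  the 3′ end of the sense transcript, so no reverse-complement scan is done.
- All site occurrences are found by scanning every offset (overlaps
  included); `N` bases never match the site, and a candidate tag containing
  `N` is rejected at that site.
- When the 3′-most site has fewer than 10 clean downstream nucleotides, the
  next site upstream is used and the extraction is flagged
  (`from_fallback_site`). This is a deterministic automation of the manual
  "reliable 3′ tag" replacement that such transcripts otherwise need.
- A transcript with no site at all cannot be tag-annotated
  (`NoSiteError`) and drops out of the panel — the documented fate of one
  candidate gene, which reduced the annotatable panel from 174 to 173.
- Poly-A tails are not trimmed before extraction; an extracted (A)₁₀ tag is
  flagged noninformative instead, and `annotate_panel` excludes such genes
  from the catalogue (a record carrying the poly-A tag could never be
  matched meaningfully).

The packaged panel (`sageprev/data/imprinted_panel_nlaiii.tsv`) carries 173
genes — 53 established imprinted, 120 high-confidence candidates — each with
its NlaIII tag, cytoband, expressed allele, and mapping flags
(multi-mapping, repetitive, replaced-unreliable). No two panel genes share a
tag; shared tags are nonetheless supported: every gene carrying the tag is
credited in the expression matrix (with a warning), while cumulative sums
count each distinct tag once so a shared tag never inflates the
transcriptome share.

## Catalogue cleaning and normalization

Cleaning removes the (A)₁₀ tag exactly (nine A's plus one other base is an
ordinary tag) and records the removed count. The clone-level "clean-up" some
published libraries received (excluding clones with ≤ 4 tags) is not
reproducible from tag tables — clones are gone by then — so the package
offers a per-tag minimum-count filter as the closest observable proxy:
`min_count=5` emulates that clean-up at tag level, and the default
`min_count=1` applies no count filter. tpm values are carried at full float
precision; formatted outputs round to 2 decimals.

Duplicate library entries are dropped by two rules, in order: a supplied
list of known-equivalent accession pairs (the first-listed member is kept;
the direction is a determinism choice, not recorded in the source data), and
exact content identity of the counts map (first in file order kept).
Each library is normalized independently; libraries are never merged.

Library selection keeps a catalogue iff it is genetically unaltered, its
reliable (post-cleaning) total is ≥ 20,000 tags (inclusive), and its dataset
is complete. The first two judgements the pipeline can make; "unaltered" and
"complete" are metadata flags the caller supplies, because they are
sample-curation judgements. Exclusions report the first failing criterion in
the fixed order i, ii, iii. Whether the 20,000-tag threshold should see the
pre- or post-cleaning total is ambiguous; the reliable total is used, which
is the conservative reading.

## Prevalence statistics

- Cohort means of percent-of-transcriptome are unweighted across libraries
  (each library counts equally regardless of depth); tag-weighted means are
  a defensible alternative but are not what a per-catalogue average reports.
- Decile rankings take ceil(fraction × n) libraries from each end, sorted by
  cumulative tpm with ties broken by accession.
- A gene's detection is "minimum level" when its raw count is 1 in every
  library where it appears — the smallest nonzero signal a library can
  report, regardless of depth.
- The argmax gene of a library breaks ties to the lexicographically smallest
  symbol.

## Clustering

The metric is d = 1 − Pearson r, range [0, 2]. A zero-variance profile has
no defined correlation; its distance to everything is set to 1 (the
uncorrelated convention) with a warning. Items clustered are libraries
(rows of the libraries × genes matrix, i.e. the transposed genes-as-rows
layout the profiles are usually stored in).

K-means is fully deterministic: the first seed is the profile farthest from
the grand-mean profile, each subsequent seed maximizes its average distance
to the seeds already chosen; assignment ties break to the lowest cluster
index; centres are arithmetic mean profiles (the standard reading — the
correlation-distance Fréchet mean has no closed form); a cluster emptied
during iteration keeps its previous centre. The `seed` field exists only
for optional jitter experiments and does not influence the default path.
The automatic k rule returns the smallest k ∈ 1..k_max whose partition
contains a singleton cluster, falling back to k_max with a warning. The
within-cluster-distance objective is monitored in tests as non-increasing
across iterations; with a mean centroid under correlation distance this is
an empirical property, not a theorem, which is one reason the exhaustive
2-partition oracle is also checked.

Hierarchical clustering is classic UPGMA: merge the cluster pair with
minimal mean pairwise leaf distance, recording that mean as the merge
height (heights are monotone for average linkage). Ties break to the pair
with the lowest original row indices. Between-cluster averages are derived
from exact sums of leaf-pair distances, so they equal the direct
recomputation a brute-force oracle performs. Newick export places each leaf
at depth height/2 below its merge (the ultrametric convention), so
patristic distances in the exported tree equal cophenetic distances; this
is the concrete reading of "branch lengths from merge heights".

## The synthetic cohort generator

The generator emulates what the pipeline sees in real tag catalogues:

| parameter | default | meaning |
|---|---|---|
| `library_size_range` | 20,000–400,000 | uniform library depth (tags), the observed span of qualifying libraries |
| `background_tag_pool` | 5,000 | distinct background tags per cohort |
| `abundance_model`, `abundance_shape` | zipf, 1.1 | heavy-tailed background abundances; lognormal available |
| `panel_fraction` | 0.01 | target panel share of informative tags, scalar or per-cohort map (observed cohorts span ≈ 0.0008–0.045) |
| `dirichlet_alpha` | 1.0 | panel dominance: small values give one dominant gene (≈ 0.9 dominance), large values a balanced (≈ 0.09) profile |
| `polyA_fraction` | 0.0 | (A)₁₀ contamination rate |
| `duplicate_rate` | 0.0 | fraction of libraries duplicated verbatim under new accessions |
| `n_altered`, `n_undersized`, `n_incomplete` | 0 | libraries planted to violate each selection criterion |

Per library: depth ~ Uniform(range); (A)₁₀ count ~ Binomial(depth, polyA);
panel count ~ Binomial(informative, target fraction), split over genes by a
Dirichlet-multinomial; the rest is a multinomial draw from the background
distribution. Background tags are random distinct 10-mers excluding the
panel tags and (A)₁₀. Everything derives from one `numpy` Generator seeded
by `seed`, so cohorts are byte-reproducible.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real data: sequencing errors in tags, ditag and
concatemer artifacts, tag-to-gene ambiguity against a full transcriptome,
GC or position biases, and biologically structured covariation between
panel genes across libraries (cohort labels are assigned independently of
expression). Parameter-recovery tests show the pipeline's arithmetic is
faithful, not that the biological estimates are unbiased.

## Problem sizes and numerical choices

The test suite and the acceptance script run on synthetic cohorts of 6–50
libraries at depths of 2×10⁴–2×10⁵ tags and clustering instances of 6–20
profiles — sizes at which the brute-force oracles (exhaustive site scans,
all 2-partitions at n = 6, step-by-step average-linkage recomputation at
n = 8) are exact and fast, while binomial sampling error at the smallest
depth (σ ≈ 0.0007 on a fraction of 0.01) still separates signal from noise.
Monte-Carlo assertions use ≥ 5σ bounds on seeded draws. tpm conservation is
asserted at 10⁻⁶ relative tolerance; oracle height comparisons at 10⁻¹⁰
absolute (exact-sum bookkeeping vs. direct means differ only by float
associativity).

## Known limitations

- The clone-level clean-up is only approximated (see above); published
  per-library reliable totals that depended on it cannot be recomputed
  exactly from tag tables.
- One tag per gene: transcript isoforms with different 3′ ends are not
  resolved; the panel fixture carries the single tag its curation chose.
- The EPCLUST software this clustering procedure mirrors did not document
  its exact seeding or correlation variant; the deterministic rules above
  are this package's declared interpretation, and cluster counts on real
  cohorts need not match those obtained with the original tool.
- LongSAGE (17-nt, MmeI) formats are out of scope.
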