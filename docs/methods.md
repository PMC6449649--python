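# Methods

## Site model and coordinate conventions

A dif/pdif site is modelled as a fixed-length 28-bp locus with an 11-bp
XerC-binding arm, a 6-bp central region and an 11-bp XerD-binding arm
(positions 1–11, 12–17, 18–28 in site-intrinsic orientation). All in-memory
coordinates are 1-based inclusive on the forward strand of the deposited
sequence, matching the coordinate style used in the primary literature for
these elements; BED export converts to 0-based half-open. Features crossing
the origin of a circular replicon keep `end = start + length − 1` with
positions beyond the replicon length read modulo the length; GFF3 export
splits such features into two segments sharing one ID (the standard
discontinuous-feature convention).

Orientation is reported relative to the forward strand: **CD** means the
XerC arm comes first, **DC** the reverse. Arm decomposition is always
reported in site-intrinsic orientation (DC hits are reverse-complemented
first), so downstream profile positions are comparable across strands.

## Scanning

Detection is an exhaustive sliding-window scan: each forward-strand 28-mer
is scored by ungapped Hamming identity (equal non-N positions / 28) against
four motifs — the CD reference, the DC reference, and their reverse
complements (which present the opposite arm order). The best-scoring motif
gives the hit's identity, orientation and matched reference; ties prefer CD
before DC, deterministically. For a fixed-length, gapless site model this
is exactly equivalent to, but more reproducible than, a local-alignment
search; the working threshold of 0.75 is the lower end of the 75–80%
identity band conventionally used for these sites. An N never counts as a
match, which keeps draft contigs from inflating hit counts. Overlapping
hits are resolved by keeping the highest identity (ties: leftmost, then CD
first): one physical locus yields one call. Circular replicons are scanned
across the origin by default.

Chromosomal classification: among a chromosome's detected sites, the single
site most similar to a dif1 reference (default: the Proteobacteria-consensus
chromosomal dif; ties broken by lowest start) is the main dif1 when it
reaches a dif1-minimum identity of 0.90; the rest are "additional" sites.
The 0.90 floor is far above what a plasmid-type site can reach against dif1
given the packaged references (≤ ~0.89 at the maximum modelled divergence),
and a perfect or one-off dif1 copy always clears it.

## Module calling

Modules are called between **consecutive** site pairs only (all-pairs
calling would double-count nested spans) and measured **inclusive of both
flanking sites** — the convention is anchored by the published chromosomal
tellurium-resistance module copy, whose printed end-point coordinates
(2363397–2364617) equal its printed length (1221 bp) only under the
inclusive convention. Defaults: maximum span 20 kb (the largest published
module is ~3 kb; the cap leaves headroom for multi-gene cargo), minimum
cargo ORF 150 bp (the smallest published cargo orf is 198 bp), ORF required.
ORFs are found on all six frames with starts {ATG, GTG, TTG} and stops
{TAA, TAG, TGA}, longest-per-stop, circular-aware. Flanking-site
orientation is deliberately unconstrained — published modules show mixed
arrangements — and is recorded per module.

Cargo labelling aligns each catalog entry into the module sequence (infix
alignment, both orientations, via edlib's edit-distance alignment; identity
= matched columns / alignment columns) and joins the names of entries at
≥ 0.90 identity in coordinate order, suffixed `_dif`. Labels are therefore
compositional (`sulP-uspA_dif`, `chrA-chrB_dif`); they are not forced to
match historical module names.

## Mobility criterion

Two occurrences of a module support mobility when (i) their module
sequences align at ≥ 0.98 global identity (orientation-normalised), (ii)
their contexts differ — the best pairing of 500-bp flanks (forward and
swapped/reverse-complement pairings, covering inverted insertions) aligns
below 0.80 identity — and (iii) they lie on different replicons. Flanks
shorter than 100 bp on both sides make a pair indeterminate rather than
supporting. Species difference is recorded but not required by default:
species labels are frequently missing on contigs, and requiring them would
silently suppress true calls; a strict mode enforces the difference.
Occurrences are grouped into families by single linkage at ≥ 0.95 module
identity before assessment, reflecting how 96–99%-identical variants are
treated as one element in practice; note this straddles the published
borderline case of two organic-peroxide module variants at 96%.

## Clustering and profiles

Site clustering is a single-linkage transitive closure of the pairwise
identity relation at 0.95 (at 28 bp, one mismatch links at 27/28 ≈ 0.964;
two mismatches do not, 26/28 ≈ 0.929), emulating the neighbour-based
behaviour of classic clustering tools; coverage parameters are moot for
fixed-length sequences. DC sites are orientation-normalised first so a
site and its reverse-complement occurrence co-cluster; whether to cluster
orientations together was an open choice, resolved in favour of "together"
since the sites are the same physical element. Clusters are numbered by
decreasing size with deterministic tie-breaks, and cluster-sorted FASTA
output keeps members of a cluster adjacent.

Profiles count bases per position (sites contributing N at a position are
excluded from that position's denominator); information content is
`2 − H(p)` bits with `0·log 0 = 0`; no small-sample correction is applied
by default (group sizes of 20–115 make the (K−1)/(2n ln 2) bias term
minor), but the standard correction is available behind a flag. Group
comparison uses base-2 Jensen–Shannon divergence per position (bounded
[0, 1], symmetric) with means over the three site regions, and the
conservation ranking checks the canonical ordering XerD arm ≥ XerC arm ≥
central region. Logo rendering is an optional matplotlib output; the
tested surface is the numeric profile.

## Summaries

The burden table uses the categories {0, 1–4, 5–8, >8} sites per replicon
with percentages rounded half-up to one decimal (dot-decimal output, where
the source tables print comma decimals). Note that four independently
rounded one-decimal percentages can sum to 100 ± 0.2. The multi-site
report lists replicons with strictly more than a cutoff (default 10) of
sites. Size histograms default to bin edges {0, 6, 10, 20, 30, 50, 100,
200, 400} kb, chosen from the observed "<6 kb" and "6–30 kb" breakpoints;
position maps count site-dense clusters as maximal runs with neighbour gaps
≤ 5 kb (circular-aware) and report the fraction of sites inside
user-supplied backbone intervals (backbones are annotations, not inferred).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Burden**: per-replicon site-count categories drawn as 40% zero, 43%
  one-to-four, 10% five-to-eight, 7% more than eight (matching the
  published survey totals), with counts uniform within a category (9–16
  for the top one).
- **Replicons**: circular by default, log-uniform lengths 2–400 kb,
  i.i.d. background at GC 0.40. Replicons shorter than 6 kb never carry
  sites, mirroring the empirical absence of sites from very small plasmids.
- **Sites**: planted as the CD or DC reference mutated at exactly k
  positions (k uniform on 0–3 by default), so realized identity is
  (28 − k)/28 exactly.
- **Modules**: seven templates at the published spans (3011, 1221, 2549,
  1063, 2159, 2739, 768 bp) with synthetic cargo ORFs at the published
  lengths inside random spacers; each **transfer event** places one
  template on two distinct replicons, the second copy with ~0.5%
  interior substitutions and a fresh random context; additional
  single-copy modules (default 2) exercise the mobility false-positive
  side.

Two placement rules make ground-truth recovery exact rather than
approximate. First, planted features keep a minimum mutual distance of
21 kb (just above the module span cap): in i.i.d. sequence, any inter-site
span under 20 kb would almost surely contain a chance ≥150-bp ORF and
become a spurious module call, which is a property of random backgrounds,
not of real backbones. Second, backgrounds are **scrubbed** of chance
dif-like windows (> 19/28 matches to any reference arrangement) before
planting — at megabase dataset volumes the expected number of chance
≥ 21/28 windows is of order one, and a generator that promises complete
truth tables must not leave unrecorded sites in its own background. The
cost of these rules is that site-dense small plasmids (e.g. 11 sites in
22 kb) and repeat-rich real backbones are not emulated; passing recovery
tests therefore demonstrate correctness of the detection logic under the
stated model, not robustness to IS elements, repeats or compositional
heterogeneity of real plasmids.

Everything is deterministic given the spec's seed (byte-identical outputs).

## Problem sizes and numerical choices

Recovery tests and the acceptance script use 50-replicon datasets
(~5 Mb total sequence, a few seconds end to end) and 200-site clustering
oracles over five seeds; the category-proportion check uses 1,000 small
replicons. Pairwise identities are computed from edlib's extended CIGAR as
matched columns over alignment columns; global identities take the better
of forward and reverse-complement comparisons. Ties everywhere are broken
deterministically (identity, then leftmost coordinate, then CD before DC),
and empty inputs return empty results except where a value is meaningless
(profiles of zero sites raise).

## Known limitations

- Fixed-length ungapped scanning cannot report sites with indels relative
  to the reference pair; the published screening practice has the same
  blind spot.
- The dif1-vs-additional chromosomal rule is a reasoned stand-in (the
  original discrimination procedure is unpublished); the 0.90 dif1 floor is
  calibrated to the packaged synthetic references.
- Catalog labelling is nucleotide-level only; protein-level homology and
  domain annotation are out of scope.
- No IS-element detection, no nested/overlapping module architectures, no
  transfer-direction inference.
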