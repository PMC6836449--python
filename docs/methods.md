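# Methods

## Genome model and region classification

Coordinates are 0-based half-open everywhere internally; GFF3 input
(1-based closed) is converted on load and BED output is 0-based
half-open.  This confines off-by-one risk to the format borders.

Every contig position receives exactly one of four labels, painted in
increasing priority so that on overlap **coding > promoter >
other_genic > intergenic**:

* **coding** — union of CDS intervals over all isoforms of all genes.
  Exonic UTR bases are deliberately *not* coding; they fall in
  other_genic together with introns.
* **promoter** — up to `promoter_length` (default 2000 nt) strand-wise
  upstream of the gene's first CDS base (the start codon), clipped at
  contig ends.  Anchoring at the start codon rather than the
  transcript start follows the tool's definition of a promoter as the
  2 kb upstream of the ATG; genes with no CDS in any isoform get no
  promoter (and no coding bases) and trigger a logged warning.
* **other_genic** — gene spans (introns + UTRs) not claimed above.
* **intergenic** — everything else.

The priority ordering is a design choice the underlying definition
leaves open: it makes the most consequential label (coding, weighted
0.7 in the overall score) win on overlap.  Labels are stored as a
per-contig uint8 array, so the partition property (disjoint, covering)
holds structurally; an interval tree over the raw per-gene
coding/promoter intervals supports gene-ownership lookups, which is
also how overlapping genes each receive their own guide for a shared
site.

## PAM scanning

Every 3-mer window on both strands is tested against NGG (canonical)
and NAG/NCG/NGA (non-canonical); a site requires 20 valid bases
immediately 5' on the same strand and no N anywhere in the 23-nt
footprint (score tables are defined over A/C/G/T only, so N-containing
windows are skipped and counted rather than ambiguity-expanded).  The
four class patterns are disjoint in the PAM's 2nd/3rd base, so class
assignment is unambiguous.  A site is identified by (contig, strand,
forward-strand coordinate of the protospacer's 5'-most base), and its
region label is taken at that single base — a deterministic convention
that avoids arbitrating footprints straddling a region border.

The 30-nt scoring context is 4 nt + protospacer + PAM + 3 nt on the
PAM strand; sites too close to a contig end (or with N in the window)
have no context and receive rs2 = 0 with a flag rather than a guessed
score.

## Off-target search

Only scanned PAM sites are off-target candidates (a 20-mer without any
of the four PAM classes cannot be cut).  Sites are partitioned into
eight datasets — {canonical, non-canonical} × {coding, promoter,
other_genic, intergenic}.  Coding and promoter share a mismatch cap
but stay separate datasets so per-region CFD maxima remain computable;
this reconciles the three cap tiers with the eight-dataset layout.

Caps (defaults, overridable): canonical 6/4/3 and non-canonical 4/3/2
for exons+promoters / introns+UTRs / intergenic.  Retrieval uses
pigeonhole seed partitioning: for a query at distance ≤ k the 20-mer
is split into k+1 near-equal fragments; any hit preserves at least one
fragment exactly, so exact fragment lookup followed by vectorised
full-Hamming verification is complete — the guarantee that alignment
heuristics lack.  Fragment indexes are built lazily per partition
count and cached.

The early-stop rule is applied per dataset: hits accumulate
level-by-level k = 0, 1, …; after completing a level, if the
cumulative count (including the flagged self-hit) reaches the
threshold (default 20), deeper levels of that dataset are withheld.
Levels are atomic — never partially reported.  The implementation
queries once at the dataset cap and replays the level rule on the
grouped results, which is observationally identical to literal
re-querying.  Scoping the rule per dataset (rather than per guide
overall) is a documented choice where the rule's original statement is
ambiguous; it prevents abundant intergenic hits from starving the
search of the far more consequential coding hits, and both the
threshold and the switch are configurable.  The self-hit is returned
flagged rather than silently dropped, keeping the search purely
geometric; exclusion happens at aggregation.

## Scoring

**CFD** multiplies a penalty per mismatched protospacer position
(keyed by 1-based position 5'→3', guide base, target base — guide
bases in DNA alphabet, T for rU) times a factor for the PAM's last two
bases, with `pam_factor("GG") = 1`.  The empty product is 1, so a
perfect NGG match scores exactly 1.0.  Missing table keys raise a
table-integrity error — never a silent 0.

**rs2** is a deterministic linear model behind a pluggable scorer
contract: `clamp(intercept + Σ wᵢxᵢ, 0, 1)`.  Features: 30 × 4
position-specific nucleotides, 29 × 16 dinucleotides, protospacer GC
terms (`gc_count`, plus `gc_low`/`gc_high` hinges around 10),
Wallace-rule melting-temperature proxies `(2·AT + 4·GC)/(4·len)` of
protospacer segments 1–5, 6–13 and 14–18, the PAM-flanking "NGGX"
dinucleotide (PAM's N and the base 3' of the PAM), and an `in_coding`
indicator that is zero for promoter guides — the original
position-in-CDS feature is undefined outside coding sequence, and
zeroing it is the documented resolution.  Clamping (not a logistic
squash) is the simplest contract-preserving choice.  Any weight file
over this feature vocabulary is accepted; unknown names raise a
schema error.

**Packaged tables are synthetic stand-ins.**  The empirically fitted
penalty/weight values are not redistributable here, so
`scripts/make_score_tables.py` deterministically generates tables with
the right qualitative shape (penalties shrink toward the PAM-proximal
end; wobble-like mismatches are more tolerated; GG = 1.0 with
non-canonical PAM factors far smaller; small seeded rs2 weights around
a 0.45 intercept).  Every correctness property of the engine —
completeness, caps, products, bounds, ranking — is independent of the
numeric table content, and users can drop in fitted tables by path.

## Ranking

Per guide, non-self hits are reduced to the maximum CFD per region
(0 when a region has no hits).  Scores:

* default: `0.5·rs2 + 1 − 0.5·(0.7·max(cfd_coding, cfd_promoter) +
  0.2·cfd_other_genic + 0.1·cfd_intergenic)` ∈ [0.5, 1.5].  The
  published formula's unbalanced parentheses are resolved so the best
  guide (rs2 = 1, no off-targets) scores highest.
* homoeolog mode: hits inside a group partner's coding/promoter
  intervals are diverted out of the penalty maxima into `cfd_hmlgs`
  (best CFD per partner, zero-filled for partners with no hit — so
  the reward `0.34·mean(cfd_hmlgs)` is largest for guides predicted
  to cut *every* copy; the zero-fill choice is switch-less but
  localised in `aggregate_region_cfd`).  Range [0.67, 1.67].

Both scores are heuristics for ranking, not fitted quantities; the
individual rs2/CFD columns are always reported.  Ordering is total:
overall desc, rs2 desc, then (contig, start, strand), so ranking is
permutation-invariant; the top 10 are flagged for default display.
Isoform coverage reports the fraction of a gene's isoforms whose exon
union contains the full 23-nt footprint (promoter guides: 0 by
definition).  Report scores print to 4 decimals; full precision is
kept internally.

## On-the-fly sequence mode

For a pasted sequence (≥ 23 nt), canonical-PAM guides are extracted
from both strands and searched against the database genome under the
same caps.  The guides carry no gene/region, so the default formula is
used and homoeolog targeting is rejected.  rs2 is computed only when
the 30-nt context lies within the pasted sequence.  The first exact
k = 0 genomic match (ordered by contig, start, strand) is flagged as
the presumptive on-target and excluded from the maxima; additional
exact matches remain off-targets.

## Persistence

A database is persisted as flat TSVs (guides, off-targets, region
BED) plus a JSON manifest recording input paths, SHA-256 checksums,
configuration and counts.  Because the build is fully deterministic,
loading re-runs the build from the recorded inputs and verifies the
stored checksums — the flat files are the canonical representation
and byte-equality is the determinism test.

## Synthetic fixtures

`make_toy_genome` draws uniform-random background sequence and lays
out equal-geometry multi-exon genes (3 × 300 nt exons, 200 nt introns,
60 nt terminal UTRs by default) with 2 kb promoters and ≥ 500 nt
intergenic spacers; alternative isoforms skip a middle exon.  Planted
guides are rejection-sampled to be more than the deepest cap (6) away
from every background 20-mer window on either strand and ≥ 15 apart
from each other, so planted off-targets (exact-k mutations with a
realised PAM, placed wholly inside the requested region) are the
*only* hits and truth tables are exact; region and distance are
re-verified post hoc with the pipeline's own primitives.  Homoeolog
triplets copy a source gene's block (promoter through 3' flank) with
independent per-base substitutions whose positions are nested across
rates for a fixed seed, making divergence — and hence homoeologue CFD
— monotone in the rate.  Everything is byte-deterministic in
(spec, seed).

What the fixtures do *not* emulate: repeat structure, GC landscape,
realistic gene density, indel/bulge variation between homoeologues,
or genome-scale size.  Passing tests therefore demonstrate algorithmic
correctness (completeness, caps, scoring algebra, determinism), not
biological performance of the score tables on real genomes.

## Problem sizes and numerical choices

The shipped verification uses 20 random genomes of 50–97.5 kb with
100 sampled guides each for the completeness check, desk-scale
stand-ins for a genome survey; completeness is a per-guide exact
set-equality property, so it does not dilute with scale.  Floating
point: CFD/overall comparisons in tests use exact or 1e-12 absolute
tolerances; score-table values are stored to 4–6 decimals; ties in
ranking are broken structurally, never by float perturbation.
Degenerate inputs are defined rather than special-cased: empty regions
score 0, guides without context score rs2 = 0 flagged, genes without
CDS contribute other_genic only.

## Known limitations

* Hamming distance only — no DNA/RNA-bulge off-targets.
* No Cas9-variant PAMs (SaCas9, Cpf1, …); the four SpCas9 classes are
  fixed.
* The synthetic score tables rank plausibly but are not predictive of
  real cleavage; swap in fitted tables for real use.
* `load_database` re-derives the index from the original inputs, so
  those files must remain available at their recorded paths.
* Whole genome, site list and index are held in memory — suitable for
  desk-scale genomes; a genome-scale build would shard by contig.
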