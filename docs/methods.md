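# Methods

This note documents the models and procedures implemented in `arkmito`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data generator does and does not emulate.

## Coordinates and circularity

All internal coordinates are 0-based half-open. A feature on a circular
genome that runs across the origin is a single record with `wraps=True`
whose span is `[start, L) ∪ [0, end)`; GenBank `join(a..L,1..b)` locations
map onto this on read and are written back as two-part joins, and GFF3
output emits two lines sharing an `ID`. This representation makes circular
arithmetic (complements, rotations, span lengths) unambiguous: rotating
the origin permutes coordinates but provably preserves every span length,
which the test suite exercises directly.

## Unassigned regions

URs are defined as the complement, on the circle, of the *union* of all
annotated feature spans. Using the union (rather than per-feature gaps)
means overlapping or abutting annotations — common for tRNA clusters and
the cox2/cox2-b tandem — can never produce negative gaps, and yields the
exact conservation law `Σ UR lengths + |feature union| = genome length`.
tRNAs and rRNAs count as assigned sequence, so "intergenic" means
everything between genes inside the coding blocks. The two large shared
URs are labelled by their flanking genes: UR1 lies downstream of cox2 or
cox2-b and upstream of nad6, UR2 between nad2 and cox1; a wrapping UR
qualifies, matching the convention in which UR2 straddles the sequencing
origin. Report percentages are rounded half-up to two decimals, the
convention needed to reproduce published UR-proportion tables digit for
digit.

## Tandem repeats

The census reports *exact* maximal tandem runs: a run of period `p`
starting at `i` is reported iff it cannot be extended left, its unit is
primitive (its own smallest period is `p`, established with a KMP border
computation), total length ≥ 6 nt and copies ≥ 2, with fractional
trailing copies allowed. Each run is therefore reported exactly once, at
its smallest period, while genuinely different periods overlapping the
same region are all reported. Exactness is a deliberate restriction:
tolerance parameters of the usual detectors are a free dial that cannot
be validated, whereas the exact detector is provably equivalent to a
brute-force scan over all (position, period) pairs — the property the
suite checks on random sequences.

## ORF discovery

Scanning uses NCBI translation table 5 with stop set {TAA, TAG}. Within
each reading frame an ORF runs from the 5'-most permitted start codon
after the previous stop to the next in-frame stop (the convention of the
common ORF finders, which report the longest ORF per stop); the stop is
included in `nt_len`, so a complete ORF has `nt_len = 3·aa + 3`. The
default start set {ATG, ATA, ATT, GTG} is the set observed in Arcidae
protein-coding genes; the full table-5 start set can be supplied instead.
Codons containing N are neither start nor stop and translate to X. Open
frames that run into the 3' boundary of the scanned region are reported
with `complete_stop=False` and stop codon `T`, `TA` (a truncated stop
completed to TAA by polyadenylation) or `none`; truncated stops are
accepted only at the region boundary. ORFs of ≥933 nt are flagged as
LORFs (large ORFs of unknown function, the class that dominates UR2
expansion). The minimum reported length is 75 nt.

## Homology screening and families

Pairwise protein alignment is affine-gap dynamic programming with
BLOSUM62 and the BLAST cost convention (a gap of length k costs 11 + k);
percent identity is matches over *all* aligned columns, gap columns
included, which makes identities comparable across pairs and is stated
explicitly because the alternative denominator shifts values by a few
points. Presence of a query ORF in another genome is called from the best
local hit against (i) the proteins of all ORFs discovered in that
genome's URs and (ii) stop-free six-frame peptides of the UR sequence
(catching frame-broken or unannotatable copies). Calls use identity ≥30%
with query coverage ≥90% (complete) or ≥30% (partial). Because identity
and coverage percentages alone cannot distinguish a short chance
similarity from a homologous fragment on short queries, a raw-score floor
(default 50 BLOSUM62 units) stands in for the E-value cutoff that
database searches would apply; a conserved stretch of even ~10 residues
clears it, while the best chance hits of unrelated short queries against
multi-kilobase six-frame translations plateau in the 30s. Duplication
families are single-linkage connected components at ≥28% global identity;
single linkage is the right closure here because the published family
evidence is a chain of pairwise identities through one hub sequence.

## Ka/Ks (NG86)

Codon alignments are built by globally aligning the two protein
translations and back-translating; gapped columns are dropped and
terminal stops stripped. For each codon, the number of synonymous sites
is the fraction of the nine single-nucleotide changes that preserve the
amino acid; changes that create a stop codon count as nonsynonymous, and
sites are averaged between the two sequences (so `S + N = 3L` exactly).
Codon pairs differing at k positions are scored by averaging the k!
minimal mutational pathways with equal weights, excluding pathways that
pass through a stop codon (falling back to all pathways only if every
one is blocked). Proportions `ps = Sd/S` and `pn = Nd/N` are corrected
with Jukes–Cantor, `d = −(3/4)·ln(1 − (4/3)p)`, raising a saturation
error at p ≥ 3/4. `Ks = 0` with `Ka > 0` yields an infinite-ratio
sentinel; both zero yields NaN. The group contrast between protein-coding
genes and ORFs uses a two-sided Mann–Whitney U test, chosen because the
ratio distributions are small-sample and skewed. NG86 with equal pathway
weights was chosen over maximum-likelihood codon models because it is
fully specified and testable against an independent exhaustive
enumeration, which the suite does for alignments up to 50 codons; the
scientific conclusions targeted (every ω < 1; ORF mean above PCG mean)
are robust to the estimator choice.

## Expression (TPM)

`TPM_i = 10⁶·(c_i/l_i)/Σ_j(c_j/l_j)` with effective length equal to the
annotated feature length (gene-level counting; no fragment-length
correction), so each sample sums to 10⁶ exactly and the measure is
invariant to library size. All-zero samples yield all-zero TPM with a
warning rather than an error.

## Brownian-motion ancestral states

Under BM a trait's covariance between two tips equals the shared
root-to-tip path length. The ML state of an internal node equals the GLS
root estimate `(1ᵀC⁻¹x)/(1ᵀC⁻¹1)` of the tree re-rooted at that node.
The implementation computes all node estimates in two traversals by
Gaussian message passing: every neighbour sends an
inverse-variance-weighted (mean, variance) message, and the estimate at a
node combines all incoming messages — algebraically identical to the
re-rooted GLS (the suite verifies the identity against an explicit
re-rooting + n×n covariance oracle) but linear time, and polytomies need
no resolution. `σ̂²` is the ML rate at the root,
`(x − â1)ᵀC⁻¹(x − â1)/n` (biased by (n−1)/n as usual for ML). Zero-length
cherries with conflicting tip values make C singular and raise with a
suggestion to prune. Trees are consumed as input (Newick with mandatory
branch lengths); tree inference is out of scope. Mitogenome sizes enter
as kb with one decimal, one tip per genome (conspecific genomes differ by
tens of kb in this clade, so species means would destroy the signal).

## Synthetic data

The generator emulates the shared Arcidae architecture: one circular
genome, all genes on the + strand in the shared order, two coding blocks,
UR1 (default 9,938 nt) between cox2-b and nad6 and UR2 (default 16,045
nt) between nad2 and cox1, with the origin placed inside UR2 so that UR2
wraps, as in the published coordinate tables. Gene lengths follow typical
Arcidae values; the default planted ORF panel mirrors the published
11-ORF census (lengths 238–1,983 nt, starts ATG/ATA, stops TAG/TAA and
one truncated `T` at the UR2 boundary), with two paralog pairs at 67% and
47% target amino-acid identity. UR background is AT-rich (68% A+T) and
explicitly *sanitized*: any chance ORF ≥75 nt or tandem run ≥12 nt
outside the planted spans is broken by point substitutions (synonymous
substitutions when the run lies inside a planted ORF, so the ORF and its
protein survive), making recovery tests sharp — at the default
thresholds the found set equals the planted set outside planted spans,
and chance ORFs can persist only where they overlap planted elements
(recovery is therefore asserted as a superset on ORFs and as exact
equality on repeats). Divergence planting applies exact counts of
synonymous and nonsynonymous single-nucleotide substitutions, at most one
per codon, sparing start and stop codons; identity targeting mutates
residues with accept/reject against the package's own global aligner
until the realized identity is within ±2 points. Read counts are
multinomial draws with read probability ∝ TPM × length. Presence-plan
cohorts plant complete copies verbatim and partial copies as an internal
~40%-of-codons fragment re-framed as a mini-ORF; the query panel is
generated without paralog pairs, because with 67%-identity paralogs among
the queries a planted copy of one necessarily also registers its paralog
and exact plan recovery would be ill-posed.

What the generator does **not** emulate: sequencing or assembly error,
heteroplasmy, tRNA annotations (URs are delimited by the union of the
features present, so absent tRNAs simply enlarge the intergenic
complement), inexact (mutation-bearing) tandem repeats, and base-level
composition structure beyond the AT bias. Passing recovery tests
therefore demonstrates correctness of the detectors under their stated
definitions, not robustness to annotation noise or repeat divergence in
real GenBank records.

## Problem sizes

The default test suite runs the generator mostly at a reduced scale
(~9 kb genomes, two planted ORFs per UR) and uses the ~40 kb study-scale
genome where the published magnitudes matter (UR lengths, 660-aa ORF,
conspecific Ka/Ks panel of 12 PCGs + 11 ORFs). Property-based
equivalences run on random sequences up to 2–3 kb, codon alignments up to
50 codons, and trees up to 32 tips; BM recovery uses 200–500 seeded
replicates. These sizes are where the brute-force oracles are exact yet
cheap, and scaling the detectors further is linear or near-linear.

## Known limitations

- Exact repeats only; the published repeat counts from tolerant detectors
  are not directly comparable.
- NG86 differs from ML codon models by a few percent at moderate
  divergence; printed 4-decimal rate values from other estimators are not
  reproduction targets, the selection regime (ω < 1, group ordering) is.
- Screening identity thresholds are calibrated for protein space;
  nucleotide-level homology of non-coding UR sequence is out of scope.
- The GenBank reader takes feature names from `gene`/`product`/
  `locus_tag` qualifiers and keeps only gene/CDS/tRNA/rRNA/ORF features.
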