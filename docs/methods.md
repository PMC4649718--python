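# Methods

## The problem

Eukaryotic ATP-binding cassette (ABC) transporters are built from two domain
classes — the nucleotide binding domain (NBD) and the transmembrane domain
(TMD) — combined into four structure classes: *single* (one NBD or TMD),
*half* (TMD-NBD or NBD-TMD), *ABC2* (NBD-NBD) and *full*
(TMD-NBD-TMD-NBD or NBD-TMD-NBD-TMD). Full and ABC2 genes arise by fusion
of two smaller genes, and the phylogeny of the fused genes' N- and
C-terminal domain copies records *how*: if fusion followed shortly after a
duplication (**homofusion**), the N- and C-terminal domains of the full
genes cluster with each other before any half-structure domain; if two
long-diverged halves fused (**heterofusion**), one terminal clusters with
half-structure (or other-family) domains first. A second topological signal
concerns origins: a eukaryotic domain nested inside a clade of prokaryotic
domains points to lateral transfer or organellar endosymbiosis.

This package implements that analysis as a tested pipeline — architecture
classification, domain extraction, alignment handling, distance trees,
fusion-mode and HGT calls — and, because genome-scale input cannot be
redistributed, ships a simulator of explicit duplication–fusion histories
that provides ground truth for every stage.

## Substitution model

Sequences evolve under a uniform-replacement Poisson model: on a branch of
length *t* expected substitutions/site each site receives Poisson(*t*)
events, each replacing the residue by one of the other 19 uniformly.  The
expected observed difference fraction is

    p(t) = (19/20) · (1 − exp(−(20/19) t)),

with saturation limit 19/20, inverted by the distance correction

    d(p) = −(19/20) · ln(1 − (20/19) p).

The model deliberately trades realism (no empirical exchangeabilities, no
rate heterogeneity, no indels) for an exact closed form, which makes the
simulator analytically calibratable and the correction an exact inverse of
the generating process.  Branch lengths are expected substitutions/site
directly; time and rate are not separately identifiable and are never
separated.  Because no indels are simulated, extracted domain instances of
one class are columnwise homologous by construction ("identity stacking"),
so the alignment stage operates on true homology without any MSA heuristic;
externally aligned FASTA is accepted for real data.

## Simulated histories

All scenarios evolve whole genes (domains plus linkers) along a fixed,
documented event order from a single seeded generator, so identical configs
give byte-identical datasets.  Parameters (defaults in brackets):

| parameter | meaning | default |
|---|---|---|
| `n_taxa` | tips radiated per lineage | 6 |
| `nbd_length` / `tmd_length` | domain lengths, residues | 180 / 260 |
| `pre_fusion_divergence` | branch length accumulated by *each* duplicate copy between duplication and fusion | 0.05 |
| `post_fusion_divergence` | stem branch of a radiating lineage after fusion | 0.4 |
| `within_group_divergence` | terminal branch of each tip (pairwise within-clade distance is twice this) | 0.1 |
| `linker_length` | inter-domain/fusion linker, residues | 10 |
| `n_prokaryote_lineages` | prokaryote clades in `hgt_mix` | 3 |

`homofusion`: a half ancestor splits into the fusion lineage and a half
sister lineage; the fusion lineage duplicates, each copy evolves
`pre_fusion_divergence` (short), the copies fuse, the full gene radiates.
The sister split is placed one `post_fusion_divergence` below the
duplication node on each side — the field gives no quantitative scale for
how deep the extant half relatives sit, so this is a package choice; it
keeps the homofusion signal (same-gene partner nearer than halves) strictly
inside the true tree metric while leaving it the *smaller* of the two
margins, which is the realistic hard case.  `heterofusion`: the ancestor
duplicates at the root, both copies evolve `pre_fusion_divergence` (long);
one copy then duplicates again at fusion time, one daughter fusing as the
C-terminal half and the other persisting as the extant half lineage — so
the C-terminal domains are sisters of the halves and the N-terminal domains
are the outgroup, the topology that defines heterofusion.  `abc2` mirrors
`homofusion` with single-NBD genes and an archaeal single-NBD sister
lineage.  `half_only` gives two half lineages (families A and B) for
identity/architecture work.  `hgt_mix` is a star of prokaryote half clades
plus one eukaryote clade, with one extra eukaryote-labelled tip generated
inside a prokaryote clade — ground truth for HGT detection.

There is no divergence scale separating "recently duplicated" from
"long-diverged" in nature; the pre-fusion divergence is exposed as a free
parameter, and the reference conditions used throughout the tests are 0.05
(homofusion) vs 0.8 (heterofusion) with post-fusion 0.4 and within-group
0.1.

The simulator also emits three-helix span tables per TMD instance with the
first inter-helix loop drawn from a family-conditional normal (family A:
mean 130, others: mean 60, sd 15, truncated to fit the TMD), emulating
transmembrane-topology predictor output for the helix-spacing analysis.

**What passing on simulations does not show.** The generator omits indels,
alignment error, site-rate heterogeneity, model misspecification (real
pipelines use approximate-ML trees), incomplete lineage sorting, and
family-assignment noise.  Recovery rates reported here are upper bounds on
real-data performance; the pipeline's value on real data is procedural
(classification, extraction and calls are deterministic and auditable), not
a guarantee of the recovery rates.

## Architecture classification

Domain hits (plain TSV or HMMER `domtblout`; 1-based inclusive envelope
coordinates) are thresholded at score ≥ 20 bits and E-value ≤ 1e-3, then
de-overlapped greedily by descending score: a hit is dropped if it overlaps
a kept hit by more than 25% of the shorter hit (tolerates ragged envelope
edges without merging tandem domains).  The nine Pfam TMD classes collapse
to "TMD" for structure typing and are retained as annotation.  The ordered
domain string maps to (structure, orientation) by the exhaustive table in
`architectures.classify_architecture`; anything outside the seven canonical
strings — including extra weak repeats — is "other" and never silently
truncated.  Family/structure combinations outside the canonical repertoire
(e.g. a single-NBD gene labelled family E, a half labelled family C) are
flagged `suspect`, mirroring the observation that such sporadic structures
usually reflect incomplete assemblies or gene mis-prediction; the flag is
rule-based only, with no manual-verification stage.

## Alignment statistics

Columns with gap fraction *strictly greater* than 0.20 are removed (a
1-in-5 gap column is kept).  Percent identity uses the both-non-gap
denominator: 100 × identical / comparable columns; pairs with no comparable
column are reported missing, not zero.  This convention is load-bearing for
every identity table the pipeline emits and is stated on the function.
Group-mean identity averages all cross-group pairs (off-diagonal) or all
unordered within-group pairs (diagonal).  Motif consensus takes the
majority non-gap residue per column in a window of trimmed-column
coordinates; ties break alphabetically and are flagged, all-gap columns
emit "-".

## Trees

p-distances on trimmed columns are Poisson-corrected and fed to
neighbor joining (Saitou–Nei Q-criterion) implemented in-repo so that
tie-breaking is fully specified: among equal-minimum Q cells the pair whose
cluster representatives (smallest contained tip id) sort lexicographically
first is joined.  Negative branch-length estimates are clamped to zero.
Trees are unrooted; serialization sorts children by smallest descendant tip
label so topologically equal trees are byte-identical.  dendropy is the
tree container (Newick I/O, bipartitions, patristic distances); scikit-bio's
independent NJ is used only as a cross-check in the test suite.

Saturation: `correct_distance` is undefined at p ≥ 19/20.  The API default
is to abort naming the offending pairs, but the pipeline's tree stage uses
an explicit capping policy — p is clamped at 19/20 − 1/(2L) for an
L-column alignment, with a logged warning — because at deep divergences
(the heterofusion reference conditions put the deepest pairs at 2.6
substitutions/site, E[p] ≈ 0.89) a finite sample crosses the saturation
point by noise in a substantial fraction of runs, and aborting the whole
tree on one noisy pair is worse than one capped, still-very-large distance.

Bootstrap supports resample trimmed columns with replacement (default 100
replicates; classical studies use 1000, the default is sized for desk-scale
data); the support of an internal edge is the fraction of replicate trees
containing its split.  Within replicates saturated pairs are always capped
(a resample can exceed the base alignment's maximum p), so replicate trees
never abort.

## Fusion-mode calls

"Firstly clustered with" is operationalized without a root: for each full
gene, the patristically nearest candidate to its C-terminal NBD is sought
among three categories — the same gene's N-terminal tip, same-family
half-structure tips, and other-family tips.  Terminal tips of *other*
same-family full/ABC2 genes are excluded from the candidate pool: their
proximity reflects the shared post-fusion radiation and carries no
information about the fusion mode (left in, another gene's C-terminal tip
would win every query).  A "same gene" winner casts a homofusion vote only
if the symmetric query from the N-terminal tip agrees; disagreement is an
unresolved vote.  Any half/other winner is a heterofusion vote.  ABC2
families use single-structure NBD tips (any family) as the half-analogue
category.  Distance ties break to the smallest tip id and are flagged.

Votes aggregate to a family call when the winning fraction reaches the
margin threshold (default 0.7, configurable) — a family-level mode is
claimed despite per-gene noise only with a clear majority; how many
discordant genes should overturn a call has no field consensus, so the
margin is exposed rather than hidden.  The call is invariant to Newick
rotation because it uses only patristic distances.

## HGT candidates

Clades are enumerated root-free as the sides of the tree's unrooted
bipartitions; for each eukaryote tip the smallest split side containing it
with at least `min_clade` (default 4) tips is examined, and the tip is
flagged when the prokaryote fraction among the side's other tips reaches
`min_prok_fraction` (default 0.8).  An earlier midpoint-rooting formulation
was rejected: on symmetric trees the midpoint can land exactly on the
enclosing clade's node, which then becomes the root and dissolves the clade
into "the whole tree".  The split formulation is consistent with the
package-wide rule that clustering statements are made on unrooted splits.
When several minimal sides tie in size the highest prokaryote fraction
decides.  This detector does not distinguish mitochondrial/plastid
endosymbiosis from other lateral transfer; that requires localization
evidence outside its scope.

## Helix spacing

Inter-helix distance counts residues strictly between two helices (adjacent
helices are at distance 0); first-pair and last-pair distances are binned
per family at a boundary of 100 residues, boundary-equal values falling in
the ≤ bin.  Whether published distances were end-to-start or
center-to-center is generally unstated; strictly-between is the convention
here and is applied uniformly.

## Pipeline and determinism

A single strict JSON config drives the run; unknown keys anywhere are
errors.  Simulated datasets are written to disk and re-read through the
same readers used for external files, so every simulated run also exercises
the files-mode path and round-trip integrity.  Result bundles contain no
timestamps; with a fixed config (including seeds) two runs are
byte-identical, bootstrap supports included.

## Problem sizes in the test and acceptance suites

Recovery properties are measured at: 50 + 50 fusion replicates
(6 taxa, 180-residue NBDs — 18-tip NBD trees), 50 `hgt_mix` replicates,
100 random 8-taxon trees for NJ consistency, and 30,000 sites for
substitution-model calibration (the 3-binomial-SE band tightens in absolute
terms as sites increase, so this is the stricter choice).  These sizes are
the package's reference desk-scale conditions; all are parameters, not
limits.

## Known limitations

- Distance/NJ trees stand in for the approximate-ML trees a real-data study
  would use; with deep divergence and short domains, corrected p-distances
  lose information faster than likelihood methods.
- Fusion-mode calls use topology only; motif divergence between N- and
  C-terminal copies (available via `motif_consensus`) is corroborating
  output, not part of the vote.
- The suspect flag cannot see assembly evidence; it is a repertoire check.
- Family labels are trusted input (or simulator truth); no homology-based
  family assignment is performed.
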