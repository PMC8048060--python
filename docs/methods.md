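# Methods

## Distance model

The only distance implemented is the uncorrected p-distance under uniform
rates: `p = m / n` over the columns where both members of a pair carry a
concrete base. Transitions and transversions count equally; no multiple-hit
correction (JC, K2P, …) is applied, which is appropriate at the shallow
divergences (< 10 %) where barcode-gap analysis is meaningful and keeps the
statistic exactly reproducible from the alignment.

Gaps *and* IUPAC ambiguity codes are treated as missing data and removed by
pairwise deletion. Treating ambiguity codes as missing (rather than as
partial matches) is the conventional choice of the widely used distance
software this engine mirrors; it also makes a 0 % within-species range
attainable for species whose consensus carries ambiguities elsewhere. A
pair with no comparable columns yields NaN plus `n_sites = 0`; NaNs
propagate into summaries as skipped values with a logged count and are
surfaced as "no data" species pairs, never coerced to zero.

Bootstrap standard errors resample columns of the *full* alignment with
replacement and re-apply pairwise deletion inside each replicate, so a
replicate can lose comparable sites; such replicates are dropped. The SE is
the SD (ddof = 1) of replicate distances. For a gap-free pair of length `L`
with `m` mismatches the replicate distance is `Bin(L, m/L)/L`, giving the
closed form `sqrt(p(1−p)/L)` that the tests and the acceptance script check
at `L = 4`, `m = 1` (0.2165).

## Barcoding-gap cut-off

`cutoff = max` within-species maximum over species not listed in
`exclude_species` (default: none excluded). `gap_ok` requires **every**
between-species minimum to exceed the cutoff strictly; pairs below it are
returned as exceptions. The exclusion list is an explicit parameter rather
than an automated outlier rule: which species' internal variation should be
allowed to set the threshold is a taxonomic judgement, and automating it
would hide exactly the cases a curator must look at. Ties for the maximum
are resolved by value; the species attaining it is logged.

## Mislabel detection

The classifier assigns each query to the species of its nearest designated
reliable reference (minimum p-distance over the panel, per-species minimum
first, deterministic tie order by distance then species name). It is a
deliberate, simple substitute for reading clade membership off a
phylogenetic tree: with well-separated species clusters the two agree, and
the distance rule is reproducible without tree inference. Its counts should
not be expected to match tree-based tallies on real data near cluster
boundaries.

Defaults: `genus_cutoff = 0.05` (a 95 % similarity screen — queries farther
than this from every reference are flagged `not_in_genus`, mirroring how
extreme outliers are excluded from barcode datasets before analysis) and
`tie_epsilon = 0` (only exact ties are `ambiguous`). Ties are always
reported, never broken silently; panel members classify against themselves
at distance 0 (panel membership is metadata, not exclusion).

## Diagnostic fragments

A column is diagnostic for species S when S's residue set (union over
members, ambiguity codes expanded to base sets, gaps excluded) is non-empty
and disjoint from the union of all other species' sets at that column. Two
consequences are intentional:

- Within-species variation is tolerated as long as the whole set stays
  disjoint — the fragment consensus then contains ambiguity codes (e.g. W).
- A column where every other species is gapped is diagnostic
  (presence/absence at an indel region is informative), so fragment spans
  can exceed their ungapped sequence length.

Assembly merges consecutive diagnostic columns separated by at most
`merge_gap = 5` non-diagnostic columns and keeps fragments with at least
`min_diag = 2` diagnostic columns; ends are diagnostic by construction.
`min_diag = 2` encodes "more than one nucleotide difference", the minimum a
probe-based assay (such as hyperbranched rolling circle amplification) can
exploit; `merge_gap = 5` is a pragmatic default allowing short conserved
interruptions inside a probe-sized region, and both are first-class CLI
parameters. The greedy left-to-right merge provably equals exhaustive
maximal-window enumeration, which the tests verify against an independent
oracle on hundreds of random alignments.

## Synthetic data generator

The generator emulates a species-structured barcode alignment and nothing
more: star phylogeny (one ancestor, independent species roots, independent
members), site-independent substitutions to a uniformly chosen different
base, no rate heterogeneity, no transition bias, fixed sequence length.
Expected within-species distance is `2p(1−p) + (2/3)p²` at member rate
`p = p_intra`; between-species distances grow monotonically with `p_inter`.
Defaults (3 species × 5 members × 600 columns, `p_intra = 0.005`,
`p_inter = 0.03`) produce within ≈ 1 % and between ≈ 6 % — the regime of a
genus with a clear barcoding gap, matching typical ITS divergences.

Indel blocks (`indel_block_rate` = per-column probability that a block
starts; lengths uniform on 3–8 columns) gap out all members of one species
to exercise pairwise deletion and gap diagnostics. Planted fragments
overwrite the target species' members and force every other species to a
different base at those columns, so planted columns are diagnostic by
construction; a planted fragment colliding with an indel block of its own
species is an error, not silently resolved. Label swaps relabel
`round(fraction · n)` sequences to a uniformly chosen other species;
designated reference sequences are never swapped, since references are the
curated anchors by definition. Seeds are mandatory everywhere.

Because the generator is a star tree with independent sites, passing tests
demonstrate correct *algorithmic* behaviour (distances, gap logic, recovery
of planted signal), not robustness to real-data features it does not model:
phylogenetic autocorrelation, rate variation across sites, length variation,
alignment error, or chimeric sequences.

## Numerical and interface choices

- Distances are proportions internally; tables print percentages with two
  decimals at the reporting layer only.
- All column coordinates at interfaces are 1-based inclusive.
- `U` is normalised to `T` and input lowercased residues are uppercased on
  read, since public-database records vary.
- Strict id reconciliation between alignment and label table is the
  default; `--loose` drops unmatched label rows with a warning (alignment
  ids always need labels).
- Pipeline runs are deterministic given the seed; the manifest records the
  config, seed, input checksums and package version needed to re-run
  exactly. Stage failures leave partial outputs plus a `FAILED` marker
  naming the stage.
- Acceptance-script problem sizes (20 replicate seeds, 10⁵ bootstrap
  replicates) were chosen so Monte-Carlo error is well below the effects
  being measured while the whole script runs in seconds.

## Known limitations

- The nearest-reference classifier ignores within-species structure; a
  species whose diversity exceeds its distance to a neighbour can shadow
  that neighbour. Tree-based placement is out of scope.
- The cut-off estimator reports the observed boundary, not an optimized
  threshold (no ROC/threshold search).
- Fragment discovery assumes the alignment is correct; diagnostic columns
  inside misaligned regions are artefacts, and alignment positions are not
  comparable across aligner versions — fragment sequences and diagnostic
  counts are the stable quantities.
- No support for protein alphabets or unaligned input.
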