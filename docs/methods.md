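# Methods

## The procedure

`refconcord` quantifies what happens to an SNV call set when it is carried
from one genome assembly version to another. The pipeline has four stages:

1. **Filtering.** Call sets are reduced to biallelic single-nucleotide
   substitutions. Indels, symbolic/structural alleles and records without a
   called genotype are removed and tallied; multi-allelic SNV records are
   split into biallelic records, each keeping the sample's dosage of that
   alt allele. Genotypes are normalized to alt dosage (`0/1` or `1/1`),
   which makes comparison phase-insensitive and invariant under allele
   complementation.
2. **Liftover.** UCSC chain files are parsed into colinear gapped alignment
   chains (block arithmetic is validated against the header spans), indexed
   by an interval tree over aligned blocks, and queried per variant. A
   position covered by several chains resolves to the highest-score chain;
   distinct equal-score targets are rejected as multi-mapped. Positions in
   alignment gaps vs outside any chain are distinguished
   (`unmapped_in_gap` / `unmapped_no_chain`). Across a `-` strand chain,
   alleles are complemented and the strand-local q-side coordinates are
   converted to plus-strand. Finally the lifted reference allele is checked
   against the target assembly base; a mismatch rejects the variant
   (configurable to keep-and-carry instead, since conversion tools differ
   on this point and the choice measurably changes conversion rates).
3. **Matching.** Converted SNVs are classified against the direct target
   call set as concordant / genotype-discordant / position-discordant; the
   match key is `(sequence, position, ref)`. An alt-allele mismatch at a
   matched position counts as genotype-discordant by default (flag
   `alt_mismatch_class` flips it to position-discordant). CR, PDR and GDR
   follow the definitions in the README; the partition
   `converted = concordant + PD + GD` is enforced structurally.
4. **Characterization.** Discordant rosters are stratified by a
   high-confidence BED (membership of the 0-based position in half-open
   intervals), the LC/HC enrichment ratios PR/GR are computed over the
   converted set, depth frequency tables are built per roster, and
   reference-allele composition is computed on the lifted (target-side)
   reference alleles — the target side is the coordinate system in which
   the discordance is observed.

### Assumptions

- Single-sample diploid call sets; genotype comparison is by alt dosage.
- Chains are trusted as given; the package maps points, it does not build
  or re-score whole-genome alignments.
- Only SNVs are lifted. Indels and structural variants are out of scope
  (they are far less reproducible across assemblies and would need
  block-edge semantics that single-base lifting avoids entirely).

### Degenerate inputs and tie-breaks

- Empty chain text parses to an empty chain set; mapping against it returns
  `unmapped_no_chain` for everything.
- `conversion_rate` with an empty source call set is an error; PDR/GDR with
  zero converted SNVs are `None` sentinels, as are PR/GR with a zero
  denominator stratum. `log2(PD/GD)` is `±inf` when exactly one class is
  empty and `None` when both are; non-finite values are excluded from
  aggregate rows in summary tables.
- Duplicate `(seq, pos, ref, alt)` records keep the first occurrence;
  split multi-allelics survive because the alt allele is part of the key.
- Base-composition percentages are closed to exactly 100 against float
  round-off (residual of order 1e-13 folded into %A); the invariant is
  checked at 1e-9.

## The synthetic-data generator

Real cross-assembly benchmarks hinge on a deep-coverage human sample and
dozens of aligner/caller pipelines; at package scale the generator replaces
them with fixtures in which every statistic has a known expected value.

`generate_assembly_pair` draws a random source sequence at a configurable
GC fraction (default 0.42, the human genome's background) and applies a
seeded edit script of non-overlapping deletions, insertions and inversions
(at least 30 colinear bases are kept between edits so every alignment block
is non-trivial). It emits both assemblies, the base-level truth map, and
chain files in both directions. The chains are re-derived into a per-base
lookup by a linear walk of all blocks and compared against the truth map on
every construction — the central cross-module oracle tying the liftover
engine to the generator.

`simulate_callsets` places variants on the source assembly and projects the
convertible ones into the direct target call set, with controlled
injections:

- `n_unconvertible` variants placed inside deleted source regions (these
  and only these fail conversion, so CR is exact by construction);
- `n_position_discordant` variants omitted from the direct set and
  `n_genotype_discordant` variants altered in it (alt allele or zygosity,
  50/50), recovered exactly by the pipeline;
- `n_target_only` direct-set variants placed in inserted (target-novel)
  sequence, which drive the reverse-direction conversion loss and let a
  single fixture reproduce the directional CR asymmetry seen when a newer
  assembly resolves sequence the older one lacks.

Injected discordances mimic the three empirical signatures of real
discordant SNVs:

- **Depth**: read depths are negative-binomial (mean 30, dispersion 10 — a
  realistic overdispersed deep-WGS profile); unconvertible and discordant
  variants use mean × `depth_shift` (default 0.2).
- **Confidence**: high-confidence BEDs are drawn as 500 bp windows kept
  with probability `hc_coverage` (default 0.7). Discordances are assigned
  to the LC stratum with a probability chosen so that the *expected value
  of the PR statistic equals* `lc_enrichment`. The naive draw odds
  `f·LC/(f·LC + HC)` would under-shoot, because the injected discordances
  are themselves part of the all-converted denominators; the generator
  therefore solves `q·(N_h + n_d(1−q)) = f·(1−q)·(N_l + n_d·q)` for
  `q ∈ (0,1)`, where `N_h`/`N_l` are the expected background stratum sizes
  and `n_d` the number of injected discordances. With this calibration the
  PR estimator recovers `f` with only binomial noise.
- **Composition**: discordant target-side reference bases are drawn from
  `gc_bias_discordant` (default A/T/G/C = 0.24/0.24/0.26/0.26, i.e. G+C
  0.52 against the 0.42 background) and positions are then sampled from
  base- and stratum-matched pools, so the injected composition is exactly
  multinomial. Genotypes are het:hom-alt 2:1.

### What the generator does not emulate

Alignment and calling are not simulated: there are no reads, no mapping
ambiguity in repeats, no caller-specific error profiles, and one synthetic
caller pair rather than a grid of pipelines. Discordances are injected by
construction, not produced by a mechanistic error process. Passing tests
therefore demonstrate that the *measurement machinery* — coordinate
mapping, allele handling, classification, stratified ratios — is exact and
unbiased under known truth; they do not validate conclusions about any
particular real aligner, caller or assembly pair.

## Problem sizes

The test suite and `scripts/acceptance.py` use fixtures from 5 kb identity
pairs up to 1 Mb pairs with 60,000 variants; the exhaustive mapping oracle
checks every base of twenty 10–100 kb pairs. These sizes give the
stochastic recoveries (PR, composition, depth) sampling errors well inside
their assertion bounds — e.g. the log2 PR check at 10,000 discordance draws
uses a 3-sigma delta-method bound of about ±0.12 — while keeping a full run
in the tens of seconds.

## Known limitations

- Chain q-side strand handling supports `+`/`-` whole-chain orientation
  (the UCSC format's model); there is no per-block strand.
- `lift_callset` holds call sets in memory; fixtures up to a few million
  variants are fine, chromosome-scale real data would want streaming.
- The reference-allele composition of discordant SNVs is computed on the
  target side; the source-side composition differs for variants on
  inverted blocks (complementation preserves the combined G+C fraction, so
  the headline G+C contrast is side-invariant).
- Multi-sample VCFs are reduced to their first sample.
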