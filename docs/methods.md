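# Methods

## Model and assumptions

`homeocall` treats each gene of an allopolyploid transcriptome as a set of
2–10 haplotypes (one per subgenome) differing only at single-base positions
(HSPs). Reads are assumed to be correctly mapped to the gene they came from;
within a gene a read(-pair) samples exactly one subgenome haplotype, so the
bases it shows at HSP positions form a consistent haplotype fragment (a
*base pattern*). Each subgenome is identified with a diploid progenitor
species whose substitution list (SBSs vs. the common reference) approximates
that subgenome's sequence, up to post-polyploidization divergence. The
method further assumes:

- subgenomes are internally homozygous at HSP positions (no allelic
  polymorphism within a subgenome) — the finalization step in particular
  relies on this and can be disabled for heterozygous material;
- every base genuinely present at an HSP belongs to some subgenome, which
  justifies both the missing-progenitor fallback (a pattern matching no
  known diploid must come from the undocumented subgenome) and elimination
  (the last unassigned base belongs to the last uncalled subgenome);
- sequencing error is rare enough that erroneous base combinations stay
  below the base-pair noise floor at two consecutive HSPs.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `hsp_min_frac` | 0.05 | minimum read fraction for a base to count as a valid subgenome base at an HSP position (validation and discovery) |
| `sbs_min_frac` | 0.30 | minimum read fraction supporting a diploid substitution for it to be kept |
| `min_diploid_coverage` | 3 reads | below this a diploid position is coded `<` (low coverage) rather than called |
| `ambiguous_min_frac` | 0.20 | a diploid position with ≥ 2 bases above this fraction is coded `*` (heterozygous/ambiguous) |
| `basepair_min_frac` | 0.05 | noise floor for base combinations at consecutive HSP positions (step 2) |
| `identity_min` | 0.50 | minimum fraction of informative positions matching a diploid for pattern assignment (step 4) and for the finalization recheck |
| `mode` | `max` | base election by single best pattern identity; `additive` sums identities over patterns carrying the base |
| `merge_enabled` | auto | pattern merging on exactly when a progenitor is missing; can be forced either way |
| `min_overlap` | 1 position | shared positions required to merge two agreeing patterns; raise for high ploidies where single-position overlaps could chimerize patterns |
| `mapq_min` | 20 | reads with mapping quality ≤ this are discarded |
| `gap_length` | 200 N | separator block after each sequence in a concatenated reference |

The validation/identity defaults (5 %, 30 %, 50 %, coverage ≥ 3, MAPQ ≤ 20
removed, 200-N gaps) are the published operating point of this family of
diploid-similarity methods; all are user-settable.

## Numerical choices

- **Exact thresholds.** Every "at least X %" rule is evaluated with
  `fractions.Fraction` built from the decimal string of the parameter, so
  5 of 100 reads is exactly 5 % and passes an ≥ 5 % rule on every platform.
  Pattern identities are stored as exact rationals (`100·matches/informative`),
  so step-5 ties are detected exactly rather than within a float tolerance.
- **Merging order.** Pairs are merged greedily by largest overlap; ties are
  broken by smaller leftmost start, then lexicographically smaller combined
  base string, making the merge order — and therefore the whole run — fully
  deterministic. The pairwise-overlap cache is updated incrementally per
  merge (O(n²) overall per gene rather than O(n³)).
- **Missing-subgenome score.** Patterns routed to the missing subgenome have
  no diploid identity, so their election score is 100 minus the best
  identity against any present diploid ("least like every known
  progenitor"). When every identity is undefined the pattern's read support
  is used instead, and such support-based scores are outranked by any
  identity-based score competing at the same position.
- **Multi-assignment.** A pattern reaching `identity_min` against several
  diploids joins all of them; the per-subgenome election arbitrates. The
  consistency sweep after each election pass removes a pattern outright if
  it conflicts with any elected base of any subgenome it joined.
- **Finalization only adds.** The step-6 loop (elimination + leftover
  recheck) never retracts an existing call; it iterates to a fixed point,
  which exists because the set of filled slots grows monotonically.
- **Degenerate inputs.** Empty HSP lists, empty VCF bodies, fragments
  covering no HSP, and positions absent from coverage tables all pass
  through without error (absent coverage ⇔ zero coverage). Mate-overlap
  positions where the two reads disagree are treated as uncovered in the
  fused fragment, and fragment-level counting keeps coverage denominators in
  the same unit as pattern support. Both election loops carry an iteration
  cap (100 passes) purely as a diagnostic guard; each pass either fixes the
  table or removes a pattern, so the cap is unreachable on sane inputs.
- **Reference construction.** One N-block follows *every* input sequence
  (n blocks for n sequences), so the separator total is exactly
  `n · gap_length`. Letters outside ACGTN are folded to N with a warning.
- **Tab round trip.** The fixed tab dialect carries positions, reference
  bases, diploid codes, assigned bases and the fully-characterized flag;
  the reader reconstructs exactly that content. Observed-base sets are not
  serialized and are not part of table equality on re-read.

## The simulator

`simulate_allopolyploid` emulates the data a real experiment would feed the
pipeline: an ancestral transcriptome (uniform ACGT), per-subgenome
substitution at rate `hsp_rate` per site (to a distinct uniform base),
diploid-vs-subgenome divergence at rate `diploid_divergence`, paired reads
at fixed per-subgenome coverage with Gaussian insert sizes and independent
per-base error. Reads are written as a genuine position-sorted SAM at their
true coordinates, so the pipeline's SAM reader, MAPQ/orphan/cross-gene
filters and mate fusion all run; no external aligner is involved. The HSP
and SBS input VCFs are *called from the simulated pileups* with naive
threshold rules (HSP: ≥ 2 bases at ≥ 5 % with ≥ 3 fragments; SBS: ≥ 80 %
majority differing from the reference), so the candidate lists contain the
false positives and dropouts that validation and discovery are there to
handle. Defaults (1 kb genes, 2×100 bp pairs, 300 ± 30 bp inserts, 30× per
subgenome, 0.2 % base error, 1 % subgenome divergence, 0.3 % diploid
divergence) describe a clean plant RNA-seq experiment.

What the simulator does **not** emulate — and what passing its tests
therefore cannot show — includes: mapping error and multi-mapping between
paralogs, expression-level variation between genes and between homeologs
(including silenced homeologs), intron structure and splice forms, indels,
quality-score variation along reads, and gene conversion or homeologous
exchange. Accuracy on real data will be bounded by those factors, chiefly
alignment quality; the simulation isolates the assignment algorithm itself.

## Scale of the bundled checks

The two headline experiments run at 200 genes × 1 kb (allotetraploid, one
progenitor withheld, ≈ 4,000 true HSPs, ≈ 8,000 scored assignments) and 150
genes × 1 kb × 3 subgenomes (allohexaploid, all progenitors, ≈ 12,500
scored assignments); each completes in under a minute of simulation plus
under half a minute of pipeline on one CPU. Unit and property tests use
small instances (≤ 12 genes) plus a fully hand-traced 1-gene/2-HSP/6-read
fixture whose expected call table is derived step by step in its docstring.

## Known limitations

- One missing progenitor at most; two unknowns would make the
  dissimilarity fallback ill-posed.
- Within-subgenome heterozygosity violates the single-haplotype-per-gene
  assumption; disable finalization and expect `*`-coded diploid positions
  to be uninformative.
- Single-base events only: indel HSPs and structural differences are out of
  scope, as is the alignment and variant-calling stage that produces the
  inputs.
- Patterns never cross gene boundaries, so genes with no or single HSPs
  yield only single-position patterns, which merging cannot extend; such
  positions rely entirely on diploid similarity and elimination.
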