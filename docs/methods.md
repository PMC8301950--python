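# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the simulator does and does not emulate, and the
known limitations.

## Read cleanup

Filters run in a fixed order so that removal classes are disjoint and
counts are conserved (`raw = clean + Σ removed`, asserted on every run):

1. mean Phred quality < 20 → `low_quality`;
2. 3′ adapter located (earliest prefix match, ≤ 1 mismatch, ≥ 12 nt
   overlap) and trimmed;
3. insert < 10 nt → `no_insert` (adapter dimers land here);
4. adenine fraction of the insert ≥ 0.8 → `polyA`;
5. insert outside 18–30 nt → `too_short` / `too_long`.

The quality and polyA thresholds are declared defaults, not inferred from
any instrument: sequencing-facility pipelines do not publish theirs. The
12-nt minimum adapter overlap keeps spurious matches inside random inserts
vanishingly rare, which makes cleaning idempotent on already-clean tags —
an invariant the test suite asserts. Cleaning is memoised per distinct
(sequence, quality) pair, because small-RNA libraries are dominated by
duplicate reads.

Tags are collapsed to one row per distinct sequence with per-library
counts; row order is total count descending, then lexicographic, so all
outputs are byte-reproducible. A second, stricter length window (18–24 nt)
is applied later, at genome mapping, keeping both length statistics
reportable.

## Contaminant removal

A tag is a contaminant iff it is contained end-to-end in a catalogue
sequence (either strand) with at most `max_mm` mismatches (default 0).
This replaces heuristic local alignment with a rule that a brute-force
window scan can verify exactly, which is what the tests do. When a tag
hits several records, the label follows rRNA > tRNA > snRNA > snoRNA >
repeat, then the smallest record id. E-value statistics and
covariance-model scanning are out of scope.

## Known miRNAs

Alignment is global, ungapped, equal-length Hamming distance ≤ 2.
Allowing gaps at zero cost alongside a 2-mismatch budget would make the
matching degenerate (any tag could align almost anywhere), so gap-free
matching is the package's documented reading of "free gaps" in
cross-species miRNA alignment.

The temporary database takes, per family, the member with the largest
total count of 0-mismatch tags (ties → lexicographically smallest id).
Basing representative choice on exact hits only keeps the two-phase
procedure non-circular with the final quantification, in which each tag
contributes its whole count to exactly one representative (fewest
mismatches, ties again by id) — no read is counted twice, and raising the
mismatch budget can only grow the recovered set (both properties are
tested).

Precursor validation folds candidate windows around every exact genomic
occurrence of the representative mature; a representative with no window
folding into a single-stem hairpin holding the mature in one arm is
flagged a pseudo-miRNA and excluded from differential testing. Matures
absent from the toy genome keep catalogue-only (cross-species) evidence
and remain valid — the focal species is assumed to be missing from the
catalogue, exactly the situation cross-species identification exists for.

## RNA folding

Two backends satisfy one contract (legal pairs only, non-crossing
brackets, energy ≤ 0 with 0 for the open chain):

* **ViennaRNA** (default): published nearest-neighbor parameters; used by
  the miRNA-calling stages.
* **Simplified stacking model**: additive pair strengths (GC −1.6,
  AU −0.55, GU −0.35 per pair, summed per stack), logarithmic hairpin
  penalties, linear bulge/internal penalties and affine multiloops. A
  single function scores *any* structure under this model; the backend's
  Zuker-style O(n⁴) dynamic program minimises exactly that function.

The split exists for testability: the simplified model admits an
independent optimality oracle. Enumerating all non-crossing pairings is
exponential — random 40-mers reach 10⁸–10⁹ structures — so the oracle is
applied exhaustively wherever a counting DP certifies the structure space
small enough to enumerate (≤ 1.5 × 10⁵ structures; roughly all sequences
up to ~30 nt), and against a large uniform sample of structures (drawn by
unranking against the counting DP) beyond that. The interior-loop size in
the DP is capped at 30 unpaired bases; on ≤ 40-nt sequences a larger loop
costs more than any stabilisation the leftover ≤ 7 nt could provide, so
the cap cannot exclude an optimum there.

### Duplex geometry

For a single-stem hairpin, the mature lies "in one arm" when it has at
least one paired base, all its pairs reach the opposite arm, and it does
not intrude into the other arm's paired region (loop-side overhang is
allowed). The miRNA/miRNA\* overhang check is structural:

* at the loop-side end, the overhang is the number of mature bases past
  the mature's outermost pair;
* at the base-side end the star's 3′ tail is not directly observable, so
  the star is taken to extend up to 2 nt past its last pair *provided
  those bases are unpaired* (a paired continuation leaves no room for an
  overhang), plus any unpaired mature lead-in that shifts the register.

A canonical Dicer duplex yields (2, 2); blunt and shifted duplexes fail on
at least one side. This rule assumes precursors without a long lower stem
below the duplex — true of the simulator's compact precursors and stated
here as a scope limit for genomic data.

Duplex defects are measured between consecutive mature pairs: unpaired
bases on one side only form a bulge; on both sides an internal loop whose
size is the larger side.

## Novel-miRNA criteria

A locus is accepted when all six verdicts hold: single-stem hairpin;
mature in one arm; overhangs exactly 2/2 (a tolerance switch exists but
defaults to strict); largest internal loop ≤ 5 and bulge ≤ 4; folding
energy ≤ −18 kcal·mol⁻¹ (inclusive, so a hairpin at exactly −18 passes);
and ≥ 5 supporting reads summed across libraries (a multi-locus tag is
counted once — one molecule, one count). Verdicts that cannot be
evaluated cascade to "not evaluable" rather than failure: without a
hairpin there are no arms, no duplex and no hairpin energy. This makes
the verdict matrix diagnostic — each simulated negative control fails
exactly one criterion.

Candidate windows step outward from the mapped tag by 15 nt up to 60 nt
per side (25 windows per locus), sized to the compact precursors the
simulator plants; both numbers are parameters and should be widened
(e.g., to ±250) for genomic precursors with long lower stems. Among
accepted windows the lowest folding energy represents the locus; when no
window is accepted, the most informative window — fewest failed criteria,
then fewest unevaluable ones, then lowest energy — is reported for
diagnosis. Overlapping mapped loci merge into clusters represented by
their highest-count tag; accepted calls are numbered `novel_mir_N` in
descending total count.

## Differential expression

Counts of validated known plus accepted novel miRNAs are normalised to
counts per million of the miRNA-assigned total per library (columns sum to
10⁶ exactly). Fold change uses a 0.01-CPM pseudocount so that miRNAs
absent from one condition still yield finite log-ratios. Significance is
a two-sided equal-variance Student *t*-test on CPM replicates; degenerate
cells are made deterministic (all values identical → p = 1; zero
within-group variance with different means → p = 0). The DEM gate is
|log₂FC| > 1 *and* p < 0.05 on raw p-values — the conventional gate for
3v3 small-RNA designs — with BH q-values reported alongside, not used for
gating. Swapping the condition order negates every log₂FC and preserves
p-values (tested).

A caution surfaced by the test design: CPM normalisation removes any
effect shared by the whole population, so operating characteristics are
only meaningful when effects are planted in a subset of a mostly-null
population, which is how both the simulator and the acceptance checks are
built. Under the default conditions (negative-binomial counts, dispersion
0.1, effect |log₂FC| = 2 at abundances drawn log-uniformly from
[50, 2000], 3v3) the measured power is ≈ 0.85 and the null rate ≈ 0.05;
power at the boundary abundance of exactly 50 is intrinsically close to
0.8 for a t-test at this sample size.

## Target prediction

The expectation score is computed by a semiglobal affine-gap
Gotoh dynamic program (target ends free, miRNA fully consumed): perfect
pairs 0, G:U 0.5, other substitutions 1, gaps 2 + 1/nt; substitution and
miRNA-side gap costs are doubled at seed positions 2–7 (target-insertion
gaps keep their base cost, since they sit between miRNA positions).
Scoring requires a site of at least the HSP length (19 nt). Transcript
scanning pre-screens with an exhaustive vectorised ungapped scan at
cutoff + gap allowance — sufficient because two gap openings already cost
more than the cutoff — then refines candidates with the gapped DP and
selects non-overlapping sites greedily, best score first, leftmost on
ties. The cutoff is inclusive (score ≤ 3 reported).

Mode classification: *translation inhibition* iff the duplex is disrupted
(mismatch or gap) at miRNA positions 10–11, the standard plant cleavage
site; a central G:U still pairs and therefore stays *cleavage*. Both the
central positions and the seed interval are configurable.

## Enrichment

Exact hypergeometric upper tail P(X ≥ k) per term with k ≥ 1 selected
genes; the background defaults to all annotated genes (configurable).
BH adjustment is applied within each namespace (BP/CC/MF/pathway), since
term families are tested as separate hypotheses families. No ontology
ancestor propagation is performed. Networks: term–term edges weight the
shared member genes; miRNA–term edges connect a miRNA to terms containing
its targets, carrying the DEM direction as a node attribute.

## qPCR

Technical replicates are averaged on the Ct scale per biological
replicate (conventional Livak usage); ΔCt subtracts the reference assay
within each sample, ΔΔCt subtracts the mean calibrator-condition ΔCt, and
relative expression is 2^−ΔΔCt per biological replicate (geometric-mean
calibrator normalisation: the calibrator's mean log₂ expression is 0
exactly). Amplification-efficiency correction is out of scope. Pearson
correlation between a miRNA and a target uses paired condition means —
the only pairing the design provides — and reports r and r² with the
sign separating inverse from positive modules; an extra rescue condition
(`LT+cPTIO`) is supported as a plain condition label.

## The simulator

What it emulates: library composition (junk classes at configurable
fractions, contaminant fragments, a 24-nt-dominant background with a
21-nt shoulder), negative-binomial tag counts (Poisson as dispersion → 0)
with per-condition multipliers cycling through null / single-treatment /
co-regulated / discordant / near-threshold patterns, miRNA family
structure with unexpressed paralogues, hairpin loci on both genomic
strands, decoy loci, target sites engineered to exact scores and modes,
an annotation with one designed enriched term (80 % coverage of the
target set vs 5 % background), and Ct tables consistent with the planted
fold changes (targets inverse to their miRNA, one designed positive
pair; the rescue condition halves the LT effect on the log₂ scale).

Every planted locus is built as a *cassette* — 150-nt unstructured A/C
spacers around the oriented precursor — and verified at design time by
running the actual novel-caller evaluation on that cassette; designs are
redrawn deterministically until planted hairpins pass all criteria and
each decoy fails exactly its designated one. In-situ verification
matters: the reverse complement of an A/C spacer is G/T-rich and can
wobble-pair, so a minus-strand locus sees a different folding context
than a plus-strand one. The canonical precursor is mature + 8-nt loop +
star with built-in 2-nt 3′ overhang geometry; decoys modify exactly one
property (no pairable context; mature inside a large loop; blunt duplex;
6-nt star-arm bulge; stem weakened by spaced 1×1 mismatches into the
(−18, 0) energy band; fixed 4-read support).

What it does not emulate: sequencing error profiles (quality is constant
per read class), isomiR heterogeneity, RNA degradation, genome-scale
repeat structure, adapter chemistry beyond a single configurable 3′
adapter, or real database content — the catalogues are toys, and
database-version-dependent quantities (absolute miRNA/term counts of any
real study) are deliberately out of reach. Passing tests therefore
demonstrate the correctness of the computational chain on data whose
generative model is known, not the biological accuracy of any particular
threshold on real libraries.

Default scale (the study conditions): 3 conditions × 3 replicates ×
10⁵ reads; 30 planted known + 15 novel miRNAs + 6 decoys on a 30-kb
genome; 2000 background tags (15 % genome-mapped); junk fractions
0.05/0.05/0.05/0.10; dispersion 0.1; effect size |log₂FC| = 2; 60
transcripts of 500 nt. Known abundances are log-uniform on [50, 2000]
reads per library, novel on [20, 200] — mirroring the observation that
novel miRNAs are expressed well below conserved ones.

## Limitations

* The overhang rule presumes compact precursors (no long lower stem); on
  genomic pre-miRNAs the base-side check can reject valid loci.
* The ±60-nt window default is matched to the simulator's precursor
  scale, not to genomic precursors.
* Hamming-based contaminant and known-miRNA matching ignores indels.
* The simplified stacking energy model is for validation, not
  thermodynamic accuracy; use the ViennaRNA backend for any sequence of
  interest.
* Target prediction does not model site accessibility or conservation.
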