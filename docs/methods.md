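# Methods

## The measurement problem

A SINE rescue assay recovers each new Alu insertion together with its empty
(pre-insertion) locus. Sequence comparison of the pair identifies the
hallmarks of L1-mediated target-primed reverse transcription (TPRT): a target
site resembling the 5′-TTTT/AA-3′ endonuclease consensus, a flanking direct
repeat (target-site duplication, TSD), an intact or 5′-truncated element
body, and a 3′ A-rich tail. Because the assay constructs carry engineered
non-adenosine "disruptions" inside the A-tail, the recovered tail sequence
also encodes where reverse transcription primed and how the tail changed
length during copying. `sinetrace` implements the simulation of this process
and the inverse inference, plus the placement statistics used to describe
where inserts land.

## Construct model

A tail template is an ordered list of poly(A) segment lengths with
disruption strings between consecutive segments. Built-ins:

| name | segments | disruptions | rendered |
|------|----------|-------------|----------|
| A70D | 17, 18, 17, 18 | CATTAC, G, CACAC | 82 nt |
| A30D | 10, 10, 10 | CT, TAC | 35 nt |

The A70D segment order is a convention: the construct fixes only the
per-segment range (17 or 18 adenosines, 70 total) and the 82-nt rendered
length; `[17, 18, 17, 18]` is the default and is configurable, as are
user templates from YAML (so other tagged SINEs — B2, BC1 — can be
analyzed).

The bundled construct body is a **synthetic** Alu-like sequence (275 nt,
deterministic, labelled as such in `construct.py`): two arms joined by a
single internal A-run, starting with a non-A base. It reproduces the
architecture the pipeline relies on (anchorable 3′ end, a unique A-rich
middle for mismatch masking) without reproducing any real element. The
masked A-rich middle defaults to the longest internal A-run of ≥6 nt;
explicit coordinates override it.

## TPRT simulator

**Site choice.** A plus-orientation site is a cut position whose bottom
strand reads TTTT/AA across the cut (top strand TT|AAAA); minus sites
mirror it. Sites are scored 0–6 by consensus matches and drawn with
probability proportional to score; the default generator uses perfect sites
only.

**Priming.** The priming point `q` (cDNA prefix length) is uniform over
positions that (a) are at least `min_prime_offset` (default 20 nt,
reflecting the observed absence of priming in the tail's 5′-most ~20 nt; the
sources quote 20–25 nt, so the cutoff is a parameter) from the tail's 5′ end
and (b) fall inside a poly(A) segment — a T-rich genomic primer anneals to
adenosine runs, not to single A's inside a disruption. The realized tail is
the template *prefix* `rendered[:q]`: internal priming truncates the tail's
3′ end, which is what makes "type C" tails (first disruption only) and short
terminal segments possible.

**Slippage.** Before each incorporated nucleotide the nascent cDNA
dissociates with probability `p₀·exp(−L/λ)` where `L` is the current cDNA
length. A slip re-anneals 3′-ward on the RNA with probability `p_duplicate`
(recopying template positions — expansion) or 5′-ward (skipping — deletion),
by a span drawn geometric(mean 3, truncated at 10). A slip whose span would
cross a disruption is truncated to the homopolymer run except with
probability `p_cross_disruption`: out-of-register re-annealing requires the
homopolymer, which is what keeps duplicated-disruption events rare while
letting every segment expand.

Defaults: `p₀ = 0.4`, `λ = 80`, `p_duplicate = 0.9`,
`p_cross_disruption = 0.05`. These were calibrated once so that simulated
A70D cohorts reproduce the observed expansion pattern — terminal-segment
median ≈ 42–45 A's vs parental 17–18, internal medians in the low-to-mid
20s, roughly one in five terminal segments contracted, and ~5% of tails
carrying a duplicated disruption. The exponential-decay form expresses
"stability grows as the cDNA lengthens"; the decay is deliberately slow so
that internal segments still expand, as observed. A30D cohorts under the
same parameters expand somewhat less at the terminal segment than reported;
the calibration privileges the larger A70D data set.

**Integration.** For an observable TSD of `k` nt the duplicated genomic
region is `k` plus the adenosine run abutting the cut (at a perfect site,
the AA·· of the consensus): under the tail-first junction convention those
adenosines are indistinguishable from tail sequence, so the generator
records them as tail and starts the observable TSD at the first non-A base.
TSD lengths default to uniform 5–27 nt; 5′ truncation occurs with
probability 0.035 (uniform length). Atypical events: *chimeric* events join
a flanking genomic Alu's 5′ portion to the construct's homologous 3′ portion
(no TSD, optional flank deletion); *endonuclease-independent* events insert
bluntly at a sub-threshold site (no TSD).

**Observability guards.** The generator refuses configurations that no
sequence-based method could resolve, because for such events "ground truth"
is not an observable: a truncation point whose neighboring body base equals
the last TSD base (junction register ambiguous), a realized tail ending in T
(collides with the TT of the consensus at the 3′ junction), and blunt
insertions with a chance junction repeat of ≥5 bp. Each guard redraws the
event; all are rare and none changes the modelled distributions materially.

## Hallmark characterization

The construct body is anchored in the post locus by an exact 20-nt seed from
its 3′ end (both strands tried; minus-strand records are analyzed in the
reverse-complemented frame throughout), then extended 5′-ward to measure
truncation; isolated substitutions are tolerated when the preceding 8 bases
confirm the register, which lets the mismatch scan count point mutations
without losing the anchor, while divergent genomic Alu copies (chimeras)
stop the extension near the recombination breakpoint.

The TSD is the longest L ≤ 50 for which the L bases immediately 5′ of the
insert are genomic and the post locus resumes the pre locus at the matching
downstream offset — i.e. the repeat is anchored at both junctions. Shared
junction adenosines go to the tail first (default) or to the TSD
(`a_assignment="tsd"`); both conventions are implemented because the
sequence cannot decide. The cleavage point is estimated by walking 5′ from
the TSD start across the junction A-run, making endonuclease-site scoring
convention-independent; both orientations are scored and the better
reported.

Classes: `TPRT_typical` = TSD ≥ 5 bp and site score ≥ 4/6;
`chimeric_recombination` = no TSD and an insert 5′ region of ≥30 nt with
≥90% identity (edlib) to an annotated flanking Alu, better than its match to
the construct; `endonuclease_independent` = no TSD, no chimerism,
sub-threshold site. Conflicting evidence yields `ambiguous` with reasons.
The 4/6 score threshold and the 90%/30-nt chimera rule are package choices
where the underlying descriptions are qualitative.

Body mismatches are counted between the anchored insert and the construct
body with the A-rich middle masked; the rate divides by analyzed bases.
Genic context intersects insertion points with gene models (CDS > UTR >
intron precedence), and the cohort sense/antisense split is tested binomially
against a configurable null (0.5 by default; 0.45 mirrors the genomic
intronic background). With 47 sense / 83 antisense genic inserts the
two-sided p is ≈ 0.002.

## A-tail segmentation

Observed tails are parsed greedily left-to-right: maximal A-runs become
segments; at each non-A position the parser aligns, as a whole string, the
next expected template disruption (skipping lost ones; ≤1 substitution
tolerated, never for 1-nt disruptions), else an already-consumed disruption
— recorded as a duplication event; duplicated copies must match exactly,
because a short fuzzy match is far likelier to be slip debris than a mutated
duplicate. Unmatched stretches are flagged and the parse continues. Insert
type is A, B, C, … by the highest-index disruption retained (D = pure
homopolymer for A70D); the terminal (priming) segment is the last observed
one, and a terminal segment shorter than parental implies internal priming
within it.

Cohort summaries report internal/terminal medians and quartiles, expansion
fractions (≥4 A's, and the alternative ≥40%-of-parental marker), the priming
histogram with a chi-square goodness of fit against priming ∝ eligible
segment length (positions inside the 20-nt exclusion contribute nothing;
zero-eligibility segments merge into the next), contracted-terminal and
duplicated-disruption counts, and a Mann-Whitney U test of internal vs
terminal lengths. The U statistic uses midranks, an exhaustive-enumeration
exact p for pooled n ≤ 10 (correct under ties), and a tie-corrected normal
approximation with continuity correction otherwise.

## Placement statistics

The karyotype-weighted placement maps each copy-number region to
`width × copy_number` consecutive integers (only relative weights matter, so
ploidy is not normalized), samples integers uniformly, and maps back to
inter-base positions. Flank summaries report mean %G+C and per-family
repeat coverage over flanks of 20 kb total (half per side, clipped at
chromosome ends with realized-length denominators).

Window enrichment assigns inserts to non-overlapping tiling windows
(fixture default 10 kb, standing in for 1-Mb genome windows; all logic is
size-parameterized) and compares insert-containing vs insert-free windows
per feature with the Mann-Whitney-Wilcoxon U. Empirical p-values come from
label permutations preserving class sizes with add-one smoothing
`(1+b)/(1+B)`; "as or more extreme" is defined on U centered at its null
mean, with ties extreme. Bonferroni uses the number of features tested.
The instability 13-mer CCNCCNTNNCCNC is counted with overlaps on both
strands by default (hotspot biology is strand-symmetric); single-strand
counting is available.

## Synthetic data: what it emulates and what it does not

The fixture genome (default two chromosomes of 200 + 150 kb, GC 0.41)
plants non-overlapping repeat intervals at genome-like densities (Alu 10.6%,
L1 16.9%, L2 3.2%, MIR 2.5%, MaLR 3.6%), genes with
UTR/CDS/intron substructure at 30% coverage, conserved elements, and extra
perfect consensus sites; background base composition is adjusted for the
planted Alu sequence so realized GC hits the target. Planted Alu copies are
divergent (15% substitutions, plus forced differences in every 20-mer) so
exact-seed anchoring can never land on them, yet chimera detection finds
them at ≥90% identity. Annotation is truth by construction — the pipeline
intersects intervals rather than rediscovering repeats.

Cohorts default to the observed class mix (96.5% typical / 2.7% chimeric /
0.8% endonuclease-independent at n = 226) and driver mix (178 ORF2 : 48 L1).
What passing tests show: the inference recovers the generative truth exactly
under the stated conventions, and the statistics behave as designed. What
they do not show: performance on real sequencing artifacts (indels, chimeric
reads, low-complexity miscalls), real repeat landscapes, or hg-scale window
features; the fixture's window feature values are not comparable to genome
values.

## Numerical and procedural choices

- Priming-location and per-segment truth are compared against parses only
  for slippage-free cohorts: once slips can land inside disruptions, the
  string record genuinely underdetermines the event, and the parser follows
  the disruption-presence rule the data support.
- Exact Mann-Whitney enumeration switches on at pooled n ≤ 10; permutation
  tests warn below 100 permutations.
- Chi-square goodness of fit drops to a warning (None) when fewer than two
  categories have eligible mass.
- All randomness flows from `numpy.random.default_rng` seeds; fixed seed ⇒
  byte-identical FASTA/TSV outputs.
- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive.

## Known limitations

- Untemplated nucleotide addition at the RNA 3′ end is not simulated.
- The slippage calibration targets the A70D cohort; A30D terminal expansion
  is under-reproduced.
- Chimeric truncation estimates are approximate (the homologous junction is
  ambiguous by construction); only the class call is asserted.
- The priming goodness-of-fit on simulated cohorts tests the *observable*
  terminal-segment distribution, which slippage distorts away from the
  uniform priming null even when priming is uniform.
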