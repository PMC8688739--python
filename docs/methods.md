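# Methods

## Clonotypes, counts and keys

A clonotype is a unique TCRβ rearrangement. Two definitions are in common
use and both are supported: the nucleotide-level key (CDR3 nucleotide
sequence + V family + J gene), which separates synonymous rearrangements,
and the amino-acid key (CDR3 AA + V + J), under which convergent
rearrangements merge. A CDR3-AA-only key is available for permissive
cross-sample matching. The amino-acid key is the default for all
cross-sample work (sharing, tracking, Venn counts) because convergent
rearrangements encode the same receptor; the nucleotide key remains the
right choice for within-sample diversity of rearrangement events. The D
segment is frequently unresolvable and never participates in keys; it is
carried as a label (`D-unresolved` when absent).

The abundance unit is the **template count** — the platform's bias-corrected
estimate of input molecules, a proxy for cell numbers. Frequencies are
always derived from counts at access time and never stored separately, so
they cannot drift from the counts. Non-productive rearrangements
(out-of-frame or containing stop codons) are removed before any statistic is
computed; zero-template rows are retained at parse time (so files round-trip
faithfully) but dropped at collapse time because they carry no frequency
mass.

Segment labels differ between platforms (`TCRBV26-01*01`) and IMGT
(`TRBV26`); both normalise to family-level tokens (`V26`, `J2-7`, `D1`) via
a pattern rule plus an extensible override table
(`src/clonetrace/data/segment_map.yaml`). Unrecognised labels pass through
verbatim with a warning rather than failing the run.

## Diversity statistics

For clone frequencies *p₁…p_N* (base-2 logs throughout):

* Shannon entropy *H = −Σ pᵢ log₂ pᵢ* (bits). Zero entries are excluded.
* **Clonality** = 1 − *H*/log₂ *N*. The evenness ratio *H*/log₂ *N* is often
  itself called "normalised entropy"; clonality is its complement so that
  higher values mean more clonal expansion. Both are exposed
  (`clonality`, `evenness`). Clonality is invariant to the log base.
  Degenerate case: a single-clone repertoire has log₂ *N* = 0; clonality is
  defined as 1 (maximal expansion). Exactly uniform counts return exactly
  0 (detected by an integer-equality check, so no floating-point residue).
* **R20**: sort clones by descending count; the smallest *k* whose
  cumulative frequency reaches 20% (inclusive threshold, whole clones, no
  interpolation) gives R20 = *k*/*N*. Uniform repertoires give 0.2 (for
  *N* divisible by 5); values far below 0.2 indicate a few dominant clones.
  A 10⁻¹² tolerance guards the ≥ comparison against rounding at exact
  boundaries.
* Top-N cumulative frequency: template-mass share of the N most abundant
  clones. Ties at the N boundary cannot change the sum (tied clones carry
  equal frequency).

## Pairwise comparison

* **Shared clone count**: cardinality of the key intersection.
* **Overlap metric**: with *S* the shared key set, *f_A* = (templates of
  *S* in A)/(total A) and *f_B* likewise; the statistic is (*f_A*+*f_B*)/2.
  It is 1 iff the key sets coincide and 0 iff they are disjoint.
* **JSD**: frequency vectors *x*, *y* on the union of keys (absent clones
  at 0); JSD = *H*((x+y)/2) − (*H*(x)+*H*(y))/2 with base-2 logs. This is
  the only formulation that makes the advertised endpoints exact: 0 for
  identical distributions and 1 for disjoint supports. (A literal
  "sum of entropies divided by entropy of the summed vector" ratio does not
  stay in [0, 1] and is not implemented.) Disjoint supports short-circuit
  to exactly 1.0; identical inputs yield exactly 0.0 because the mixture
  vector is bitwise equal to the inputs. Results are clamped to [0, 1]
  against ~10⁻¹⁶ rounding.

Pairwise matrices order samples deterministically by tissue (blood, spleen,
pLN, mLN, liver, lung, gut, skin, graft), then mouse, then day. Venn
regions are reported for 2–4 samples as `&`-joined sample-id labels; region
counts always sum to the union size.

## Ranking and tracing

Clone ranks use a stable sort: templates descending, then CDR3 AA, V, J
ascending. The tie rule is arbitrary but fixed, so rank tables and
heatmaps are reproducible across runs and input orderings. A queried clone
absent from a target sample gets an explicit absent marker (`None` in the
API, `NA` in tables), never a pseudo-rank.

Donor trace-back reports, for each recipient top clone, its template count
and frequency in the pre-transplant graft sample; "detectable" means ≥1
template — no pseudo-counts and no abundance threshold, so detectability at
a given graft sampling depth is a statement about sampling, not biology.

Cross-recipient sharing: a clone qualifies when it lies within the top-k of
every mouse. The default membership pools each mouse's tissues (summed
counts) before ranking, matching a per-mouse top-k framing; `any`/`every`
per-sample modes are provided. With k = ∞ the operation reduces to plain
key-set intersection. Group-level combined top clones pool template counts
across samples (robust to unequal depths); a mean-of-frequencies weighting
is available via a flag.

## Gene usage and statistics

Usage of segment *g* is the summed template frequency of clones labelled
*g* — abundance-weighted, so one expanded clone moves its whole family. A
unique-clone weighting exists for exploration. Group comparisons run a
two-tailed unpaired Student's t-test (equal variances) per segment;
`anova_sidak` applies the Šidák family-wise correction
*p̃ = 1 − (1 − p)^m* over the *m* segments of the family (statsmodels).
When both groups have zero variance the t statistic is undefined: equal
means report p = 1 with a warning, unequal means p = 0. Significance is
judged on the adjusted p at α = 0.05.

## The simulator

The generator reproduces the statistical structure the analysis assumes,
with the latent truth exposed for parameter-recovery tests.

**Donor pool.** `n_clones` = 50,000 clones with frequencies ∝ rank^(−α),
α = `zipf_alpha` = 1.3 (α = 0 gives a uniform pool). CDR3s are `C` +
8–16 uniform residues + `F`; nucleotide sequences are a fixed codon
back-translation (so NT and AA keys coincide on simulated data — convergent
recombination is not modelled). V families follow a fixed baseline usage
table; J and D likewise. A fraction `allo_fraction` = 0.005 of clones is
flagged alloreactive, sampled without replacement with probability ∝ rank —
i.e. preferentially from the low-frequency tail — and draws its V family
from a V26-enriched distribution (`v26_bias` = 10 multiplies the baseline
V26 probability of 0.04, capped at 0.9). Tail placement is what makes the
expanded clones usually undetectable in a finite graft sample: the same
clone universe, insufficient sampling depth.

**Recipients.** Allogeneic: `activated_per_recipient` = 50 alloreactive
clones are chosen per recipient (independently, so dominants are
recipient-private) and multiplied by lognormal factors with natural-log
mean 12 and sd 2, then renormalised. The median multiplier e¹² ≈ 1.6·10⁵
carries a tail clone of frequency ~10⁻⁶ into the percent range — the
magnitude implied by top clones at 2.5–15% that sit at ≤0.015% in the
graft. The sd of 2 spreads the multipliers over ~2 orders of magnitude so
a handful of clones dominates each recipient, which is what raises
clonality above the (already skewed) syngeneic baseline. Syngeneic
recipients get mild Dirichlet jitter of the pool frequencies
(concentration `recipient_jitter_tau` · p, τ = 2·10⁵). Each tissue then
draws a Dirichlet-perturbed copy of the recipient distribution
(`tissue_dirichlet_tau` = 2·10⁴) and a multinomial template sample:
30,000 templates for lymphoid compartments (blood, spleen, pLN, mLN) and
10,000 for parenchymal organs (liver, lung, gut, skin). The pre-transplant
graft sample draws 20,000 templates from the unmodified pool. An optional
day-14 time point reuses the day-7 activation draw with the multiplier
compounded by e^1.5, which raises within-recipient cross-tissue overlap
over time without new mechanisms.

**What the generator does not emulate.** No V(D)J generation-probability
model, no sequencing error, no convergent recombination, no clock — so
passing tests demonstrate that the pipeline recovers planted statistical
structure (expansion, privacy, tail origin, V26 bias), not that it
reproduces any particular biological dataset. In particular, a desk-scale
pool of 5·10⁴ clones with a rank^(−1.3) law concentrates ~27% of mass on
the top clone; real naive repertoires are vastly larger and flatter, so
absolute values of clonality or cross-recipient sharing are not comparable
to sequenced data — only the allo-vs-syn directions are.

**Free parameters.** The expansion magnitude (log-mean 12, log-sd 2) and
`v26_bias` = 10 are not identified by any external measurement; they were
fixed once, by a small pilot sweep, to the weakest values that reproduce
all directional contrasts robustly, and are documented here as the
package's study conditions.

## Determinism and problem sizes

All randomness flows from a single seed through spawned child streams
(`numpy.random.SeedSequence`), so every simulated table, report bundle and
test is reproducible byte-for-byte. The test suite exercises the
directional contrasts at the full default configuration over 50 seeds
(~3 minutes) and uses reduced configurations (3,000-clone pools,
1,500–3,000-template samples) for integration smoke tests; the acceptance
script runs desk-scale inputs (50–1,000 clones) chosen so each endpoint is
exact by construction.

## Known limitations

* Sharing is exact-key only; no sequence-similarity clustering of
  near-identical clones.
* No rarefaction or richness estimation; unique-clone counts are compared
  at equal sampling depth instead.
* The per-segment t-test + Šidák procedure treats tissues of the same mouse
  as independent replicates when whole groups are compared; a mixed-model
  treatment of the tissue × group design is out of scope.
* `venn_regions` supports 2–4 sets (the practical plotting range).
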