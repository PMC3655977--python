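# Methods

## Statistical model

All three analyses share one inferential scheme: an observed ratio
statistic is compared with a Monte Carlo null that randomises exactly one
ingredient while holding every chromosome arm's composition fixed.
Stratifying by arm matters because arm identity confounds everything the
analyses touch — CNP density, OL sizes, and the distribution of
gonad-specific genes all differ between arms — so unrestricted shuffles
would mistake arm effects for the contrast of interest.

Empirical tails are tie-inclusive plain fractions over the valid
replicates: `P_upper = #{null ≥ observed}/R_valid` and `P_lower = #{null ≤
observed}/R_valid`, so `P_upper + P_lower ≥ 1` when no replicate is
invalid.  No pseudo-count correction is applied by default (it exists
behind `add_pseudocount=True` as a sensitivity option), and no
multiple-testing correction is applied across the three stability
definitions or the several tests: each cell of the report is a raw
empirical p-value.  Floating-point ties are compared exactly; the
statistics are ratios of small-integer arithmetic in which exact ties are
meaningful and frequent on small inputs.

### Stage 1 — CNP enrichment in lamina-associated domains

A CNP "hits" an OL iff at least one of its two end coordinates lies
within the OL interval.  This endpoint rule is deliberate and literal: a
CNP fully covering an OL with both ends outside does *not* count.  The
rule makes *x* a count of CNPs (never endpoints — a CNP with both ends in
one OL counts once; one straddling two OLs counts in both), and an
any-overlap variant is available as `mode="overlap"` for sensitivity
analysis.  Kind-filtered runs (deletions-only, duplications-only) filter
both the per-OL count *x* and the arm normaliser *X* to the same event
class, so arm-level differences in deletion vs duplication rates cannot
leak into the contrast.

The statistic averages `(x/X)/A` over Lam OLs and divides by the same
average over non-Lam OLs.  Dividing by *X* removes arm-level CNP density;
dividing by *A* removes OL size; the ratio of class means is therefore a
per-base-pair, arm-adjusted enrichment.  It is scale-invariant in OL
lengths and inverts exactly under swapping the class labels.  OLs sitting
on an arm with zero kind-filtered CNPs have an undefined `x/X`; they are
dropped from both sums (with the class sizes L/nL adjusted and a logged
warning) — the only division-safe treatment.  A replicate whose non-Lam
mean is zero has an undefined ratio; such replicates are excluded from
both tails and reported in `n_invalid` rather than coerced to a value.

The null redraws each CNP's start uniformly on `[0, arm_length −
cnp_length]`, keeping arm, length and kind.  Relocated CNPs may overlap
one another and their original positions: the null models independent
placement, not a packing.

### Stage 2 — breakpoints around germ-line-accessible genes

Breakpoints per gene are the sum of the pre-computed left- and right-flank
rearrangement-breakpoint counts for the active stability definition; genes
lacking annotation under that definition are excluded from both the
observed statistic and the null (logged).  The null shuffles gonadal tags
uniformly within each arm over **all** OL genes of the arm, preserving
each arm's (ovary, testis, untagged) count vector.  The all-genes universe
is the default because the question is whether tagged genes differ from
the arm-matched genomic background; a `tagged-only` universe (shuffling
labels only among tagged genes) is available for sensitivity analysis.
One documented consequence, asserted by a test: the breakpoint counts of
untagged genes shape the null, because shuffled tags can land on them.
Alongside the ratio, the per-class means No/O and Nt/T are reported
against the same null sample, so a significant ratio can be attributed to
ovary excess, testis depletion, or both.

### Stage 3 — synteny classes and expression bias

Class assignment precedence: (1) a nested gene is always bisyntenic, even
if it also hosts others; (2) a host gene with both flanks changed is
unisyntenic; (3) both flanks changed → singleton; (4) exactly one →
unisyntenic; (5) neither → bisyntenic.  Only direct nesting links are
consulted.  Untagged genes never enter the 3×2 table but do participate in
the permutation universe.

The trend test is the Cochran-Armitage chi-square with equally spaced
scores (0, 1, 2) on singleton < unisyntenic < bisyntenic and no continuity
correction; both choices are pinned down by the published values the test
suite asserts (89.35 / 73.13 / 22.56).  The statistic is invariant under
affine score changes, reduces to the Pearson chi-square on two-row tables,
and is cross-checked in the tests against the independent linear-by-linear
statistic ((N−1)·r², rescaled by N/(N−1)).  Per-class ratios
`(no/No)/(nt/Nt)` use the global tagged totals as the baseline; a class
with zero testis genes in a replicate is undefined for that replicate and
counted in `n_invalid` (an observed zero causes the class to be omitted,
with a warning, rather than faked).

## Coordinates and I/O

Input and output TSV tables are 1-based inclusive; memory is 0-based
half-open, so `length = end − start` everywhere and the file ↔ object
round trip is the identity.  Strand is ignored throughout: no analysis
uses orientation (orientation enters only through the upstream GOO
annotation, which arrives pre-computed).  OLs with no genes are rejected
at read time, overlapping OLs within one definition are reported as
errors rather than silently merged, and `hosts` links are derived from
`nested_in` so the nesting relation cannot be inconsistent.

## Synthetic data generator

The generator emulates the structure of the real inputs at a reduced,
fast-to-simulate scale; it does not attempt to match *D. melanogaster*'s
actual arm lengths, OL counts, or microarray noise.  Defaults (the
standard conditions of the package's experiments):

| parameter | default | rationale |
|---|---|---|
| arms × length | 5 × 2 Mb | several strata, ~1/10 scale of a fly arm |
| OLs per arm | 30, non-overlapping | log-normal lengths, median 20 kb |
| Lam fraction | 0.25 | Lam OL median doubled (40 kb): LADs are long |
| genes per OL | 3–8, tiled | ~800 genes per genome |
| tag fractions | ovary 0.10, testis 0.20 | testis-specific genes are the larger class |
| CNPs | 400, half deletions | log-normal lengths, median 2 kb |
| breakpoint rate μ | 0.5 per flank (Poisson) | keeps bisyntenic the largest class |
| flank change rate | 0.10 | extra changes beyond breakpoint-implied ones |
| nested fraction | 0.05 | nested genes exercise the class precedence |
| probe noise | 0.01 per call | classifier concordance stays ≥ 99% |

`SyntheticConfig.small()` is a reduced preset (3 arms × 0.8 Mb, 12 OLs per
arm, 200 CNPs, ~160 genes) used for experiments that need hundreds of
independent bundles.

Effects are planted mechanistically, not by relabelling outputs:
deletions are placed by rejection sampling with acceptance weight λ when
the proposed position hits a Lam OL (so the per-bp deletion hit rate in
Lam OLs scales by λ); testis-specific genes draw flank breakpoints at
Poisson rate θμ; and bisyntenic genes (under the first configured
definition) re-draw their tag with testis odds multiplied by β.  λ = θ =
β = 1 is the exchangeable null regime.  Flank-change flags are coupled to
breakpoint counts (breakpoints imply change) for internal consistency —
a generator choice, made so the two annotations can never contradict each
other.  Probe calls are emitted from the intended tag (ovary-specific:
4/4 ovary presents, 0/4 testis; untagged: broadly present in both gonads)
with independent per-call flip noise, so the expression classifier
reproduces the intended tags on ≥ 99% of genes rather than by
construction.

Because β re-draws tags after θ-dependent breakpoints were drawn, the two
dials are meant to be used one at a time; all shipped experiments do so.

What passing tests on synthetic data do **not** show: the generator's OLs
are independent and uniformly scattered, CNP lengths are i.i.d.
log-normal, and expression calls have no probe-level structure — real
genomes violate all three, so calibration here demonstrates correctness
of the machinery, not robustness to real-data pathologies.

## Numerical and design choices

* Each test draws all replicates from one `numpy` Generator seeded per
  invocation; results are exactly reproducible given (inputs, seed,
  replicate count).  Bulk vectorised draws are used instead of
  per-replicate substreams — a 1,000-replicate test on default-size data
  runs in tens of milliseconds, which is what makes 200-bundle
  calibration experiments routine.
* Undefined statistics (zero denominators) always signal — as an
  exception for observed values, as NaN-and-`n_invalid` for replicates —
  never as a silent 0 or ∞.
* The experiment sizes shipped in the tests and the acceptance script
  (200 calibration bundles at the small preset with 1,000 replicates;
  100 recovery bundles per effect at default sizes) were chosen once as
  the smallest designs whose binomial/KS error bands are decisively
  narrower than the effects being checked.

## Known limitations

* The endpoint hit rule under-counts very long CNPs relative to an
  overlap rule; the `overlap` mode exists precisely to measure that
  sensitivity on real inputs.
* The tag-shuffle null conditions on per-arm tag counts only; finer
  spatial structure (clustering of testis genes within arms) is not
  preserved, and a clustered reality would make the null anti-
  conservative for spatially autocorrelated statistics.
* Multi-level nesting is accepted by the reader, but classification uses
  only direct links; deep nesting chains are therefore treated gene by
  gene.
* p-values are granular at 1/replicates; with the tie-inclusive
  convention the smallest attainable `P_upper` is 0 (reported as such,
  with the replicate count alongside, never as an analytic approximation).
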