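# Methods

This note documents the models, the synthetic-data assumptions, the
numerical choices, and the limits of what the test suite shows.

## Bipartite promoter model

A subgroup's promoter model is a pair of position probability matrices
(−35 and −10 elements) plus a spacer-length model. All scores are
log2-odds against a background base composition (default uniform), so a
score reads as bits of preference:

- `build_pwm`: `p[i][b] = (count + κ·bg[b]) / (n + κ)` with pseudocount
  κ = 1 by default, distributed by the background (Laplace-style). With
  κ > 0 probabilities are interior and log-odds finite.
- Spacer penalty: `log2 p̂(L)/p̂(L*)` where `p̂(L) ∝ count(L) + κ_s` over an
  inclusive support and `L*` is the smoothed mode (smallest mode on ties).
  The penalty is 0 at the mode and −∞ outside the support, so a perfect
  promoter's total equals the sum of its two consensus block scores. The
  functional form of the penalty is this package's choice; only the
  existence of a spacing penalty is dictated by the modelling problem.
- `scan_promoter` enumerates every (−35 offset, spacer ∈ support)
  placement on one strand (promoters are directional; callers
  reverse-complement minus-strand regions). Ties break to the smallest
  −35 offset, then the smallest spacer, making output deterministic. An
  exhaustive brute-force enumeration is kept in the tests as the oracle.
- Optional UP term: `up_bonus · (A/T fraction of ≤23 nt upstream of the
  −35 placement)`, default off (`up_bonus = 0`). The published model
  family includes an "UP" term whose exact form is not printed; this
  A/T-richness bonus is our configurable interpretation and plays no role
  in any default result.

`information_content` uses `2 + Σ p log2 p` per column against a uniform
background and the KL form `Σ p log2(p/bg)` otherwise; the discovery
sampler always uses the KL form, so non-uniform backgrounds are handled
consistently.

## Two-block Gibbs discovery

`discover_two_block` is a collapsed Gibbs sampler with one site per
sequence over placements (−35 offset, spacer). Each sweep resamples each
sequence's placement from the predictive distribution given the counts of
all other sites (PWM pseudocount 1, spacer pseudocount 1). Defaults:
5 restarts x 150 sweeps; the restart with the highest total information
content wins. Two deterministic post-passes sharpen the result:

1. greedy finalisation — each sequence takes its argmax placement; passes
   are kept only while total IC increases, so the reported IC never drops
   below the sampled state's;
2. register polish — small coordinated shifts of all sites (whole motif
   ±1–2 nt; −10 block only via the spacer; −35 block only), accepted only
   on IC improvement. Gapped-motif samplers commonly converge one base
   off register; this removes that failure mode deterministically.

Background frequencies are estimated from the input sequences (clipped to
≥ 1e-3). The sampler is a pure function of (inputs, seed). At the study
conditions (30 windows of 80 nt, 13 informative positions, 10% per-position
mutation) it recovers ≥ 90% of planted consensus positions in ≥ 9/10 seeds;
recovery degrades monotonically as the mutation rate rises to 0.3.

## Mining and design conventions

- Promoter coordinates follow the bacterial convention −60..+20 with no
  position 0; sequences are stored 0-based with accessor-mapped offsets.
  In planted windows the −10 element's 3' end sits at position −7, so the
  planted window starts exactly 60 nt upstream of the (operon head) gene
  start and the motif lies fully in the intergenic segment.
- Operon walking: same strand, intergenic gap ≤ 50 nt (a common
  heuristic; nothing in the modelling fixes it), upstream window
  ≤ 300 nt by default.
- Host exclusion: candidates scoring within 6 bits of a host model's
  consensus score are flagged. The sigma70 fixture uses the textbook
  TTGACA / 17±2 / TATAAT consensus; the FecI-like fixture is a synthetic
  approximation assembled from fecA-promoter-style elements, adequate for
  flagging FecI-like sequences but not a published consensus.
- UP element: a packaged 25 nt A/T-rich sequence replaces −60..−36;
  everything from −35 on is untouched and ids gain the `UP` tag. For
  subgroups with long spacers the −35 element can extend upstream of −36;
  the reconstructed library therefore *selects* (from several generated
  candidates) the promoter that scores best after replacement, mirroring
  how candidates are screened by model score in practice.
- "Autoregulatory" is defined as the promoter window ending within 150 nt
  of the cognate gene or operon start; assessments rank host-unflagged
  first, then by descending orthogonality margin, autoregulatory first on
  ties.

## Crosstalk conventions

- Activity thresholds are strict (>5-fold sigma activation, >2-fold
  anti-sigma repression); a boundary value is inactive.
- Off-target load of a cognate pair sums `max(fold − 1, 0)` over the
  pair's row and column (cognate cell excluded) within the submatrix of
  cognate pairs. Subtracting the neutral fold of 1 makes a silent cell
  contribute zero; clipping at zero keeps loads nonnegative when noisy
  silent cells scatter below 1. The published ordering's arithmetic is
  not printed; this definition is the package's.
- `select_orthogonal` removes the largest-load pair and recomputes until
  k remain (ties toward the lexicographically last sigma id), then orders
  survivors by ascending load. A brute-force subset search in the tests
  bounds the greedy gap (≤ 10% on 8-pair problems; 0% in the packaged
  runs).
- `scores_to_folds` calibrates model scores to predicted folds per sigma:
  `fold = 1 + (F_cog − 1)·2^min(ΔS, 0)` with ΔS the bit deficit relative
  to the sigma's cognate score — each bit halves the predicted excess.
- Growth rate is the least-squares slope of ln(OD600) vs time over the
  requested window, or the maximal-slope contiguous 5-point window when
  unspecified ("linear section" is not otherwise defined). Toxicity is
  strict <75% of the WT mean.

## Sequestration switch

Free sigma solves the 1:1 equilibrium mass balance with the
cancellation-safe quadratic form (conjugate expression when
`anti + K_d − sigma_tot > 0`), accurate to ~1e-15 relative over 12 decades
of parameters. Output is `basal0 + vmax·S/(k_half + S)`; total sigma is
linear in the input activity. No RNAP competition and no kinetics: 1:1
equilibrium sequestration is the minimal model producing the
threshold-gating phenotype.

`fit_hill` minimises squared residuals of log outputs (weighting the
low-output regime where the basal matters), multi-starts over
n ∈ {0.5, 1, 2, 4, 8}, bounds n ∈ [0.2, 12], tolerances 1e-12, ≤ 10⁴
evaluations. Flat data (range below twice the replicate noise floor, or
below 0.2% of the median when no replicate SD is given) return an
`unidentifiable` flag instead of a spurious n. Noiseless transfer
functions are recovered to machine precision; with 10% multiplicative
noise, n is within ±0.3 in ≥ 90/100 runs.

`tuning_curve` reports, per anti-sigma level, the Hill fit plus the
OFF-state basal defined as the fitted curve at the lowest (leak) input.
The Hill `basal` parameter extrapolates to zero input, which for a sharp
titration switch can exceed the leak-level output; the OFF state at the
uninduced input is the quantity sequestration actually suppresses, and it
is provably non-increasing in the anti-sigma level. The property sweep
(`random_tuning_study`) draws switches in the informative titration
regime — binding tight relative to the output promoter
(`K_d/k_half ∈ 10^[−2,−1.5]`) and anti levels spanning 0.2–6 x `k_half` —
where the fitted cooperativity rises gradually instead of pinning at the
fit bound. The packaged demo configuration (`demo_tuning_config`) uses
tighter binding and a wider anti range to demonstrate > 100x threshold
tuning and a > 10-fold basal drop.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed); stage-level
substreams derive from one global seed by stable (sha256) hashing of
stage names, so partial pipeline reruns reproduce per-stage data.

- Planted mutations always substitute to a different base (uniform over
  the three alternatives), so the per-position mismatch fraction equals
  the mutation rate exactly and planted information content is
  analytically predictable.
- Fluorescence noise is multiplicative mean-1 lognormal (positive
  support, matching geometric-mean summaries of flow data). Promoter
  leakiness spans 10-fold by default on a log-uniform grid.
- Crosstalk truth tables concentrate off-target activity in a
  "promiscuous" clique plus a bounded, round-robin splash onto clean
  promoters. In `make_screen_study` promiscuity is modelled mechanistically
  as *relaxed* (high-pseudocount, low-information) PWMs — weak specificity
  — which yields broad mid-level off-target folds; that, not the clique
  alone, is what makes the planted clean set identifiable by iterative
  elimination (a clique member whose partners have all been eliminated is
  genuinely orthogonal within the survivor set).
- Toy genomes plant one promoter window per sigma operon, sometimes with
  the sigma as the second operon gene, on mixed strands. They have no gene
  content, codon structure, or repeats; presence matrices have no
  phylogenetic structure. Passing tests therefore demonstrate correctness
  of the algorithms under the stated generative assumptions, not
  performance on real genomes or real screens.

The reconstructed part library (`reference`) reproduces the published
design arithmetic — 86 sigmas (two per subgroup), 62 anti-sigmas, 29
promoters of which 26 active, 58 active sigmas, a 25 x 36 anti-sigma
screen, 16 distinct −35 and 10 distinct −10 specificity classes (160
chimera upper bound) — with synthetic organisms, motifs and sequences and
a fixed internal seed. Exemplar ids (ECF11_987/AS11_987, P_15_UP436,
P_02_rpoHP3, ...) are kept for readability. Which third promoter subgroup
is inactive, and which sigmas/antis fill the screen subsets, are
reconstruction choices; only the counts are meaningful.

## Co-occurrence test

Partner count of a subgroup: mean over genomes containing it of the
number of other subgroups present. `compare_groups` permutes group labels
over the union (two-sided, difference of means; add-one p-value for
sampled permutations; exact enumeration available for ≤ ~10 subgroups).
Null p-values are uniform by KS test over 200 simulated datasets, and
power against the biased generator (bias 0.5, 20 subgroups x 80 genomes)
exceeds 90%. Published partner-count figures depend on a genome panel and
a test definition that are not printed, so no numerical agreement with
them is claimed — only the direction and the calibration of this test.

## Problem sizes

Default suite scales were chosen to exercise each claim at the smallest
informative size: 30 x 80 nt windows for discovery (10 seeds), 50
sequences for the scan oracle, 30-pair screens over 100 noise seeds,
C(8,4) exhaustive selection oracles, 10⁴ draws for mass balance, 20
switch draws, 200 null datasets x 400 permutations. The acceptance script
re-runs all of them from one seed in under a minute of CPU.
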