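# Methods

## Model

cloneclock models a tumor as two competing cell populations. A founder cell
(MRCA0) at generation t0 = 0 divides in discrete time; each division yields
two daughters, each of which dies before its next division with probability
β (default 0.2). The ancestral clone Ka therefore grows at the net
per-generation rate λβ = ln(2(1 − β)) ≈ 0.470, so its expected size is
N(t) = e^{λβ·t}. At generation tf one cell (MRCAf) acquires a fitness
advantage quantified by the selection coefficient s and seeds a subclone Kf
growing at λβ(1 + s). At the sampling generation te the subclone is a
fraction P of the tumor, and the clone ratio obeys the logit identity

    ln(P / (1 − P)) = λβ (s·te − (1 + s)·tf).

Each surviving daughter acquires Poisson(μ) new mutations, where μ is the
per-diploid-genome per-division mutation rate. Mutations divide into five
genealogical classes with characteristic cell fractions at te:

| class      | origin                                   | cell fraction            |
|------------|------------------------------------------|--------------------------|
| root       | preexist at t0                           | 1                        |
| trunk      | foundation lineage, generation t < tf    | P + (1 − P)e^{−λβ·t}     |
| branch     | acquired by MRCAf at tf                  | exactly P                |
| successive | inside Kf after tf                       | P·e^{−λβ(1+s)(t−tf)}     |
| incidental | in Ka off the foundation lineage         | low-frequency tail       |

For a heterozygous mutation in a diploid region the expected VAF is
purity × fraction / 2; `preprocess` restricts calls to diploid segments and
converts VAFs to cell fractions. The derived heterogeneity metrics are the
fitness diversity index θ = −[P log₂P + (1 − P) log₂(1 − P)] (base-2 so a
balanced mixture scores exactly 1; non-analyzable samples are assigned
θ = 0 on the assumption that they are dominated by a single clone) and the
subclone expansion score τ = te/tf.

## Simulator

`simulate` generates tumors by a hybrid scheme: exact per-cell branching
(genealogy, deaths, Poisson mutation influx, single-cell subclone seeding at
⌊tf⌋) while the population is below a cutover size (default 10⁴), then
deterministic exponential expansion of every clone and mutation cohort to
te. Cell fractions are computed from realized descendant counts at the
handoff, so cohort fractions carry the true lineage stochasticity, not just
their expectations. Subclone cells draw surviving offspring from a Poisson
distribution with mean (2(1 − β))^{1+s}; ancestral cells use the exact
two-daughter Bernoulli scheme. Mutations whose realized fraction falls
below 10⁻⁴ are dropped (counted).

The benchmark configuration holds μ = 16, β = 0.2, depth 120× and final
size N = 10⁸ fixed, draws tf uniformly from {4,…,14} and s from
[0.125, 1.625], and samples each tumor when it reaches N; draws whose
realized subclone fraction falls outside [0, 0.97] are redrawn. Because te
is pinned by N, the benchmark satisfies the census closure that the
inference engine uses for s (below) — this is a property of the study
design, not a free calibration. Sequencing draws per-site depth from
Poisson(d) (minimum 1) and alt reads from Binomial(depth, purity·f/2).

What the generator emulates: clonal competition between exactly two
fitness levels, neutral passenger accumulation, binomial read sampling.
What it does not: copy-number change, sequencing error beyond binomial
noise, spatial structure, multiple independent subclones, variable
per-site mappability. Passing recovery tests therefore demonstrate
correctness of the estimator under the model's own assumptions, not
robustness to their violation.

## Inference

Stage 1 clusters read counts with a binomial mixture (EM, k-means++ starts,
best two of ten restarts run to convergence, BIC selection over k ≤ 12) and
assigns clusters to the five classes by maximizing a cluster-level joint
likelihood (Poisson cluster sizes × binomial read counts) over admissible
assignments, with closed-form parameter blocks.

On realized branching data this one-cluster-per-generation picture is not
identifiable at routine depth: early trunk cohorts ride single-survivor
bottlenecks to fraction 1, late trunk, branch and early subclone cohorts
all collapse to exactly P, and both clones shed polyphyletic neutral tails
with N(≥u) ≈ 0.94·μc/(m·u)·exp(−(u/(b·c))^k) (c the clone fraction, m its
growth rate; shape constants measured on the generator and verified by a
generator property test). Stage 2 therefore maximizes a thinned-Poisson
point-process likelihood over (alt, depth) whose intensity combines

* a clonal atom at fraction 1 with free weight (root plus bottlenecked
  trunk cohorts),
* the trunk continuum: mass μ per generation mapped through the fk decay,
* a free-weight atom at P absorbing collapsed generations (converted back
  to generations through its excess over μ, plus measured bottleneck
  constants of 0.6 root-side and 0.45 branch-side generations),
* the two neutral tails with amplitudes tied to μ but carrying penalized
  log-offsets (σ = 0.2 ancestral, 0.45 subclone — the measured lognormal
  dispersion of realized tail amplitudes), and
* a 2% uniform background robustifying against lineage lumpiness.

Detection thinning uses alt ~ Poisson(depth·purity·f/2) with the effective
minimum-read threshold max(3, ⌈0.02·depth⌉): inference never descends below
a 2% VAF floor, where the two-population structure carries no information
(a no-op at ~120×).

Optimization is multi-start L-BFGS-B (the stage-1 block fit plus
moment-initialized starts at each plausible subclone fraction, including
fixed high-fraction candidates); only likelihood-improving moves are
accepted, so the recorded trace is non-decreasing. Optima whose clonal
atom absorbs mutations sitting significantly below VAF = purity/2
(z < −3) are rejected: root mutations are carried by every cell, and a
shifted "clonal" cluster is the signature of a self-similar
misinterpretation that reads the interior of a nearly fixed subclone as a
whole tumor.

**Selection coefficient.** A single timepoint carries almost no direct
information about s: the subclone and ancestral tails are both ∝ 1/f² and
mutually absorbing, and the positions of realized subclone cohorts are
governed by lineage-split randomness, not by s (we measured < 1σ of signal
across the full s range). s and te are therefore reported through the
census closure te = ln((1 − P)·N)/λβ, s = (logit(P)/λβ + tf)/(te − tf)
with an assumed final size N (default 10⁸, configurable), which is exact
for tumors sampled at a known size and accurate to a few percent under
census stochasticity. The `s_path` field records this.

**Analyzability.** A sample is analyzable iff all of (μ, s, tf, te, P) are
finite and in-domain, the fit converged, the subclone evidence test passes
(the full model must beat a clonal-only null — root atom, pinned-support
neutral tail, and one free neutral-lineage lump — by 1.5·ln n), at least
one full trunk generation is resolved, and P ∈ [0.02, 0.98] with
s ∈ [0.1, 5]. The s bounds are identifiability screens, not biology: a
fitted advantage below 0.1 cannot be distinguished from neutral
nested-lineage structure, and one above 5 signals a degenerate closure.
Non-analyzable samples carry reason codes; θ is imputed as 0 for them.

Standard errors come from a nonparametric bootstrap over mutations
(100 resamples, warm-started, seeded).

## Numerical choices

Intensity evaluation uses a 140-cell geometric fraction grid from 3×10⁻⁴
to 1 with exact per-cell binomial kernels (incomplete-beta integrals), so
the likelihood remains well defined at arbitrary depth. Tail masses are
exact differences of the closed-form N(≥u). EM ties break toward smaller k
(BIC), class-assignment ties toward the larger branch fraction (earlier
emergence). Degenerate inputs (empty samples, neutral configurations,
unreachable target fractions) produce reason-coded verdicts or typed
errors, never crashes; extinct lineages are retried with incremented
sub-seeds.

## Problem sizes

The shipped recovery experiments use a 150-tumor suite for the
analyzability rate and mutation-rate medians, an 18-tumor common-truth
sweep over depths 60/120/300/1000×, and 100-replicate Monte-Carlo checks
of the simulator's cohort statistics.

## Known limitations

* Parameter accuracy for μ, s and tf is dominated by truth-level lineage
  stochasticity (bottleneck collapse, lumpy tails); deeper sequencing
  sharpens P markedly but does not reduce those error sources, and the
  emergence-time decomposition can degrade at very high depth as near-P
  mass resolves.
* Nearly fixed subclones (P ≳ 0.95) are self-similar to whole tumors from
  a single timepoint; some are misread as moderate-fraction tumors and
  some genuinely weakly selected tumors are screened out by the
  near-neutral floor. Failures concentrate at extreme subclone fractions,
  which is also the regime the method is expected to reject.
* The reported s inherits the assumed final population size through the
  census closure; it is a scaled, not an absolute, estimate when the true
  size differs.
* Copy-number aberrant regions are excluded, not modeled; purity is
  consumed, never estimated.
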