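# Methods

## The objective

For locus s with n_s allele states and an assignment z of N individuals
into K groups, let O_ki be the number of non-missing allele calls equal
to i among individuals of group k, R_k = Σ_i O_ki the group's call total,
C_i = Σ_k O_ki the allele total and G the grand total. The per-locus
statistic is

    LR_s = Σ_{k,i} O_ki ln(O_ki / E_ki),   E_ki = R_k C_i / G,

with the conventions 0·ln(0/E) = 0 and cells with E = 0 (which force
O = 0, since E vanishes only with a zero marginal) contributing 0. LR_s
is non-negative, vanishes exactly when every row is proportional to the
allele totals, and 2·LR_s is the G-statistic of the table. The dataset
objective is LR(X|z) = Σ_s LR_s, valid under locus independence — hence
the recommendation to LD-prune first. Natural logarithms are used
everywhere and stated as nats in outputs; the argmax over assignments
does not depend on the base.

The counting unit is the allele call: a diploid individual contributes
two calls, a half-missing genotype one, a fully missing genotype none.
This uses all observed information without imputation.

### Incremental evaluation

C_i and G are invariant when individuals change groups, so

    LR_s = Σ_{k,i} xlogx(O_ki) − Σ_k xlogx(R_k) + const(s),

with xlogx(x) = x·ln x. Moving one individual touches two rows, so the
LR change of a move costs O(ploidy) table lookups per locus where the
individual has calls. The search kernels precompute xlogx on the
integers 0..N·ploidy and run over these lookups (compiled with numba); a
pure-numpy implementation of the same delta (`lr_core.delta_lr_move`)
serves as the reference the kernels are tested against, and both are
tested against full recomputation.

## The search

Annealed Gibbs sampling over assignments: pick an individual uniformly
at random, resample its label from p(C) ∝ exp(LR(X | z_r = C)/T)
(max-subtracted for stability), cool T geometrically once per epoch
(an epoch = N single-individual steps, so runtime per epoch is linear in
N and S), then refine with zero-temperature passes — each individual
moves to its argmax label; ties keep the current label, otherwise the
smallest label wins — until a pass makes no move. The whole procedure
restarts from independent uniform random assignments, and the best-LR
state ever visited is returned, relabelled by order of first appearance.
The greedy phase starts from the best state visited during annealing
rather than the final chain state; both readings are consistent with
recording the maximum-LR state, and hill-climbing the incumbent is the
safer deterministic choice.

Defaults: T0 = max(1, LR(initial)/N) — the scale of one individual's
contribution to the objective of a random assignment — alpha = 0.95,
200 annealing epochs, up to 50 greedy passes, 10 restarts. None of these
is critical for the strong-signal regimes the method targets; restarts
are the knob that matters, and all are exposed on the CLI and estimator.
Empty groups are legal throughout (an all-zero row contributes nothing);
a warning reports when the best partition uses fewer than K groups.

Randomness: one master seed; restart streams are spawned from it
deterministically, so results are independent of restart execution order
and identical across re-runs.

For comparing differentiation statistics, `fipsa run --objective daf|fst`
drives the same partition search with a generic random-restart greedy
coordinate ascent that recomputes the chosen objective in full for every
candidate move. It is much slower than the LR path (whose incremental
updates are objective-specific) and intended for small comparative runs,
not production clustering.

## Permutation test for structure

Under the null of panmixia every arrangement of a locus's alleles across
individuals is equally likely. Shuffling the non-missing calls of each
locus independently (missing slots stay missing, per-locus allele counts
are conserved exactly) therefore produces datasets with no structure but
identical marginal information. The observed dataset and each of the
n_perm (default 20) shuffled datasets get the same annealing schedule
and restart count with deterministically derived seeds, making the best
LRs exchangeable under the null; structure is declared when the observed
LR exceeds every null LR, and the empirical p-value
(1 + #{null ≥ obs})/(1 + n_perm) is reported so users can apply their
own cutoff. With 20 permutations the false-detection rate of the
max-rule is 1/21 per dataset by exchangeability.

## Choice of K

LR(K) rises steeply while real subpopulations remain unsplit and
flattens into a small, noisy overfitting gain beyond the true K; with
LR(1) = 0 by definition, SOD(K) = LR(K) − (LR(K−1)+LR(K+1))/2 peaks at
the elbow. Candidates K ∈ {2..K_max−3} must satisfy SOD(K) > 0 and
SOD(K) > SOD(K+1) and are scored by

    SOD(K)² / Σ_{i=K}^{K_max−1} SOD(i)²  ·  (1 − SOD(K+1)/SOD(K))²

— global dominance of the tail times the sharpness of the local drop —
with ties going to the smallest K and "no informative K" returned when
no candidate passes the guards. The score is invariant to scaling the
profile by a positive constant.

Numerical choice: SOD(K+1) is clamped at 0 in the local factor. In the
plateau beyond the true K the SOD values are noise with random signs,
and the raw ratio would award scores above 1 to a noise candidate whose
successor happens to be negative — a scale-free artifact that no amount
of extra optimization removes. A drop to or below zero already satisfies
the local criterion completely, so the local factor saturates at 1.
Profiles whose SOD values are all positive are unaffected.

The selection is advisory: when the number of populations is known from
design or biology, pass it directly and skip model selection.

## Synthetic data

The generator is a Balding–Nichols F-model. Per locus: ancestral
frequency p ~ Beta(a, b) (default uniform) truncated by rejection to
[0.05, 0.95] so near-monomorphic loci — absent from the SNV-array-like
data the method targets — do not dominate; each of K subpopulations
draws its frequency from Beta(p(1−F)/F, (1−p)(1−F)/F), i.e. mean p and
variance F·p(1−p), so F is the subpopulations' Fst against the ancestral
pool (F = 0 gives panmixia exactly); diploid genotypes are binomial.
The `split_tree` variant drifts frequencies along a balanced binary
split tree with per-branch parameter F instead of the star model,
giving nested fine structure. Missing calls are masked uniformly at a
configurable rate (default 0).

What the generator does *not* emulate: linkage disequilibrium (all loci
are independent, which is the regime the objective assumes and the one
LD pruning approximates), admixed individuals (the method assigns
discrete labels and is not an admixture model), mutation/ascertainment
processes, or any specific real demographic history. Passing the
recovery tests therefore demonstrates correctness of the search and the
statistic under the model's own assumptions, not robustness to LD or
admixture in real cohorts.

Evaluation: the adjusted Rand index is the standard Hubert–Arabie
pair-counting form (computed via scikit-learn, cross-checked against a
direct computation in the tests); confusion tables name each cluster by
its majority reference label (ties lexicographic), and concordance drops
excluded reference classes (e.g. an admixed class) from numerator and
denominator alike. The bundled 11,257-genome validation table reproduces
the published cluster-versus-super-population counts; excluding the
2,385 admixed individuals, 8,795 of 8,872 assignments agree (99.1%).

## LD pruning

Plink-style greedy windowed pruning on allele-1 dosages: within a window
of loci, any pair with squared Pearson correlation (pairwise-complete
over missing genotypes) above r² all have the later locus removed, the
window sliding by a step over the sequence of surviving loci, swept to a
fixpoint so that pruning an already-pruned set changes nothing. Defaults
r² = 0.2, window 50, step 5. Non-biallelic loci pass through untouched
with a warning. Genotypes with a half-missing call are treated as
missing for correlation purposes (their dosage is not on the 0..ploidy
scale).

## Problem sizes used in the validation runs

The test suite and `scripts/acceptance.py` size their simulations to
run comfortably on a single CPU while staying in the regimes where the
method's claims apply: recovery and K selection use K = 5 subpopulations
of 40 diploid individuals, F = 0.05, S = 2,000 unlinked loci (with a
locus-count sweep over S ∈ {250, 1,000, 4,000}); the permutation test
uses N = 200, S = 1,000, F ∈ {0, 0.05} with 20 permutations; search
effort is 60 annealing epochs, 40 greedy passes and 4 restarts for the
profile runs and 40/30/2 for the permutation runs — ample at these
signal strengths (the annealed optimum matches exhaustive enumeration on
every tiny instance tested). Exhaustive-search comparisons use N ≤ 10,
where enumeration of all bipartitions is feasible.

## Known limitations

- The objective presumes unlinked loci; unpruned LD inflates the LR and
  can distort both the permutation test and the choice of K.
- The LR loses power under extremely imbalanced subgroup sizes, and the
  method does not model admixture proportions.
- The annealer offers no optimality guarantee; restarts are the defense
  against local maxima, and the K-profile's plateau noise reflects
  residual optimization variance.
- DAF is defined only for two groups; the Fst objective is a Hudson-type
  estimator chosen for robustness and simplicity (pairwise-averaged for
  K > 2) and is pluggable rather than canonical.
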