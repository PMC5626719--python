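"""Existence-of-structure testing and choice of the number of groups K.

Structure test: a homogeneous population partitioned into K = 2 groups by
the annealer still attains some positive LR through overfitting; to
calibrate it, alleles are shuffled among individuals independently at each
locus (breaking any real structure while conserving every per-locus allele
count exactly), the annealer is run with identical effort on each shuffled
dataset, and structure is declared when the observed LR exceeds every
permutation LR.  An empirical p-value (1 + #{null >= obs}) / (1 + n_perm)
is reported alongside the decision.

Choice of K: the LR-versus-K profile flattens once K exceeds the number of
real subpopulations.  SOD(K) = LR(K) - (LR(K-1) + LR(K+1))/2 is the
(negative) second difference of the profile; an elbow shows up as a K
whose SOD dominates both everything to its right (globally) and its
immediate successor (locally).  The discriminant combines the two:

    score(K) = SOD(K)^2 / sum_{i=K}^{Kmax-1} SOD(i)^2
               * (1 - SOD(K+1)/SOD(K))^2

maximized over K in {2, ..., Kmax-3} subject to SOD(K) > 0 and
SOD(K) > SOD(K+1); if no K passes the guards, no informative K exists.
The selected K is advisory — prior biological knowledge of K should take
precedence when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annealer import CoolingSchedule, anneal
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "PermutationResult",
    "LRProfile",
    "SODResult",
    "permute_alleles",
    "test_structure",
    "lr_profile",
    "sod",
    "k_max_info",
    "select_k",
]


@dataclass
class PermutationResult:
    observed_lr: float
    null_lrs: np.ndarray
    structure_detected: bool
    empirical_p: float


@dataclass
class LRProfile:
    """Best LR (nats) per K over a contiguous K range."""

    entries: dict[int, float]

    def __post_init__(self) -> None:
        ks = sorted(self.entries)
        if not ks:
            raise ValueError("empty profile")
        if ks != list(range(ks[0], ks[-1] + 1)):
            raise ValueError("profile K values must be contiguous")
        if not all(np.isfinite(v) for v in self.entries.values()):
            raise ValueError("profile values must be finite")

    @property
    def k_max(self) -> int:
        return max(self.entries)

    @property
    def k_min(self) -> int:
        return min(self.entries)


@dataclass
class SODResult:
    sod: dict[int, float]
    k_max_info: int | None
    discriminant: dict[int, float]


def permute_alleles(gm: GenotypeMatrix, seed: int = 0) -> GenotypeMatrix:
    """Shuffle alleles among individuals independently at every locus.

    The multiset of non-missing calls at each locus is permuted across
    that locus's non-missing call slots; the missingness mask and the
    per-locus allele counts are conserved exactly.
    """
    rng = np.random.default_rng(seed)
    calls = gm.calls.copy()
    for s in range(gm.n_loci):
        slot = calls[:, s, :]
        mask = slot != MISSING
        vals = slot[mask]
        slot[mask] = rng.permutation(vals)
    return GenotypeMatrix(
        list(gm.individual_ids),
        list(gm.locus_ids),
        calls,
        n_alleles=gm.n_alleles.copy(),
        ploidy=gm.ploidy,
    )


def test_structure(
    gm: GenotypeMatrix,
    n_perm: int = 20,
    schedule: CoolingSchedule | None = None,
    restarts: int = 10,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for the existence of population structure at K = 2.

    The observed dataset and each allele-shuffled dataset get identical
    optimization effort (same schedule and restart count, deterministically
    derived seeds), so their best LRs are exchangeable under the null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    child = np.random.SeedSequence(seed).generate_state(2 * n_perm + 1, dtype=np.uint32)
    seeds = [int(x) % (2**31 - 1) for x in child]
    observed = anneal(gm, 2, schedule=schedule, seed=seeds[0], restarts=restarts)
    null_lrs = np.empty(n_perm)
    for i in range(n_perm):
        permuted = permute_alleles(gm, seed=seeds[1 + 2 * i])
        res = anneal(permuted, 2, schedule=schedule, seed=seeds[2 + 2 * i], restarts=restarts)
        null_lrs[i] = res.best_lr
    detected = bool(observed.best_lr > null_lrs.max())
    p = (1 + int((null_lrs >= observed.best_lr).sum())) / (1 + n_perm)
    return PermutationResult(observed.best_lr, null_lrs, detected, p)


def lr_profile(
    gm: GenotypeMatrix,
    k_min: int = 1,
    k_max: int = 10,
    schedule: CoolingSchedule | None = None,
    restarts: int = 10,
    seed: int = 0,
) -> LRProfile:
    """Best LR over restarts for each K in [k_min, k_max].

    K = 1 is exactly 0 (a single group makes every expectation equal its
    observation), so it is entered without running the annealer.
    """
    if not (1 <= k_min < k_max <= gm.n_individuals):
        raise ValueError("need 1 <= k_min < k_max <= N_ind")
    seeds = [
        int(x) % (2**31 - 1)
        for x in np.random.SeedSequence(seed).generate_state(k_max + 1, dtype=np.uint32)
    ]
    entries: dict[int, float] = {}
    for K in range(k_min, k_max + 1):
        if K == 1:
            entries[1] = 0.0
        else:
            entries[K] = anneal(gm, K, schedule=schedule, seed=seeds[K], restarts=restarts).best_lr
    return LRProfile(entries)


def sod(profile: LRProfile) -> dict[int, float]:
    """Second-difference statistic SOD(K) = LR(K) - (LR(K-1)+LR(K+1))/2.

    Defined for every K whose two neighbors are in the profile.
    """
    e = profile.entries
    return {
        K: e[K] - (e[K - 1] + e[K + 1]) / 2.0
        for K in range(profile.k_min + 1, profile.k_max)
    }


def k_max_info(profile: LRProfile) -> int | None:
    """The maximum informative K, or None when no elbow passes the guards."""
    return select_k(profile).k_max_info


def select_k(profile: LRProfile) -> SODResult:
    """Evaluate the elbow discriminant over the LR profile.

    Candidates are K in {2, ..., Kmax-3} with SOD(K) > 0 and
    SOD(K) > SOD(K+1); each scores
    SOD(K)^2 / sum_{i=K}^{Kmax-1} SOD(i)^2 * (1 - SOD(K+1)/SOD(K))^2
    (candidates with a zero normalization sum are skipped).  Ties go to
    the smallest K.

    A negative SOD(K+1) is clamped to 0 in the local factor: a drop to or
    below zero already satisfies the local criterion completely, and the
    raw ratio would otherwise reward noise fluctuations in the plateau
    beyond the true K with scores above 1.
    """
    kmax = profile.k_max
    if kmax < 6:
        raise ValueError("K selection needs a profile up to K_max >= 6")
    if profile.k_min > 1:
        raise ValueError("profile must start at K = 1")
    s = sod(profile)
    scores: dict[int, float] = {}
    for K in range(2, kmax - 2):  # {2, ..., Kmax-3}
        if not (s[K] > 0 and s[K] > s[K + 1]):
            continue
        norm = sum(s[i] ** 2 for i in range(K, kmax))
        if norm == 0:
            continue
        scores[K] = s[K] ** 2 / norm * (1.0 - max(s[K + 1], 0.0) / s[K]) ** 2
    if not scores:
        return SODResult(s, None, scores)
    best = max(scores.values())
    chosen = min(K for K, v in scores.items() if v == best)
    return SODResult(s, chosen, scores)
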