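"""Simulated-annealing search for the maximum-LR partition.

The chain state is a full assignment of individuals to K groups.  Each
step picks one individual uniformly at random and resamples its label from
the annealed Gibbs kernel p(C) proportional to exp(LR(X | z_r = C) / T),
with the temperature cooled geometrically once per epoch (an epoch is
``steps_per_epoch`` single-individual updates, by default one per
individual).  The annealing phase is followed by zero-temperature
hill-climbing passes, and the whole procedure is restarted from
independent random initial assignments; the best-LR state ever visited is
returned.  Empty groups are allowed throughout (an all-zero table row
contributes nothing to the LR); a warning reports when the final partition
uses fewer than K groups.

Everything is reproducible from a single integer seed; restarts draw from
deterministically derived independent streams, so results do not depend on
the order in which restarts execute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .genotype_io import GenotypeMatrix
from .lr_core import CountTables, Partition, build_counts, delta_lr_move, total_lr

__all__ = ["CoolingSchedule", "AnnealResult", "anneal", "gibbs_step", "canonicalize"]

#: LR slack treated as a tie in the greedy phase (keeps the current label).
GREEDY_TOL = 1e-9


@dataclass(frozen=True)
class CoolingSchedule:
    """Geometric cooling: epoch ``i`` runs at ``T0 * alpha**i``.

    ``t0=None`` means automatic: ``max(1, LR(initial)/N_ind)``, putting the
    initial temperature on the scale of one individual's LR contribution.
    """

    t0: float | None = None
    alpha: float = 0.95
    n_epochs: int = 200
    greedy_epochs: int = 50
    steps_per_epoch: int | None = None

    def __post_init__(self) -> None:
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_epochs < 1 or self.greedy_epochs < 1:
            raise ValueError("n_epochs and greedy_epochs must be positive")
        if self.steps_per_epoch is not None and self.steps_per_epoch < 1:
            raise ValueError("steps_per_epoch must be positive")


@dataclass
class AnnealResult:
    best_partition: Partition
    best_lr: float
    lr_trace: np.ndarray  # running best LR per epoch (annealing then greedy)
    n_nonempty_groups: int
    seed: int
    restart_index: int
    restart_lrs: np.ndarray = field(default_factory=lambda: np.empty(0))


def canonicalize(part: Partition) -> Partition:
    """Relabel groups by order of first appearance (idempotent)."""
    return part.canonical()


def gibbs_step(
    counts: CountTables,
    part: Partition,
    gm: GenotypeMatrix,
    individual: int,
    temperature: float,
    rng: np.random.Generator,
) -> tuple[CountTables, Partition, float]:
    """One annealed Gibbs update of a single individual's label.

    Resamples individual `individual`'s group from
    p(C) proportional to exp(delta_LR(C) / temperature), computed in
    max-subtracted form, and applies the move.  Returns the updated counts
    and partition and the LR change.  This is the reference (pure
    numpy) version of the compiled inner loop used by :func:`anneal`.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    K = part.K
    z = part.z
    frm = int(z[individual])
    calls_r = gm.calls[individual]
    delta = np.array(
        [delta_lr_move(counts, calls_r, frm, c) for c in range(1, K + 1)]
    )
    if not np.isfinite(delta).all():
        raise FloatingPointError("non-finite LR delta; count tables corrupted?")
    w = np.exp((delta - delta.max()) / temperature)
    p = w / w.sum()
    chosen = int(rng.choice(K, p=p)) + 1
    d = float(delta[chosen - 1])
    if chosen != frm:
        from .lr_core import apply_move

        apply_move(counts, calls_r, frm, chosen)
        z = z.copy()
        z[individual] = chosen
    return counts, Partition(z, K), d


def _xlogx_table(max_count: int) -> np.ndarray:
    c = np.arange(max_count + 2, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        xl = c * np.log(c)
    xl[0] = 0.0
    return xl


def anneal(
    gm: GenotypeMatrix,
    K: int,
    schedule: CoolingSchedule | None = None,
    seed: int = 0,
    restarts: int = 10,
) -> AnnealResult:
    """Maximize the summed per-locus LR over partitions into K groups.

    Runs `restarts` independent chains (random uniform initial
    assignments, annealed Gibbs updates, then greedy refinement) and
    returns the best state ever visited, canonically relabelled.  Fully
    reproducible from `seed`; identical inputs give identical results.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    N = gm.n_individuals
    if K > N:
        warnings.warn(f"K={K} exceeds the number of individuals ({N})", stacklevel=2)
    schedule = schedule or CoolingSchedule()
    spe = schedule.steps_per_epoch or N

    if K == 1:
        part = Partition(np.ones(N, dtype=np.int64), 1)
        trace = np.zeros(schedule.n_epochs + 1)
        return AnnealResult(part, 0.0, trace, 1, seed, 0, np.zeros(restarts))

    calls = np.ascontiguousarray(gm.calls, dtype=np.int16)
    xl = _xlogx_table(N * gm.ploidy)
    streams = np.random.SeedSequence(seed).spawn(restarts)

    best_lr = -np.inf
    best_z: np.ndarray | None = None
    best_trace: np.ndarray | None = None
    best_restart = 0
    restart_lrs = np.empty(restarts)

    for ri in range(restarts):
        rng = np.random.default_rng(streams[ri])
        z = rng.integers(0, K, size=N).astype(np.int64)
        counts = build_counts(gm, Partition(z + 1, K))
        O = counts.O.astype(np.int64)
        R = counts.row_totals.astype(np.int64)
        lr0 = total_lr(counts)
        t0 = schedule.t0 if schedule.t0 is not None else max(1.0, abs(lr0) / N)

        n_steps = schedule.n_epochs * spe
        r_seq = rng.integers(0, N, size=n_steps).astype(np.int64)
        u_seq = rng.random(n_steps)
        t_seq = np.repeat(t0 * schedule.alpha ** np.arange(schedule.n_epochs), spe)

        z_best = np.empty(N, dtype=np.int64)
        trace = np.empty(schedule.n_epochs + 1, dtype=np.float64)
        lr_anneal, _ = _kernels.anneal_chain(
            calls, O, R, xl, z, r_seq, u_seq, t_seq, spe, lr0, z_best, trace[:-1]
        )

        # hill-climb from the best annealed state
        part_best = Partition(z_best + 1, K)
        counts = build_counts(gm, part_best)
        O = counts.O.astype(np.int64)
        R = counts.row_totals.astype(np.int64)
        zg = z_best.copy()
        lr_final, _ = _kernels.greedy_passes(
            calls, O, R, xl, zg, schedule.greedy_epochs, lr_anneal, GREEDY_TOL
        )
        trace[-1] = max(lr_final, lr_anneal)
        restart_lrs[ri] = trace[-1]
        np.maximum.accumulate(trace, out=trace)
        if trace[-1] > best_lr:
            best_lr = trace[-1]
            best_z = zg if lr_final >= lr_anneal else z_best
            best_trace = trace
            best_restart = ri

    assert best_z is not None and best_trace is not None
    part = Partition(best_z + 1, K).canonical()
    exact_lr = total_lr(build_counts(gm, part))
    n_nonempty = part.n_nonempty()
    if n_nonempty < K:
        warnings.warn(
            f"best partition uses {n_nonempty} of K={K} groups", stacklevel=2
        )
    return AnnealResult(
        best_partition=part,
        best_lr=exact_lr,
        lr_trace=best_trace,
        n_nonempty_groups=n_nonempty,
        seed=seed,
        restart_index=best_restart,
        restart_lrs=restart_lrs,
    )


def greedy_maximize(
    gm: GenotypeMatrix,
    K: int,
    objective,
    seed: int = 0,
    restarts: int = 10,
    max_passes: int = 50,
) -> tuple[Partition, float]:
    """Random-restart greedy coordinate ascent for an arbitrary objective.

    `objective(gm, Partition) -> float` is recomputed in full for every
    candidate move, so this is far slower than :func:`anneal` and exists
    to let alternative differentiation statistics (DAF, Fst) drive the
    same partition search for comparison purposes.  Ties keep the current
    label.
    """
    N = gm.n_individuals
    streams = np.random.SeedSequence(seed).spawn(restarts)
    best: tuple[float, Partition | None] = (-np.inf, None)
    for ri in range(restarts):
        rng = np.random.default_rng(streams[ri])
        z = rng.integers(1, K + 1, size=N).astype(np.int64)
        val = objective(gm, Partition(z, K))
        for _ in range(max_passes):
            moved = False
            for r in range(N):
                cur = int(z[r])
                cand_val, cand_lab = val, cur
                for lab in range(1, K + 1):
                    if lab == cur:
                        continue
                    z[r] = lab
                    v = objective(gm, Partition(z, K))
                    if v > cand_val + 1e-12:
                        cand_val, cand_lab = v, lab
                z[r] = cand_lab
                if cand_lab != cur:
                    val, moved = cand_val, True
            if not moved:
                break
        if val > best[0]:
            best = (val, Partition(z.copy(), K))
    val, part = best
    assert part is not None
    return part.canonical(), float(val)


def brute_force_best(gm: GenotypeMatrix, K: int = 2) -> tuple[Partition, float]:
    """Exhaustive argmax of the LR over all partitions (tiny N only).

    Enumerates label vectors with the first individual fixed to group 1
    (label symmetry).  Exponential in N; refuse N > 16.
    """
    N = gm.n_individuals
    if N > 16:
        raise ValueError("brute force is limited to N <= 16")
    best = (-np.inf, None)
    z = np.ones(N, dtype=np.int64)

    def rec(i: int, used: int) -> None:
        nonlocal best
        if i == N:
            part = Partition(z.copy(), K)
            lr = total_lr(build_counts(gm, part))
            if lr > best[0]:
                best = (lr, part)
            return
        for lab in range(1, min(used + 1, K) + 1):
            z[i] = lab
            rec(i + 1, max(used, lab))

    z[0] = 1
    rec(1, 1)
    lr, part = best
    assert part is not None
    return part.canonical(), float(lr)
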