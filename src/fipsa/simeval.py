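"""Truth-labelled synthetic genotypes and clustering evaluation.

The generator is a Balding–Nichols F-model: each locus draws an ancestral
frequency p from a (truncated) Beta law, each subpopulation draws its own
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) — mean p, variance
F·p·(1-p), so F plays the role of the subpopulations' Fst against the
ancestral pool — and diploid genotypes are binomial in the subpopulation
frequency.  Loci are mutually independent given the frequencies (no LD).
A ``split_tree`` variant lets frequencies drift along a balanced binary
split tree with per-branch parameter F, producing nested (fine) structure
rather than a star phylogeny.

Evaluation helpers: the adjusted Rand index between partitions, a
cluster-by-reference-label confusion table with majority naming, and the
concordance of a confusion table after excluding reference classes (for
instance admixed individuals that no discrete assignment can match).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .genotype_io import MISSING, GenotypeMatrix
from .lr_core import Partition

__all__ = [
    "SimulationSpec",
    "ConfusionTable",
    "simulate",
    "adjusted_rand_index",
    "confusion",
    "concordance",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters for one synthetic dataset.

    ``F`` in (0, 1) controls drift (F = 0 collapses every subpopulation
    onto the ancestral frequency: panmixia); ``freq_prior`` is the Beta
    law for ancestral frequencies, truncated to [0.05, 0.95] so
    near-monomorphic loci do not dominate; ``model`` is ``"bn"`` (star)
    or ``"split_tree"`` (nested splits).
    """

    K: int
    sizes: tuple[int, ...]
    n_loci: int
    F: float
    freq_prior: tuple[float, float] = (1.0, 1.0)
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.0
    model: str = "bn"
    seed: int = 0
    ploidy: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "sizes", tuple(int(x) for x in self.sizes))
        if self.K < 1 or len(self.sizes) != self.K:
            raise ValueError("sizes must list one positive count per subpopulation")
        if any(x < 1 for x in self.sizes):
            raise ValueError("subpopulation sizes must be positive")
        if self.n_loci < 1:
            raise ValueError("n_loci must be positive")
        if not 0.0 <= self.F < 1.0:
            raise ValueError("F must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.model not in ("bn", "split_tree"):
            raise ValueError("model must be 'bn' or 'split_tree'")
        lo, hi = self.freq_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("invalid freq_bounds")

    @property
    def n_individuals(self) -> int:
        return sum(self.sizes)


def _truncated_beta(rng: np.random.Generator, a: float, b: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sample Beta(a, b) restricted to [lo, hi]."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.beta(a, b, size=2 * (size - filled) + 16)
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _drift(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """One Balding–Nichols drift step: Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    if F == 0.0:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return np.clip(rng.beta(a, b), 0.0, 1.0)


def _split_tree_freqs(rng: np.random.Generator, p: np.ndarray, F: float, K: int) -> np.ndarray:
    """Evolve frequencies along a balanced binary split tree to K leaves.

    Starting from one ancestral lineage, the widest current lineage splits
    into two children (each drifting independently with parameter F) until
    K lineages exist; lineage order is deterministic so leaf k maps to
    subpopulation k + 1.
    """
    lineages = [p.copy()]
    while len(lineages) < K:
        q = lineages.pop(0)  # oldest lineage splits first -> balanced tree
        lineages.append(_drift(rng, q, F))
        lineages.append(_drift(rng, q, F))
    return np.stack(lineages, axis=0)


def simulate(spec: SimulationSpec) -> tuple[GenotypeMatrix, Partition]:
    """Draw one truth-labelled dataset under `spec`.

    Returns the genotype matrix (individuals blocked by subpopulation,
    biallelic loci) and the true partition with labels 1..K.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.freq_prior
    lo, hi = spec.freq_bounds
    p_anc = _truncated_beta(rng, a, b, lo, hi, spec.n_loci)
    if spec.model == "bn":
        freqs = np.stack([_drift(rng, p_anc, spec.F) for _ in range(spec.K)], axis=0)
    else:
        freqs = _split_tree_freqs(rng, p_anc, spec.F, spec.K)

    N = spec.n_individuals
    S = spec.n_loci
    calls = np.empty((N, S, spec.ploidy), dtype=np.int16)
    z = np.empty(N, dtype=np.int64)
    row = 0
    for k, nk in enumerate(spec.sizes):
        block = (
            rng.random((nk, S, spec.ploidy)) < freqs[k][None, :, None]
        ).astype(np.int16)
        calls[row : row + nk] = block
        z[row : row + nk] = k + 1
        row += nk
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape) < spec.missing_rate
        calls[mask] = MISSING
    gm = GenotypeMatrix(
        individual_ids=[f"ind{i}" for i in range(N)],
        locus_ids=[f"snv{s}" for s in range(S)],
        calls=calls,
        n_alleles=np.full(S, 2, dtype=np.int64),
        ploidy=spec.ploidy,
    )
    return gm, Partition(z, spec.K)


def adjusted_rand_index(z_true: Partition | np.ndarray, z_inferred: Partition | np.ndarray) -> float:
    """Hubert–Arabie adjusted Rand index between two partitions.

    1 means identical up to relabelling, about 0 means no better than
    chance; symmetric in its arguments.
    """
    a = z_true.z if isinstance(z_true, Partition) else np.asarray(z_true)
    b = z_inferred.z if isinstance(z_inferred, Partition) else np.asarray(z_inferred)
    if a.shape != b.shape:
        raise ValueError("partitions must have equal length")
    return float(adjusted_rand_score(a, b))


@dataclass
class ConfusionTable:
    """Cluster x reference-label counts with majority cluster naming."""

    counts: pd.DataFrame  # index: cluster label, columns: reference labels
    cluster_names: dict[int, str] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def confusion(z_inferred: Partition | np.ndarray, ref_labels) -> ConfusionTable:
    """Cross-tabulate inferred clusters against reference labels.

    Each cluster is named by its majority reference label (ties broken
    lexicographically).
    """
    z = z_inferred.z if isinstance(z_inferred, Partition) else np.asarray(z_inferred)
    ref = np.asarray(list(ref_labels), dtype=object)
    if z.shape[0] != ref.shape[0]:
        raise ValueError("label vectors must have equal length")
    counts = pd.crosstab(pd.Series(z, name="cluster"), pd.Series(ref, name="reference"))
    counts = counts.sort_index().sort_index(axis=1)
    names = {}
    for cluster, row in counts.iterrows():
        top = row.max()
        names[int(cluster)] = sorted(c for c in counts.columns if row[c] == top)[0]
    return ConfusionTable(counts, names)


def concordance(table: ConfusionTable, exclude_labels=()) -> float:
    """Fraction of individuals whose cluster's name matches their label.

    Columns in `exclude_labels` (for example an admixed class that no
    discrete cluster can legitimately claim) are dropped before both the
    numerator and the denominator.
    """
    drop = [c for c in table.counts.columns if c in set(exclude_labels)]
    kept = table.counts.drop(columns=drop)
    denom = kept.to_numpy().sum()
    if denom == 0:
        raise ValueError("no cells left after exclusion")
    num = 0
    for cluster, row in kept.iterrows():
        name = table.cluster_names.get(int(cluster))
        if name in kept.columns:
            num += int(row[name])
    return float(num / denom)
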