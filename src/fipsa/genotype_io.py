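"""Genotype matrix I/O, filtering and LD pruning.

The in-memory container is :class:`GenotypeMatrix`: an ``(N, S, ploidy)``
array of integer allele codes (0-based, ``MISSING = -1`` for an absent
call) with per-locus allele-state counts.  Loci are treated as exchangeable
unlinked sites; chromosome and position are not tracked beyond locus order.

Two on-disk formats are supported: VCF 4.x (plain or bgzipped, read with
cyvcf2) and a simple tab-delimited matrix (header row of locus ids, one row
per individual, cells like ``0/1`` with ``.`` for a missing allele) that the
test suite and CLI use as a lightweight interchange format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele calls with missing-data support.

    Parameters
    ----------
    individual_ids :
        Unique sample identifiers, length ``N``.
    locus_ids :
        Unique locus identifiers, length ``S``.
    calls :
        ``(N, S, ploidy)`` integer array of allele codes; ``MISSING`` (-1)
        marks an absent call.  Phase is never represented.
    n_alleles :
        Per-locus number of allele states ``n``; every non-missing call at
        locus ``s`` lies in ``{0, ..., n_alleles[s] - 1}``.
    ploidy :
        Calls per individual per locus (2 for diploids).
    """

    individual_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray
    n_alleles: np.ndarray = field(default=None)  # type: ignore[assignment]
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.ndim != 3:
            raise ValueError("calls must be a 3-d (N, S, ploidy) array")
        n, s, p = self.calls.shape
        if n < 1 or s < 1:
            raise ValueError("need at least one individual and one locus")
        if p != self.ploidy:
            raise ValueError(f"calls last dimension {p} != ploidy {self.ploidy}")
        if len(self.individual_ids) != n:
            raise ValueError("individual_ids length does not match calls")
        if len(self.locus_ids) != s:
            raise ValueError("locus_ids length does not match calls")
        if len(set(self.individual_ids)) != n:
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_ids)) != s:
            raise ValueError("duplicate locus ids")
        if self.n_alleles is None:
            observed = np.where(self.calls >= 0, self.calls, -1).max(axis=(0, 2))
            self.n_alleles = np.maximum(observed + 1, 1).astype(np.int64)
        else:
            self.n_alleles = np.asarray(self.n_alleles, dtype=np.int64)
        if self.n_alleles.shape != (s,):
            raise ValueError("n_alleles must have one entry per locus")
        if (self.n_alleles < 1).any():
            raise ValueError("n_alleles must be positive")
        bad = (self.calls >= self.n_alleles[None, :, None]) | (
            (self.calls < 0) & (self.calls != MISSING)
        )
        if bad.any():
            raise ValueError("allele codes out of range for their locus")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean ``(N, S, ploidy)`` mask of missing calls."""
        return self.calls == MISSING

    def dosage(self, allele: int = 1) -> np.ndarray:
        """Per-genotype count of `allele`, NaN where any call is missing.

        Used for LD pruning; a genotype with a half-missing call is treated
        as missing because its dosage is not on the same 0..ploidy scale.
        """
        d = (self.calls == allele).sum(axis=2).astype(float)
        d[self.missing_mask.any(axis=2)] = np.nan
        return d

    def subset_loci(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=np.int64)
        return GenotypeMatrix(
            individual_ids=list(self.individual_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            calls=self.calls[:, idx, :].copy(),
            n_alleles=self.n_alleles[idx].copy(),
            ploidy=self.ploidy,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individual_ids == other.individual_ids
            and self.locus_ids == other.locus_ids
            and self.ploidy == other.ploidy
            and np.array_equal(self.calls, other.calls)
            and np.array_equal(self.n_alleles, other.n_alleles)
        )


def _parse_cell(cell: str, ploidy: int) -> list[int]:
    parts = cell.strip().split("/")
    if len(parts) != ploidy:
        raise ValueError(f"cell {cell!r} does not have {ploidy} allele tokens")
    out = []
    for tok in parts:
        if tok == ".":
            out.append(MISSING)
        else:
            try:
                code = int(tok)
            except ValueError as exc:
                raise ValueError(f"non-integer allele token {tok!r}") from exc
            if code < 0:
                raise ValueError(f"negative allele code {tok!r}")
            out.append(code)
    return out


def read_matrix(path, ploidy: int = 2) -> GenotypeMatrix:
    """Read the tab-delimited genotype matrix format.

    Line 1 is ``id`` followed by locus ids; each subsequent line is an
    individual id followed by one cell per locus, a cell being `ploidy`
    integers joined by ``/`` with ``.`` for a missing allele.
    ``n_alleles`` is inferred as 1 + the maximum observed code per locus.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        cols = header.split("\t")
        locus_ids = cols[1:]
        if not locus_ids:
            raise ValueError(f"{path}: no loci in header")
        individual_ids: list[str] = []
        rows: list[list[list[int]]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(locus_ids) + 1:
                raise ValueError(
                    f"{path}:{lineno}: expected {len(locus_ids) + 1} columns, got {len(parts)}"
                )
            individual_ids.append(parts[0])
            rows.append([_parse_cell(c, ploidy) for c in parts[1:]])
    if not rows:
        raise ValueError(f"{path}: no individuals")
    calls = np.asarray(rows, dtype=np.int16)
    return GenotypeMatrix(individual_ids, locus_ids, calls, ploidy=ploidy)


def write_matrix(gm: GenotypeMatrix, path) -> None:
    """Write `gm` in the tab-delimited matrix format (read_matrix inverse)."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(gm.locus_ids) + "\n")
        for i, ind in enumerate(gm.individual_ids):
            cells = [
                "/".join("." if a == MISSING else str(int(a)) for a in gm.calls[i, s])
                for s in range(gm.n_loci)
            ]
            fh.write(ind + "\t" + "\t".join(cells) + "\n")


def read_vcf(path, min_allele_count: int = 0, biallelic_only: bool = False) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF/VCF.gz file.

    One locus per record passing filters; phase is discarded and ``.``
    components become missing calls.  A record is dropped when no
    non-reference allele reaches `min_allele_count` copies (so
    ``min_allele_count=1`` drops monomorphic-reference records), or when it
    has more than one ALT allele and `biallelic_only` is set.

    Raises
    ------
    ValueError
        If no loci survive filtering (the message reports each filter's
        casualty count) or a GT field is malformed.
    OSError
        If the file cannot be opened.
    """
    from cyvcf2 import VCF

    if min_allele_count < 0:
        raise ValueError("min_allele_count must be non-negative")
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # cyvcf2 raises bare Exception subclasses
        raise OSError(f"cannot open VCF {path}: {exc}") from exc
    individual_ids = list(vcf.samples)
    if not individual_ids:
        raise ValueError(f"{path}: VCF has no samples")
    locus_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_alleles: list[int] = []
    n_multi = n_mac = 0
    n_records = 0
    for var in vcf:
        n_records += 1
        n_alt = len(var.ALT)
        if biallelic_only and n_alt != 1:
            n_multi += 1
            continue
        gts = np.asarray(var.genotypes, dtype=np.int16)  # (N, ploidy + 1), last = phase
        if gts.ndim != 2 or gts.shape[1] < 3:
            raise ValueError(f"{path}: malformed GT at record {var.ID or var.POS}")
        col = gts[:, :2].copy()
        col[col < 0] = MISSING
        if (col > n_alt).any():
            raise ValueError(
                f"{path}: allele code exceeds ALT count at record {var.ID or var.POS}"
            )
        if min_allele_count > 0:
            nonref = np.bincount(
                col[col > 0].ravel(), minlength=n_alt + 1
            )[1:]
            if nonref.size == 0 or nonref.max(initial=0) < min_allele_count:
                n_mac += 1
                continue
        name = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(name)
        columns.append(col)
        n_alleles.append(n_alt + 1)
    vcf.close()
    if not columns:
        raise ValueError(
            f"{path}: no loci left after filtering ({n_records} records; "
            f"{n_multi} failed biallelic filter, {n_mac} failed min_allele_count)"
        )
    calls = np.stack(columns, axis=1)
    if len(set(locus_ids)) != len(locus_ids):
        locus_ids = [f"{lid}#{i}" for i, lid in enumerate(locus_ids)]
    return GenotypeMatrix(individual_ids, locus_ids, calls, n_alleles=np.asarray(n_alleles))


def ld_prune(
    gm: GenotypeMatrix,
    r2_max: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> list[int]:
    """Greedy windowed LD pruning on genotype dosages (plink style).

    Within each `window` of loci, for every pair whose squared Pearson
    correlation of dosages (pairwise-complete over missing genotypes)
    exceeds `r2_max`, the later locus is removed; the window then slides by
    `step`.  Non-biallelic loci are passed through untouched (a warning
    reports how many).  Returns the strictly increasing retained indices.
    """
    if not 0.0 <= r2_max <= 1.0:
        raise ValueError("r2_max must be in [0, 1]")
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if window < step:
        raise ValueError("window must be >= step")
    S = gm.n_loci
    biallelic = gm.n_alleles == 2
    n_skipped = int((~biallelic).sum())
    if n_skipped:
        warnings.warn(
            f"{n_skipped} non-biallelic loci passed through ld_prune untouched",
            stacklevel=2,
        )
    dos = pd.DataFrame(gm.dosage())
    survivors = [int(i) for i in np.nonzero(biallelic)[0]]
    # windows slide over the survivor sequence; sweep to a fixpoint so the
    # result is idempotent under re-pruning of the compacted set
    changed = True
    while changed:
        changed = False
        pos = 0
        while survivors:
            ids = survivors[pos : pos + window]
            if len(ids) >= 2:
                r2 = np.square(dos.iloc[:, ids].corr().to_numpy())
                drop: set[int] = set()
                for a in range(len(ids)):
                    if a in drop:
                        continue
                    for b in range(a + 1, len(ids)):
                        if b not in drop and r2[a, b] > r2_max:
                            drop.add(b)
                if drop:
                    changed = True
                    dropped = {ids[b] for b in drop}
                    survivors = [i for i in survivors if i not in dropped]
            if pos + window >= len(survivors):
                break
            pos += step
    retained = sorted(set(survivors) | set(np.nonzero(~biallelic)[0].tolist()))
    return [int(i) for i in retained]
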