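"""Genetic distances: allele-sharing (1 - IBS) between individual samples and
Weir-Cockerham F_ST between populations.

The allele-sharing distance between two diploid individuals is one minus the
mean proportion of alleles identical by state across loci where both calls
are non-missing: per locus IBS = (2 - |g_i - g_j|) / 2 for allele-count
coded genotypes, so D = mean(|g_i - g_j|) / 2.

F_ST uses the Weir & Cockerham (1984) moment estimator for two populations
at biallelic loci: per-locus variance components a (among populations),
b (among individuals within populations) and c (within individuals,
heterozygosity), combined across loci as the ratio of sums
theta-hat = sum(a) / sum(a + b + c).  The raw estimate may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import MISSING, OUTGROUP, GenotypeMatrix, SampleSheet


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over samples or populations."""

    labels: list[str]
    d: np.ndarray
    kind: str = "generic"  # {allele_sharing, fst, generic}

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise DistanceError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise DistanceError("matrix is not symmetric")
        if np.diag(self.d).any():
            raise DistanceError("diagonal must be zero")
        if (self.d < 0).any():
            raise DistanceError("negative distances")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(pair[0]), self.labels.index(pair[1]))
        return float(self.d[i, j])

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], self.kind)

    # -- I/O ---------------------------------------------------------------
    def to_phylip(self, path: str | Path) -> None:
        """PHYLIP square distance-matrix format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.9f}" for x in row) + "\n")

    @classmethod
    def from_phylip(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        return cls(labels, np.array(rows), kind)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.d, index=self.labels, columns=self.labels).to_csv(
            path, sep="\t", index_label="label"
        )

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "generic") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# allele-sharing distance
# ---------------------------------------------------------------------------

def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 1 - IBS allele-sharing distance over all samples.

    Pairs with no overlapping non-missing locus raise, naming the pair.
    """
    calls = g.calls.astype(np.float64)
    miss = calls == MISSING
    calls[miss] = np.nan
    n = g.n_samples
    # |g_i - g_j| summed over shared loci; nan-aware via masking
    D = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        diff = np.abs(calls[i + 1:] - calls[i])            # (n-i-1, L)
        ok = ~np.isnan(diff)
        cnt = ok.sum(axis=1)
        tot = np.nansum(diff, axis=1)
        shared[i, i + 1:] = cnt
        with np.errstate(invalid="ignore"):
            D[i, i + 1:] = np.where(cnt > 0, tot / (2.0 * cnt), np.nan)
    bad = np.argwhere((shared == 0) & np.triu(np.ones((n, n), bool), 1))
    if bad.size:
        i, j = bad[0]
        raise DistanceError(
            f"no overlapping non-missing loci for pair "
            f"({g.sample_ids[i]}, {g.sample_ids[j]})"
        )
    D = D + D.T
    return DistanceMatrix(list(g.sample_ids), D, kind="allele_sharing")


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

@dataclass
class FstComponents:
    """Per-locus Weir-Cockerham variance components for two populations."""

    locus_ids: list[str]
    a: np.ndarray  # among-population
    b: np.ndarray  # among-individual within population
    c: np.ndarray  # within-individual
    n: np.ndarray  # (L, 2) non-missing diploid counts
    p: np.ndarray  # (L, 2) alternate-allele frequencies
    informative: np.ndarray  # loci entering the ratio of sums

    @property
    def theta_hat(self) -> float:
        num = float(self.a[self.informative].sum())
        den = float(
            (self.a + self.b + self.c)[self.informative].sum()
        )
        if den == 0.0:
            raise DistanceError("no informative loci (denominator zero)")
        return num / den


def wc_fst_components(
    g: GenotypeMatrix, samples_a: Sequence[str], samples_b: Sequence[str]
) -> FstComponents:
    """Per-locus a, b, c components between two sample sets (r = 2).

    Loci are informative when both populations have at least one non-missing
    call, the pooled per-locus sample size supports the estimator
    (n_bar > 1), and the locus is not monomorphic across both populations.
    """
    r = 2
    comp = []
    for ss in (samples_a, samples_b):
        calls = g.calls[g.sample_index(ss)].astype(float)
        calls[calls == MISSING] = np.nan
        comp.append(calls)
    ca, cb = comp
    n_i = np.stack([(~np.isnan(c)).sum(axis=0) for c in (ca, cb)], axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_i = np.stack(
            [np.nansum(c, axis=0) / (2.0 * (~np.isnan(c)).sum(axis=0)) for c in (ca, cb)],
            axis=1,
        )
        h_i = np.stack(
            [(c == 1).sum(axis=0) / (~np.isnan(c)).sum(axis=0) for c in (ca, cb)],
            axis=1,
        )

    usable = (n_i >= 1).all(axis=1)
    n_bar = n_i.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_c = (r * n_bar - (n_i**2).sum(axis=1) / (r * n_bar)) / (r - 1)
        p_bar = (n_i * p_i).sum(axis=1) / (r * n_bar)
        s2 = (n_i * (p_i - p_bar[:, None]) ** 2).sum(axis=1) / ((r - 1) * n_bar)
        h_bar = (n_i * h_i).sum(axis=1) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (1.0 / (n_bar - 1))
            * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar)
            - ((r - 1) / r) * s2
            - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2.0

    monomorphic = (p_bar == 0.0) | (p_bar == 1.0)
    informative = usable & (n_bar > 1) & (n_c > 0) & ~monomorphic
    for arr in (a, b, c):
        arr[~informative] = 0.0
    return FstComponents(
        locus_ids=list(g.locus_ids), a=a, b=b, c=c, n=n_i, p=p_i,
        informative=informative,
    )


def wc_fst(
    g: GenotypeMatrix, sheet: SampleSheet, pop_a: str, pop_b: str,
    level: str = "subspecies",
) -> float:
    """Multi-locus Weir-Cockerham F_ST between two named populations.

    Ratio-of-sums estimator; the raw value is returned and may be negative.
    """
    units = sheet.units(level)
    for p in (pop_a, pop_b):
        if p not in units:
            raise DistanceError(f"unknown population {p!r} at level {level!r}")
    return wc_fst_components(g, units[pop_a], units[pop_b]).theta_hat


def fst_matrix(
    g: GenotypeMatrix,
    sheet: SampleSheet,
    level: str = "subspecies",
    pool_outgroups: bool = False,
) -> tuple[DistanceMatrix, list[tuple[str, str]]]:
    """Pairwise F_ST distance matrix over populations.

    Negative estimates are floored at zero for use as a distance; the list of
    floored pairs is returned alongside.  With ``pool_outgroups`` the outgroup
    species are combined into a single population labelled ``OUTGROUP``.
    """
    units = sheet.units(level)
    if pool_outgroups and sheet.outgroup_species:
        pooled: list[str] = []
        for sp in sheet.outgroup_species:
            pooled.extend(units.pop(sp))
        units[OUTGROUP] = pooled
    names = list(units)
    if len(names) < 3:
        raise DistanceError("need at least 3 populations")
    n = len(names)
    D = np.zeros((n, n))
    floored: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            est = wc_fst_components(g, units[names[i]], units[names[j]]).theta_hat
            if est < 0:
                floored.append((names[i], names[j]))
                est = 0.0
            D[i, j] = D[j, i] = est
    return DistanceMatrix(names, D, kind="fst"), floored
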