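"""Sample-size-corrected Watterson's theta per subspecies or lineage group.

For a unit with ``n`` chromosomes sampled, theta_W = S / a_n with
``S`` the number of loci segregating within the unit and
``a_n = sum_{i=1}^{n-1} 1/i`` the harmonic correction.  With a SNP panel
there is no sequence length, so theta is reported raw (comparable across
units) and per assayed locus, never per base pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, SampleSheet, _allele_presence


@dataclass
class ThetaEstimate:
    unit: str
    S: int                 # segregating-locus count within the unit
    n_chrom: int           # chromosomes used for the harmonic correction
    theta: float           # S / a_n
    theta_per_locus: float # theta / assayed locus count


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i (the Watterson correction denominator)."""
    return float(sum(1.0 / i for i in range(1, n)))


def watterson_theta(
    g: GenotypeMatrix,
    sheet: SampleSheet,
    unit: str,
    level: str = "subspecies",
    correction: str = "modal",
) -> ThetaEstimate:
    """Watterson's theta for one unit.

    ``correction`` selects how missing data enter the sample-size term:

    - ``"modal"`` (default): a single a_n using the modal per-locus
      chromosome count across assayed loci, giving theta = S / a_n.
    - ``"per-locus"``: theta = sum over segregating loci of 1 / a_{n_locus},
      correcting each locus at its own chromosome count.

    Haploid samples (optional ``ploidy`` column in the sheet) contribute one
    chromosome; all others contribute two.
    """
    units = sheet.units(level)
    if unit not in units:
        raise ValueError(f"unknown unit {unit!r} at level {level!r}")
    samples = units[unit]
    calls = g.calls[g.sample_index(samples)]
    if "ploidy" in sheet.table.columns:
        ploidy = (
            sheet.table.set_index("sample").loc[samples, "ploidy"].astype(int).to_numpy()
        )
    else:
        ploidy = np.full(len(samples), 2)

    nonmissing = calls != MISSING
    assayed = nonmissing.any(axis=0)
    if not assayed.any():
        raise ValueError(f"unit {unit!r} has no locus with non-missing data")
    n_per_locus = (nonmissing * ploidy[:, None]).sum(axis=0)

    has_ref, has_alt = _allele_presence(calls)
    seg = has_ref & has_alt
    S = int(seg.sum())

    vals, cnts = np.unique(n_per_locus[assayed], return_counts=True)
    n_modal = int(vals[np.argmax(cnts)])
    if n_modal < 2:
        raise ValueError(f"unit {unit!r}: theta undefined for n_chrom < 2")

    if correction == "modal":
        theta = S / harmonic_number(n_modal)
    elif correction == "per-locus":
        n_seg = n_per_locus[seg]
        if (n_seg < 2).any():
            raise ValueError("segregating locus with n_chrom < 2")
        theta = float(sum(1.0 / harmonic_number(int(n)) for n in n_seg))
    else:
        raise ValueError(f"unknown correction mode {correction!r}")
    return ThetaEstimate(
        unit=unit,
        S=S,
        n_chrom=n_modal,
        theta=theta,
        theta_per_locus=theta / int(assayed.sum()),
    )
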