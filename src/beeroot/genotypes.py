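"""Diploid SNP genotype panels, sample metadata and polymorphism-sharing summaries.

Genotypes are coded as the count of the alternate allele in a diploid call
(0, 1, 2) with ``-1`` for missing.  Every locus is biallelic by construction:
the coding admits only two alleles.  A panel is a samples x loci matrix plus a
sample sheet assigning each sample to a subspecies and to one of the four
honeybee lineage groups (M, C, O, A) or to an outgroup species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1

#: the five admissible lineage-group symbols
GROUPS = ("M", "C", "O", "A")
OUTGROUP = "OUTGROUP"
VALID_GROUPS = GROUPS + (OUTGROUP,)


class GenotypeError(ValueError):
    """Raised for malformed or contract-violating genotype input."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic-loci matrix of diploid alternate-allele counts.

    Parameters
    ----------
    sample_ids
        Ordered unique sample identifiers (rows).
    locus_ids
        Ordered unique locus identifiers (columns).
    calls
        ``int8`` array of shape ``(n_samples, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, L = self.calls.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != L:
            raise GenotypeError("id list lengths do not match call matrix shape")
        if n < 2 or L < 1:
            raise GenotypeError("need at least 2 samples and 1 locus")
        if len(set(self.sample_ids)) != n:
            raise GenotypeError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise GenotypeError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        all_missing = (self.calls == MISSING).all(axis=0)
        if all_missing.any():
            j = int(np.argmax(all_missing))
            raise GenotypeError(f"locus {self.locus_ids[j]!r} has all calls missing")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in sample_ids], dtype=int)

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeMatrix":
        """Row-subset preserving this matrix's sample order."""
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        missing = keep_set - set(self.sample_ids)
        if missing:
            raise GenotypeError(f"unknown samples: {sorted(missing)}")
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx], list(self.locus_ids), self.calls[idx]
        )

    def subset_loci(self, keep_idx: np.ndarray) -> "GenotypeMatrix":
        keep_idx = np.asarray(keep_idx, dtype=int)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.locus_ids[j] for j in keep_idx],
            self.calls[:, keep_idx],
        )

    def resample_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Column resample (bootstrap); resampled loci get suffixed unique ids."""
        idx = np.asarray(idx, dtype=int)
        ids = [f"{self.locus_ids[j]}_b{k}" for k, j in enumerate(idx)]
        return GenotypeMatrix(list(self.sample_ids), ids, self.calls[:, idx])


@dataclass
class SampleSheet:
    """Sample -> subspecies -> lineage-group / outgroup-species assignment."""

    table: pd.DataFrame  # columns: sample, subspecies, group, species[, ploidy]

    def __post_init__(self) -> None:
        required = {"sample", "subspecies", "group"}
        if not required.issubset(self.table.columns):
            raise GenotypeError(f"sample sheet must have columns {sorted(required)}")
        if "species" not in self.table.columns:
            self.table = self.table.assign(species="")
        if self.table["sample"].duplicated().any():
            dup = self.table.loc[self.table["sample"].duplicated(), "sample"].iloc[0]
            raise GenotypeError(f"duplicate sample row: {dup!r}")
        bad = ~self.table["group"].isin(VALID_GROUPS)
        if bad.any():
            raise GenotypeError(
                f"invalid lineage group {self.table.loc[bad, 'group'].iloc[0]!r}; "
                f"allowed: {VALID_GROUPS}"
            )

    @classmethod
    def from_records(cls, rows: Iterable[tuple]) -> "SampleSheet":
        """Build from (sample, subspecies, group[, species]) tuples."""
        recs = []
        for r in rows:
            r = tuple(r)
            recs.append(r + ("",) * (4 - len(r)))
        return cls(pd.DataFrame(recs, columns=["sample", "subspecies", "group", "species"]))

    def validate_against(self, g: GenotypeMatrix) -> None:
        missing = set(g.sample_ids) - set(self.table["sample"])
        if missing:
            raise GenotypeError(f"samples without metadata: {sorted(missing)}")

    # -- lookups -----------------------------------------------------------
    def group_of(self, sample: str) -> str:
        return str(self.table.set_index("sample").loc[sample, "group"])

    def samples_of_subspecies(self, name: str) -> list[str]:
        return list(self.table.loc[self.table["subspecies"] == name, "sample"])

    def samples_of_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample"])

    @property
    def subspecies(self) -> list[str]:
        """Ingroup subspecies names in sheet order (outgroups excluded)."""
        t = self.table[self.table["group"] != OUTGROUP]
        return list(dict.fromkeys(t["subspecies"]))

    @property
    def outgroup_species(self) -> list[str]:
        t = self.table[self.table["group"] == OUTGROUP]
        return list(dict.fromkeys(t["subspecies"]))

    @property
    def outgroup_samples(self) -> list[str]:
        return list(self.table.loc[self.table["group"] == OUTGROUP, "sample"])

    def ingroup_groups(self) -> list[str]:
        return [gp for gp in GROUPS if (self.table["group"] == gp).any()]

    def units(self, level: str) -> dict[str, list[str]]:
        """Unit name -> sample list at ``level`` in {'subspecies','group'}.

        Units are ingroup units; outgroup species are returned as their own
        units at either level (one unit per species).
        """
        out: dict[str, list[str]] = {}
        if level == "subspecies":
            for name in self.subspecies:
                out[name] = self.samples_of_subspecies(name)
        elif level == "group":
            for gp in self.ingroup_groups():
                out[gp] = self.samples_of_group(gp)
        else:
            raise ValueError(f"unknown unit level {level!r}")
        for sp in self.outgroup_species:
            out[sp] = self.samples_of_subspecies(sp)
        return out

    def subset(self, samples: Sequence[str]) -> "SampleSheet":
        keep = self.table[self.table["sample"].isin(set(samples))].reset_index(drop=True)
        return SampleSheet(keep)

    def drop_subspecies(self, names: Iterable[str]) -> "SampleSheet":
        names = set(names)
        unknown = names - set(self.table["subspecies"])
        if unknown:
            raise GenotypeError(f"cannot exclude unknown subspecies: {sorted(unknown)}")
        keep = self.table[~self.table["subspecies"].isin(names)].reset_index(drop=True)
        return SampleSheet(keep)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path: str | Path, format: str = "tabular", strict: bool = True) -> GenotypeMatrix:
    """Read a genotype matrix from the tabular TSV format or from VCF.

    Tabular: header row ``sample<TAB>locus1<TAB>...``; cells ``0|1|2|NA``.
    VCF: the GT field is parsed; ``./.`` becomes missing; phasing is ignored.
    In strict mode a multi-allelic VCF record raises; otherwise it is skipped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tabular":
        return _read_tabular(path)
    if format == "vcf":
        return _read_vcf(path, strict=strict)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_tabular(path: Path) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "sample":
            raise GenotypeError(f"{path}:1: expected header starting with 'sample'")
        locus_ids = header[1:]
        sample_ids: list[str] = []
        rows: list[list[int]] = []
        code = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise GenotypeError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            sample_ids.append(parts[0])
            try:
                rows.append([code[c] for c in parts[1:]])
            except KeyError as e:
                raise GenotypeError(f"{path}:{lineno}: invalid call {e.args[0]!r}") from None
    return GenotypeMatrix(sample_ids, locus_ids, np.array(rows, dtype=np.int8))


def _read_vcf(path: Path, strict: bool) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    cols: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            if strict:
                raise GenotypeError(
                    f"{path}: non-biallelic record at {rec.CHROM}:{rec.POS} "
                    f"(ALT={','.join(rec.ALT)})"
                )
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gts = rec.genotype.array()[:, :2]
        col = np.where((gts < 0).any(axis=1), MISSING, (gts > 0).sum(axis=1))
        locus_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        cols.append(col.astype(np.int8))
    if not cols:
        raise GenotypeError(f"{path}: no usable biallelic records")
    return GenotypeMatrix(sample_ids, locus_ids, np.column_stack(cols))


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the tabular TSV genotype format (bit-exact round trip)."""
    code = {0: "0", 1: "1", 2: "2", MISSING: "NA"}
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(g.locus_ids) + "\n")
        for i, s in enumerate(g.sample_ids):
            fh.write(s + "\t" + "\t".join(code[int(c)] for c in g.calls[i]) + "\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read metadata TSV with header ``sample subspecies group species``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# polymorphism classification
# ---------------------------------------------------------------------------

def _allele_presence(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus booleans: reference allele observed, alternate allele observed."""
    has_ref = ((calls == 0) | (calls == 1)).any(axis=0)
    has_alt = ((calls == 2) | (calls == 1)).any(axis=0)
    return has_ref, has_alt


def classify_locus(
    g: GenotypeMatrix, sheet: SampleSheet, locus: str, unit: str, level: str = "subspecies"
) -> dict[str, bool | None]:
    """Classify one locus within one unit (subspecies or lineage group).

    Returns ``{'polymorphic': ..., 'private': ..., 'fixed_private': ...}``;
    all three are ``None`` when the unit has no non-missing call at the locus.
    Outgroup species are skipped when assessing "elsewhere" for ingroup units.
    """
    j = g.locus_ids.index(locus)
    units = sheet.units(level)
    if unit not in units:
        raise GenotypeError(f"unknown unit {unit!r} at level {level!r}")
    res = _classify_all(g, sheet, level)
    row = {k: bool(v[units_order(units).index(unit)][j]) for k, v in res.items()}
    if not row.pop("informative"):
        return {"polymorphic": None, "private": None, "fixed_private": None}
    return row


def units_order(units: Mapping[str, list[str]]) -> list[str]:
    return list(units)


def _classify_all(
    g: GenotypeMatrix, sheet: SampleSheet, level: str
) -> dict[str, np.ndarray]:
    """Vectorised per-(unit, locus) classification.

    Returns arrays of shape (n_units, n_loci) keyed by
    informative/polymorphic/private/fixed_private, unit order as in
    ``sheet.units(level)``.  "Elsewhere" for an ingroup unit means all other
    ingroup units; outgroup species are excluded from both sides of the
    private/fixed-private comparison for ingroup units, and vice versa.
    """
    sheet.validate_against(g)
    units = sheet.units(level)
    names = list(units)
    outgroup_units = set(sheet.outgroup_species)
    n_u, L = len(names), g.n_loci

    has_ref = np.zeros((n_u, L), dtype=bool)
    has_alt = np.zeros((n_u, L), dtype=bool)
    informative = np.zeros((n_u, L), dtype=bool)
    for k, name in enumerate(names):
        calls = g.calls[g.sample_index(units[name])]
        has_ref[k], has_alt[k] = _allele_presence(calls)
        informative[k] = (calls != MISSING).any(axis=0)

    ingroup_mask = np.array([name not in outgroup_units for name in names])
    poly = has_ref & has_alt
    private = np.zeros_like(poly)
    fixed_private = np.zeros_like(poly)
    for k in range(n_u):
        same_side = ingroup_mask == ingroup_mask[k]
        others = same_side.copy()
        others[k] = False
        o_ref = has_ref[others].any(axis=0)
        o_alt = has_alt[others].any(axis=0)
        if not others.any():
            # single-unit panel: private collapses to polymorphic
            private[k] = poly[k]
            continue
        private[k] = poly[k] & (o_ref ^ o_alt)
        fixed_ref = informative[k] & has_ref[k] & ~has_alt[k]
        fixed_alt = informative[k] & has_alt[k] & ~has_ref[k]
        fixed_private[k] = (fixed_ref & ~o_ref) | (fixed_alt & ~o_alt)
    return {
        "informative": informative,
        "polymorphic": poly & informative,
        "private": private & informative,
        "fixed_private": fixed_private,
    }


@dataclass
class PolymorphismTable:
    """Per-subspecies and per-group locus classification counts."""

    table: pd.DataFrame  # columns: lineage, unit, level, n_samples,
    #                       polymorphic, private, fixed_private

    def row(self, unit: str) -> pd.Series:
        return self.table.set_index("unit").loc[unit]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def polymorphism_table(g: GenotypeMatrix, sheet: SampleSheet) -> PolymorphismTable:
    """Counts of polymorphic / private / fixed-private loci per subspecies,
    plus one "All group" row per lineage group (ingroup units only)."""
    rows = []
    for level in ("subspecies", "group"):
        res = _classify_all(g, sheet, level)
        units = sheet.units(level)
        names = list(units)
        for k, name in enumerate(names):
            if name in set(sheet.outgroup_species):
                continue
            if level == "subspecies":
                lineage = sheet.group_of(units[name][0])
            else:
                lineage = name
            rows.append(
                {
                    "lineage": lineage,
                    "unit": name if level == "subspecies" else f"All {name}",
                    "level": level,
                    "n_samples": len(units[name]),
                    "polymorphic": int(res["polymorphic"][k].sum()),
                    "private": int(res["private"][k].sum()),
                    "fixed_private": int(res["fixed_private"][k].sum()),
                }
            )
    order = {gp: i for i, gp in enumerate(GROUPS)}
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["lineage", "level"], key=lambda s: s.map(lambda v: order.get(v, v))
    , kind="stable").reset_index(drop=True)
    return PolymorphismTable(df)


def group_sharing_spectrum(
    g: GenotypeMatrix, sheet: SampleSheet
) -> dict[tuple[str, ...], int]:
    """Count loci by the exact subset of lineage groups in which each is
    polymorphic.  Keys are sorted tuples over {M, C, O, A}; the empty tuple
    collects loci polymorphic in no group.  Counts sum to the locus total.
    """
    present = sheet.ingroup_groups()
    if set(present) != set(GROUPS):
        raise GenotypeError(f"all four groups required, found {present}")
    res = _classify_all(g, sheet, "group")
    units = list(sheet.units("group"))
    poly = {name: res["polymorphic"][k] for k, name in enumerate(units) if name in GROUPS}
    counts: dict[tuple[str, ...], int] = {}
    for r in range(0, 5):
        for subset in itertools.combinations(GROUPS, r):
            counts[subset] = 0
    for j in range(g.n_loci):
        key = tuple(gp for gp in GROUPS if poly[gp][j])
        counts[key] += 1
    return counts
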