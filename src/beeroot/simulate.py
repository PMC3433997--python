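"""Synthetic SNP panels with honeybee-like population structure.

The generator draws allele frequencies down a two-level Balding-Nichols
hierarchy that mirrors the structure the analyses assume: an ancestral
frequency per locus, drifted first into two super-clades following a planted
group topology ((A,M),(C,O)), then into the four lineage groups, then into
subspecies within groups.  Genotypes are binomial draws from the subspecies
frequency.  Outgroup taxa are fixed at each locus, carrying the rare panel
allele with a configurable probability and the common allele otherwise.
One subspecies can be made admixed between two groups by drawing each locus's
frequency from one of the two source groups at random.

Every planted feature (per-population frequencies, private/fixed-private
locus lists, the group topology) is recorded as ground truth so downstream
estimators can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotypes import (
    GROUPS,
    MISSING,
    OUTGROUP,
    GenotypeMatrix,
    SampleSheet,
)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies: Beta(p(1-F)/F, (1-p)(1-F)/F).

    F = 0 copies the parent frequencies (no drift); F = 1 fixes each locus
    by a Bernoulli(p) draw.
    """
    if F <= 0.0:
        return p.copy()
    if F >= 1.0:
        return (rng.random(p.shape) < p).astype(float)
    k = (1.0 - F) / F
    return rng.beta(np.maximum(p * k, 1e-12), np.maximum((1.0 - p) * k, 1e-12))


@dataclass
class AdmixtureSpec:
    """One subspecies mixing two groups' ancestry at the locus level.

    ``drift`` is the taxon's own Balding-Nichols drift away from its mixed
    source frequencies: a hybrid-origin population that has also undergone a
    strong local founder effect gets a long terminal branch, which is what
    lets it capture the outgroup attachment in neighbor-joining trees.
    ``None`` falls back to the panel-wide subspecies drift.
    """

    name: str
    source_groups: tuple[str, str] = ("A", "M")
    alpha: float = 0.5            # probability a locus draws from source_groups[0]
    assigned_group: str = "A"     # lineage-group label it carries in the sheet
    drift: float | None = 0.75

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.drift is not None and not 0.0 <= self.drift <= 1.0:
            raise ValueError("drift must be in [0, 1]")


@dataclass
class SimConfig:
    """Study-scale defaults: ~1,000 unlinked loci, 14 subspecies in four
    lineage groups, three divergent outgroup taxa.

    Drift parameters are F_ST-like: ``clade_drift`` separates the (A,M) and
    (C,O) super-clades from the ancestor, ``group_drift`` the groups from
    their clade, ``subspecies_drift`` the subspecies from their group.
    """

    seed: int = 0
    n_loci: int = 1000
    subspecies_per_group: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "M": ("mel_1", "mel_2"),
            "C": ("car_1", "car_2"),
            "O": ("ana_1", "ana_2", "ana_3", "ana_4"),
            "A": ("scu_1", "scu_2", "scu_3", "scu_4", "scu_5", "scu_6"),
        }
    )
    samples_per_subspecies: int = 4
    clade_drift: float = 0.02
    group_drift: float | Mapping[str, float] = 0.10
    subspecies_drift: float = 0.05
    outgroup_species: Sequence[str] = ("og_cerana", "og_florea", "og_dorsata")
    samples_per_outgroup: int = 2
    outgroup_divergence: float = 0.3   # P(fixed for the rare panel allele)
    admixture: AdmixtureSpec | None = None
    planted_private: Mapping[str, int] = field(default_factory=dict)
    planted_fixed_private: Mapping[str, int] = field(default_factory=dict)
    exact_private_counts: bool | None = None  # None: on iff planting requested
    missing_rate: float = 0.0

    def group_drift_of(self, group: str) -> float:
        if isinstance(self.group_drift, Mapping):
            return float(self.group_drift[group])
        return float(self.group_drift)

    def __post_init__(self) -> None:
        gdrifts = (
            list(self.group_drift.values())
            if isinstance(self.group_drift, Mapping)
            else [self.group_drift]
        )
        for F in [self.clade_drift, self.subspecies_drift, *gdrifts]:
            if not 0.0 <= F <= 1.0:
                raise ValueError("drift parameters must be in [0, 1]")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        unknown = set(self.subspecies_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups {unknown}")


@dataclass
class SimTruth:
    """Ground truth for a simulated panel."""

    ancestral_freq: np.ndarray                    # (L,)
    subspecies_freq: dict[str, np.ndarray]        # per ingroup subspecies (L,)
    group_freq: dict[str, np.ndarray]             # per lineage group (L,)
    admixture_source: np.ndarray | None           # (L,) 0/1 per locus, or None
    private_loci: dict[str, list[str]]            # planted private locus ids
    fixed_private_loci: dict[str, list[str]]      # planted fixed-private locus ids
    topology: str = "((A,M),(C,O))"
    retained_mask: np.ndarray | None = None       # set by apply_ascertainment


def simulate_panel(cfg: SimConfig) -> tuple[GenotypeMatrix, SampleSheet, SimTruth]:
    """Simulate a genotype panel, sample sheet and ground truth.

    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    p_anc = rng.uniform(0.05, 0.95, size=L)

    clade_of = {"A": "AM", "M": "AM", "C": "CO", "O": "CO"}
    clade_freq = {
        cl: _balding_nichols(rng, p_anc, cfg.clade_drift) for cl in ("AM", "CO")
    }
    group_freq = {
        gp: _balding_nichols(rng, clade_freq[clade_of[gp]], cfg.group_drift_of(gp))
        for gp in cfg.subspecies_per_group
    }
    sub_freq: dict[str, np.ndarray] = {}
    sub_group: dict[str, str] = {}
    for gp, subs in cfg.subspecies_per_group.items():
        for name in subs:
            sub_freq[name] = _balding_nichols(rng, group_freq[gp], cfg.subspecies_drift)
            sub_group[name] = gp

    admix_source = None
    if cfg.admixture is not None:
        adm = cfg.admixture
        for gp in adm.source_groups:
            if gp not in group_freq:
                raise ValueError(f"admixture source group {gp!r} not simulated")
        admix_source = (rng.random(L) >= adm.alpha).astype(int)  # 0 -> first source
        base = np.where(
            admix_source == 0,
            group_freq[adm.source_groups[0]],
            group_freq[adm.source_groups[1]],
        )
        adm_drift = cfg.subspecies_drift if adm.drift is None else adm.drift
        sub_freq[adm.name] = _balding_nichols(rng, base, adm_drift)
        sub_group[adm.name] = adm.assigned_group

    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    sheet_rows: list[tuple] = []
    for name, freq in sub_freq.items():
        for k in range(cfg.samples_per_subspecies):
            sid = f"{name}_s{k}"
            sample_ids.append(sid)
            rows.append(rng.binomial(2, freq).astype(np.int8))
            sheet_rows.append((sid, name, sub_group[name], ""))

    # outgroups: per-species fixed calls, rare panel allele with prob d
    minor_is_alt = p_anc < 0.5   # alt allele is the rarer panel allele
    for sp in cfg.outgroup_species:
        rare = rng.random(L) < cfg.outgroup_divergence
        fixed_alt = np.where(rare, minor_is_alt, ~minor_is_alt)
        calls = np.where(fixed_alt, 2, 0).astype(np.int8)
        for k in range(cfg.samples_per_outgroup):
            sid = f"{sp}_s{k}"
            sample_ids.append(sid)
            rows.append(calls.copy())
            sheet_rows.append((sid, sp, OUTGROUP, sp))

    calls = np.vstack(rows)
    locus_ids = [f"snp{j:05d}" for j in range(L)]

    if cfg.missing_rate > 0.0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        # keep at least one non-missing call per locus
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(0, calls.shape[0]), j] = False
        calls[mask] = MISSING

    sheet = SampleSheet.from_records(sheet_rows)
    sub_samples = {
        name: [s for s, ss, *_ in sheet_rows if ss == name] for name in sub_freq
    }

    exact = cfg.exact_private_counts
    if exact is None:
        exact = bool(cfg.planted_private or cfg.planted_fixed_private)

    # plant private / fixed-private loci by overwriting calls
    private_loci: dict[str, list[str]] = {}
    fixed_private_loci: dict[str, list[str]] = {}
    plant_pool = list(range(L))
    rng.shuffle(plant_pool)
    cursor = 0

    def take(k: int) -> list[int]:
        nonlocal cursor
        if cursor + k > L:
            raise ValueError("not enough loci to plant the requested features")
        out = plant_pool[cursor:cursor + k]
        cursor += k
        return out

    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    planted_idx: set[int] = set()
    for name, k in cfg.planted_private.items():
        idx = take(k)
        planted_idx.update(idx)
        private_loci[name] = [locus_ids[j] for j in idx]
        for j in idx:
            calls[:, j] = 0
            members = sub_samples[name]
            calls[sample_pos[members[0]], j] = 1   # one het: polymorphic, nowhere else
    for name, k in cfg.planted_fixed_private.items():
        idx = take(k)
        planted_idx.update(idx)
        fixed_private_loci[name] = [locus_ids[j] for j in idx]
        for j in idx:
            calls[:, j] = 0
            for s in sub_samples[name]:
                calls[sample_pos[s], j] = 2        # fixed for an allele absent elsewhere

    if exact:
        _repair_natural_privates(
            calls, sample_ids, locus_ids, sheet, sample_pos, planted_idx
        )

    g = GenotypeMatrix(sample_ids, locus_ids, calls)
    truth = SimTruth(
        ancestral_freq=p_anc,
        subspecies_freq=sub_freq,
        group_freq=group_freq,
        admixture_source=admix_source,
        private_loci=private_loci,
        fixed_private_loci=fixed_private_loci,
    )
    return g, sheet, truth


def headline_config(seed: int, n_loci: int = 1000) -> SimConfig:
    """The canonical taxon-exclusion scenario: planted group topology
    ((A,M),(C,O)), three divergent outgroup taxa, and one A/M-admixed,
    strongly drifted subspecies ("adm") carried in group A.

    Three diploids per subspecies and one per outgroup species keep the
    bootstrap workload desk-sized while leaving the placement signal intact.
    """
    return SimConfig(
        seed=seed,
        n_loci=n_loci,
        admixture=AdmixtureSpec(
            name="adm", source_groups=("A", "M"), alpha=0.5, assigned_group="A"
        ),
        samples_per_subspecies=3,
        samples_per_outgroup=1,
    )


def _repair_natural_privates(
    calls: np.ndarray,
    sample_ids: list[str],
    locus_ids: list[str],
    sheet: SampleSheet,
    sample_pos: Mapping[str, int],
    planted_idx: set[int],
) -> None:
    """Remove chance private / fixed-private loci so planted counts are exact.

    Any non-planted locus that is private or fixed-private in some ingroup
    unit (at subspecies or group level) gets one heterozygous call added in
    the first subspecies of a different lineage group, making the locus
    polymorphic in two groups and therefore private nowhere.
    """
    from .genotypes import _classify_all

    g = GenotypeMatrix(list(sample_ids), list(locus_ids), calls.copy())
    sub_names = sheet.subspecies
    sub_group = {
        name: sheet.group_of(sheet.samples_of_subspecies(name)[0]) for name in sub_names
    }
    triggers: dict[int, str] = {}   # locus index -> group of the triggering unit
    for level in ("subspecies", "group"):
        res = _classify_all(g, sheet, level)
        names = list(sheet.units(level))
        outg = set(sheet.outgroup_species)
        flagged = res["private"] | res["fixed_private"]
        for k, name in enumerate(names):
            if name in outg:
                continue
            gp = sub_group[name] if level == "subspecies" else name
            for j in np.flatnonzero(flagged[k]):
                if j not in planted_idx:
                    triggers.setdefault(int(j), gp)
    for j, gp in triggers.items():
        target = next(name for name in sub_names if sub_group[name] != gp)
        calls[sample_pos[sheet.samples_of_subspecies(target)[0]], j] = 1


def apply_ascertainment(
    g: GenotypeMatrix,
    truth: SimTruth,
    sheet: SampleSheet,
    panel_subspecies: Sequence[str],
    min_minor_count: int = 1,
) -> GenotypeMatrix:
    """Keep loci whose minor-allele count within the discovery panel reaches
    ``min_minor_count`` — emulating SNP discovery restricted to an
    unrepresentative (e.g. European) panel.  Updates ``truth.retained_mask``.
    """
    if not panel_subspecies:
        raise ValueError("empty ascertainment panel")
    samples: list[str] = []
    for name in panel_subspecies:
        samples.extend(sheet.samples_of_subspecies(name))
    calls = g.calls[g.sample_index(samples)].astype(float)
    calls[calls == MISSING] = np.nan
    alt = np.nansum(calls, axis=0)
    tot = 2.0 * (~np.isnan(calls)).sum(axis=0)
    minor = np.minimum(alt, tot - alt)
    keep = minor >= min_minor_count
    if not keep.any():
        raise ValueError("ascertainment filter removed all loci")
    truth.retained_mask = keep
    return g.subset_loci(np.flatnonzero(keep))
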