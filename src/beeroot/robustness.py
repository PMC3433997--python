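"""End-to-end orchestration: bootstrap trees, consensus, compatibility
filtering and outgroup-placement tallies, with and without excluded
subspecies.

The motivating analysis asks whether the position of the root of the
honeybee subspecies tree survives removing taxa of suspected hybrid origin:
the full panel is bootstrapped, a majority-rule consensus built, replicate
trees incompatible with the consensus are collected into a second consensus,
and the attachment point of the outgroup is classified per replicate.  The
same machinery rerun after dropping chosen subspecies shows how placement
frequencies move.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .genotypes import GenotypeMatrix, SampleSheet
from .trees import (
    PlacementTally,
    UnrootedTree,
    bootstrap_trees,
    filter_compatible,
    majority_rule_consensus,
    placement_frequencies,
)


@dataclass
class AnalysisConfig:
    distance_kind: str = "allele_sharing"
    replicates: int = 100
    seed: int = 0
    excluded_subspecies: tuple[str, ...] = ()
    consensus_threshold: float = 0.5
    pool_outgroups: bool = False
    unit_level: str = "subspecies"   # used by the fst distance kind

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


@dataclass
class RobustnessReport:
    config: AnalysisConfig
    consensus: UnrootedTree
    tally_all: PlacementTally          # over all bootstrap replicates
    tally_remainder: PlacementTally | None  # over consensus-incompatible trees
    n_compatible: int
    n_remainder: int
    second_consensus: UnrootedTree | None
    redrawn_replicates: int = 0

    def to_dict(self) -> dict:
        return {
            "config": {
                "distance_kind": self.config.distance_kind,
                "replicates": self.config.replicates,
                "seed": self.config.seed,
                "excluded_subspecies": list(self.config.excluded_subspecies),
                "consensus_threshold": self.config.consensus_threshold,
                "pool_outgroups": self.config.pool_outgroups,
            },
            "consensus_newick": self.consensus.to_newick(),
            "placement_fractions_all": self.tally_all.fractions,
            "placement_fractions_remainder": (
                self.tally_remainder.fractions if self.tally_remainder else None
            ),
            "modal_placement": self.tally_all.modal_category,
            "n_compatible": self.n_compatible,
            "n_remainder": self.n_remainder,
            "second_consensus_newick": (
                self.second_consensus.to_newick() if self.second_consensus else None
            ),
            "redrawn_replicates": self.redrawn_replicates,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_exclusion_analysis(
    g: GenotypeMatrix, sheet: SampleSheet, cfg: AnalysisConfig
) -> RobustnessReport:
    """Drop the configured subspecies, bootstrap, build consensus, filter and
    tally outgroup placements.  Deterministic given the seed; the same base
    seed is used whatever the exclusion list, so the locus resampling is
    shared between baseline and exclusion runs (common random numbers).
    """
    if cfg.excluded_subspecies:
        sheet_x = sheet.drop_subspecies(cfg.excluded_subspecies)
        g_x = g.subset_samples(list(sheet_x.table["sample"]))
    else:
        sheet_x, g_x = sheet, g
    for gp in sheet.ingroup_groups():
        if not sheet_x.samples_of_group(gp):
            raise ValueError(f"exclusion empties lineage group {gp}")
    if not sheet_x.outgroup_samples:
        raise ValueError("exclusion leaves no outgroup sample")

    trees, redrawn = bootstrap_trees(
        g_x,
        sheet_x,
        distance_kind=cfg.distance_kind,
        R=cfg.replicates,
        seed=cfg.seed,
        level=cfg.unit_level,
        pool_outgroups=cfg.pool_outgroups,
    )
    consensus = majority_rule_consensus(trees, threshold=cfg.consensus_threshold)
    compat, remainder, second = filter_compatible(trees, consensus)
    tally_all = placement_frequencies(trees, sheet_x)
    tally_rem = placement_frequencies(remainder, sheet_x) if remainder else None
    return RobustnessReport(
        config=cfg,
        consensus=consensus,
        tally_all=tally_all,
        tally_remainder=tally_rem,
        n_compatible=len(compat),
        n_remainder=len(remainder),
        second_consensus=second,
        redrawn_replicates=redrawn,
    )


def compare_reports(r1: RobustnessReport, r2: RobustnessReport) -> dict:
    """Structured diff: per-category placement-fraction deltas and the
    consensus splits unique to either run (restricted to shared leaves)."""
    f1, f2 = r1.tally_all.fractions, r2.tally_all.fractions
    deltas = {k: f2[k] - f1[k] for k in f1}
    leaves1 = set(r1.consensus.leaf_labels)
    leaves2 = set(r2.consensus.leaf_labels)
    shared = leaves1 & leaves2

    def restricted(t: UnrootedTree) -> set[frozenset[str]]:
        out = set()
        for s in t.splits():
            r = frozenset(s & shared)
            if 1 < len(r) < len(shared) - 1:
                out.add(min(r, frozenset(shared) - r, key=sorted))
        return out

    s1, s2 = restricted(r1.consensus), restricted(r2.consensus)
    return {
        "fraction_deltas": deltas,
        "modal_change": (r1.tally_all.modal_category, r2.tally_all.modal_category),
        "splits_only_in_first": sorted(sorted(s) for s in s1 - s2),
        "splits_only_in_second": sorted(sorted(s) for s in s2 - s1),
        "shared_splits": len(s1 & s2),
    }
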