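"""Root-placement robustness under taxon exclusion.

The headline experiment: a panel with a hybrid-origin, strongly drifted
subspecies ("adm", A/M-admixed, carried in group A) is bootstrapped twice —
once as is, once with the hybrid excluded — and the outgroup-placement
tallies are compared.  The hybrid's long terminal branch captures the
outgroup, rooting the tree inside group A; removing it releases the root
to competing positions.
"""

import beeroot as br

g, sheet, _ = br.simulate_panel(br.headline_config(seed=0))

base = br.run_exclusion_analysis(
    g, sheet, br.AnalysisConfig(replicates=100, seed=0)
)
excl = br.run_exclusion_analysis(
    g, sheet, br.AnalysisConfig(replicates=100, seed=0,
                                excluded_subspecies=("adm",))
)

for label, rep in (("with adm", base), ("without adm", excl)):
    print(f"{label}: modal outgroup placement = {rep.tally_all.modal_category}")
    for cat, frac in rep.tally_all.fractions.items():
        if frac:
            print(f"    {cat:20s} {100 * frac:5.1f}%")
    print(f"    consensus-incompatible replicates: {rep.n_remainder}/100")

diff = br.compare_reports(base, excl)
print("\nmodal change:", " -> ".join(diff["modal_change"]))
print(
    "\nWith the hybrid included the root sits inside group A; once it is "
    "excluded the replicates scatter over positions adjacent to the "
    "central A+M | C+O edge — the rooting was carried by one taxon."
)
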