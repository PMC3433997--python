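"""Sample-size-corrected diversity (Watterson's theta) per subspecies.

theta_W = S / a_n, with S the number of loci segregating in the unit and
a_n the harmonic number of (chromosomes - 1); the correction makes units
with different sample sizes comparable.
"""

import beeroot as br

g, sheet, _ = br.simulate_panel(br.SimConfig(seed=2, n_loci=1000))

print(f"{'subspecies':10s} {'group':>5s} {'S':>5s} {'n_chr':>6s} {'theta':>9s} {'per locus':>10s}")
for name in sheet.subspecies:
    est = br.watterson_theta(g, sheet, name)
    gp = sheet.group_of(sheet.samples_of_subspecies(name)[0])
    print(f"{name:10s} {gp:>5s} {est.S:5d} {est.n_chrom:6d} "
          f"{est.theta:9.2f} {est.theta_per_locus:10.4f}")

print(
    "\nS is the segregating-locus count, n_chr the chromosomes sampled "
    "(2 per diploid), theta the corrected diversity.  With equal drift per "
    "group the estimates are comparable across subspecies; on a SNP panel "
    "theta has no per-base-pair scale, so only relative levels matter."
)
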