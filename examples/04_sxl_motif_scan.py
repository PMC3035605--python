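"""Scan 3'UTRs for SXL consensus sites and tally predicted targets.

The SXL protein binds poly-U stretches (AUUUUUUU or UUUUUUUU).  A
transcript whose 3'UTR carries three or more sites is flagged as a
predicted SXL target; in the fly genome such targets are strongly
enriched on the X, consistent with a role for SXL in early zygotic
dosage compensation.  The simulated UTRs plant sites with an X bias.
"""

from ezdc.motif import count_sxl_sites, flag_targets
from ezdc.simulate import SimConfig, simulate_utrs

utrs = simulate_utrs(SimConfig(n_genes=2000, seed=23))
per_gene, tally = flag_targets(utrs, min_sites=3)

print(f"scanned {len(per_gene)} 3'UTRs")
print(f"predicted SXL targets (>= 3 sites): {per_gene['flagged'].sum()}")
print("flagged genes per arm:")
print(tally.to_string())
x_frac = tally.get("X", 0) / per_gene["flagged"].sum()
print(f"-> {x_frac:.0%} of predicted targets are X-linked")

print("\ncounting conventions on a 9-U run:")
print("  greedy non-overlapping:", count_sxl_sites("UUUUUUUUU"))
print("  overlapping:           ", count_sxl_sites("UUUUUUUUU", overlapping=True))
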