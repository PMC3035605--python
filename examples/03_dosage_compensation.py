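"""Score early zygotic dosage compensation on the X chromosome.

X-linked genes are simulated with per-gene F:M targets uniform on
[1.0, 2.0] (1.0 = fully compensated, 2.0 = uncompensated single male X).
The compensation score is the through-origin least-squares slope of
female on male replicate-averaged stage levels, computed for every
zygotic gene with max normalized RPKM > 3.0.
"""

import numpy as np

from ezdc.classify import ClassifyConfig, classify_all
from ezdc.dosage import chrom_aggregate, fm_ratio, score_summary, score_table
from ezdc.partition import normalize_autosomal, partition_rpkm
from ezdc.simulate import SimConfig, simulate_timecourse
from ezdc.stages import CYCLE14_STAGES

cfg = SimConfig(n_genes=3000, seed=19)
expr, counts, truth = simulate_timecourse(cfg)
expr = normalize_autosomal(expr)
part = partition_rpkm(expr, counts)
classes, _ = classify_all(part, expr, counts, ClassifyConfig())

scores = score_table(expr, classes)
print("compensation scores by arm (slope of F on M; 1.0 = compensated):")
print(score_summary(scores).to_string())

x = scores[scores["chrom"] == "X"]["score"]
auto = scores[scores["chrom"] != "X"]["score"]
print(f"\nX:         mean {x.mean():.2f}, median {x.median():.2f}")
print(f"autosomes: mean {auto.mean():.2f}, median {auto.median():.2f}")
print("-> X scores sit between 1 and 2; autosomal scores center on 1")

ratios = fm_ratio(expr, classes, min_rpkm=2.0, stages=CYCLE14_STAGES)
print(f"\nmedian cycle-14 F:M ratio, X genes: {np.nanmedian(ratios.loc[expr.genes['chrom'] == 'X'].to_numpy()):.2f}")

agg = chrom_aggregate(part, expr, classes).set_index(["chrom", "sex", "stage", "origin"])["value"]
print(f"female X at 14D   maternal {agg[('X','F','14D','maternal')]:.0f}  paternal {agg[('X','F','14D','paternal')]:.0f}")
print(f"male X at 14D     total    {agg[('X','M','14D','total')]:.0f}")
print("-> the single male X outproduces either female X: the early embryo is dosage compensated")
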