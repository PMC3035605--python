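"""Shared fixtures: small synthetic datasets and the default study run.

The expensive default-design run (full gene count, clustering and
classification) is computed once per session and shared by the tests
that grade recovery against the generator's ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ezdc.classify import classify_all
from ezdc.partition import normalize_autosomal, partition_rpkm
from ezdc.simulate import SimConfig, simulate_timecourse


@pytest.fixture(scope="session")
def default_run():
    """Full default-design simulation, normalized, partitioned, classified."""
    cfg = SimConfig(seed=1)
    expr, counts, truth = simulate_timecourse(cfg)
    expr_n = normalize_autosomal(expr)
    part = partition_rpkm(expr_n, counts)
    classes, model = classify_all(part, expr_n, counts)
    return {
        "cfg": cfg,
        "expr": expr,
        "expr_n": expr_n,
        "counts": counts,
        "truth": truth,
        "part": part,
        "classes": classes,
        "model": model,
    }


@pytest.fixture(scope="session")
def small_timecourse():
    """A fast 600-gene simulation for structural checks."""
    cfg = SimConfig(n_genes=600, seed=42)
    expr, counts, truth = simulate_timecourse(cfg)
    return cfg, expr, counts, truth


def toy_expression(rpkm: dict, chrom: dict, samples: pd.DataFrame):
    """Assemble an ExpressionData from plain dicts (tests' shorthand)."""
    from ezdc.containers import ExpressionData

    rpkm_df = pd.DataFrame(rpkm)
    genes = pd.DataFrame(
        {"chrom": pd.Series(chrom), "length": 1000}
    ).loc[rpkm_df.index]
    return ExpressionData(rpkm=rpkm_df, genes=genes, samples=samples)


def design_samples():
    """The 24-sample study design sheet."""
    from ezdc.simulate import sample_sheet

    return sample_sheet(SimConfig())
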