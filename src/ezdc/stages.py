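"""The common developmental time axis and sample-design constants.

The time course spans interphases of mitotic cycles 10-13 and the four
cellularization substages of cycle 14 (25% membrane-invagination bins),
ordered C10 < C11 < C12 < C13 < 14A < 14B < 14C < 14D.  All kinetic models
in this package are parameterized on the integer stage index t = 0..7;
no wall-clock times are attached to stages.
"""

from __future__ import annotations

STAGES: tuple[str, ...] = ("C10", "C11", "C12", "C13", "14A", "14B", "14C", "14D")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: embryos sequenced per (sex, stage): one per sex at cycles 10-13, two per
#: sex at each cycle-14 substage -> 12 female + 12 male = 24 samples.
REPLICATES: tuple[int, ...] = (1, 1, 1, 1, 2, 2, 2, 2)

SEXES: tuple[str, str] = ("F", "M")

#: chromosome arms; "X" is the sex chromosome, the rest are autosomal arms.
ARMS: tuple[str, ...] = ("X", "2L", "2R", "3L", "3R")
CYCLE14_STAGES: tuple[str, ...] = ("14A", "14B", "14C", "14D")


def is_x(arm) -> bool:
    """True for the X chromosome arm (vectorized over pandas/numpy inputs)."""
    import numpy as np

    return np.asarray(arm) == "X"


def stage_sorted(stages) -> list[str]:
    """Sort stage labels into developmental order; unknown labels raise."""
    try:
        return sorted(stages, key=STAGE_INDEX.__getitem__)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"unknown stage label {e.args[0]!r}") from e
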