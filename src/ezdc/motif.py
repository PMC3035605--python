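"""SXL consensus-site scanning in 3'UTR sequences.

The SXL protein binds poly-U stretches; the consensus used here is
AUUUUUUU or UUUUUUUU (8 nt).  Counting is case-insensitive, T and U are
equivalent, and by default matches are non-overlapping, taken greedily
left to right (a "site" is a bound protein footprint); an overlapping
convention is available since published tallies do not state one.
Transcripts whose 3'UTR carries three or more sites are flagged as
predicted SXL targets.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["count_sxl_sites", "flag_targets"]

_VALID = set("ACGTUN")
_SITE_LEN = 8


def _is_site(window: str) -> bool:
    return len(window) == _SITE_LEN and window[0] in "AU" and window[1:] == "U" * 7


def count_sxl_sites(sequence: str, overlapping: bool = False) -> int:
    """Number of SXL consensus sites (AUUUUUUU or UUUUUUUU) in a sequence.

    Greedy left-to-right non-overlapping scan by default; with
    ``overlapping=True`` every matching start position counts.  The
    sequence may use DNA or RNA alphabet (T==U), any case; N never
    matches; other characters raise ValueError.
    """
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid sequence character(s): {sorted(bad)}")
    n, i, hits = len(seq), 0, 0
    while i <= n - _SITE_LEN:
        if _is_site(seq[i : i + _SITE_LEN]):
            hits += 1
            i += 1 if overlapping else _SITE_LEN
        else:
            i += 1
    return hits


def flag_targets(
    utrs: pd.DataFrame,
    min_sites: int = 3,
    overlapping: bool = False,
) -> tuple[pd.DataFrame, pd.Series]:
    """Predicted SXL targets and their per-arm tally.

    ``utrs`` is indexed by gene_id with columns ``arm`` and ``sequence``
    (one row per transcript UTR; a gene appearing multiple times is
    scored by its maximum site count).  Returns ``(per_gene, tally)``:
    per-gene table gene_id, arm, n_sites, flagged (n_sites >= min_sites),
    and the count of flagged genes per chromosome arm.
    """
    counts = utrs["sequence"].map(lambda s: count_sxl_sites(s, overlapping=overlapping))
    per_gene = (
        pd.DataFrame({"arm": utrs["arm"], "n_sites": counts})
        .groupby(level=0)
        .agg(arm=("arm", "first"), n_sites=("n_sites", "max"))
    )
    per_gene["flagged"] = per_gene["n_sites"] >= min_sites
    tally = per_gene.loc[per_gene["flagged"]].groupby("arm").size()
    tally = tally.rename("n_flagged")
    return per_gene, tally
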