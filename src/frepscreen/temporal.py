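"""Responder-group classification of FRep-score time courses.

Genes are classified by when their knockdown increases reporter condensation
over a heat-shock time course (0, 10, 30 and 60 minutes at 42C):

* ``basal`` — hit only at steady state: score > 2 at 0 min and below 3 at
  every heated timepoint (the asymmetric cap is deliberate and configurable);
* ``sustained`` — score > 2 at all four timepoints;
* ``early`` — below 2 at 0 min, above 2 at 10, 30 and 60 min;
* ``time_dependent`` — strictly increasing across all consecutive timepoint
  pairs with a final score > 2;
* ``other`` — none of the above.

The printed rules overlap (a sustained gene with scores below 3 also
satisfies the basal rule; an early gene with rising scores also satisfies the
time-dependent rule), so labels are assigned in a precedence order that
prefers the stronger phenotype: sustained > basal > early > time_dependent.
All comparisons are strict, so scores exactly at a threshold fail it.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

LABELS = ("basal", "sustained", "early", "time_dependent", "other")
TIMEPOINTS = (0, 10, 30, 60)
SCORE_COLUMNS = tuple(f"frep_{m}" for m in TIMEPOINTS)
DEFAULT_PRECEDENCE = ("sustained", "basal", "early", "time_dependent")


def classify_trajectory(
    scores: Sequence[float],
    hit: float = 2.0,
    basal_cap: float = 3.0,
    precedence: Iterable[str] = DEFAULT_PRECEDENCE,
) -> str:
    """Label one gene's (0, 10, 30, 60)-minute FRep-score trajectory."""
    values = [float(x) for x in scores]
    if len(values) != len(TIMEPOINTS):
        raise ValueError(f"expected {len(TIMEPOINTS)} scores, got {len(values)}")
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"scores must be finite, got {values}")
    precedence = tuple(precedence)
    if sorted(precedence) != sorted(set(LABELS) - {"other"}):
        raise ValueError(
            f"precedence must order {sorted(set(LABELS) - {'other'})}, "
            f"got {precedence}"
        )
    s0, s10, s30, s60 = values
    rules = {
        "sustained": all(v > hit for v in values),
        "basal": s0 > hit and s10 < basal_cap and s30 < basal_cap and s60 < basal_cap,
        "early": s0 < hit and s10 > hit and s30 > hit and s60 > hit,
        "time_dependent": (
            (s10 - s0) > 0 and (s30 - s10) > 0 and (s60 - s30) > 0 and s60 > hit
        ),
    }
    for name in precedence:
        if rules[name]:
            return name
    return "other"


def classify_all(
    table: pd.DataFrame,
    hit: float = 2.0,
    basal_cap: float = 3.0,
    precedence: Iterable[str] = DEFAULT_PRECEDENCE,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Label every gene in a wide score table and tally the groups.

    ``table`` must carry columns ``frep_0 frep_10 frep_30 frep_60`` (genes as
    index or in a ``gene`` column).  Genes with any missing score are labeled
    ``other`` and flagged ``missing_scores``.  Returns the labeled table and
    per-group counts covering all five labels.
    """
    out = table.copy()
    if "gene" in out.columns:
        out = out.set_index("gene")
    missing_cols = [c for c in SCORE_COLUMNS if c not in out.columns]
    if missing_cols:
        raise ValueError(f"score table missing columns: {missing_cols}")

    labels: list[str] = []
    flags: list[str] = []
    for row in out[list(SCORE_COLUMNS)].itertuples(index=False):
        values = list(row)
        if any(pd.isna(v) for v in values):
            labels.append("other")
            flags.append("missing_scores")
        else:
            labels.append(classify_trajectory(values, hit, basal_cap, precedence))
            flags.append("")
    out["label"] = labels
    out["flag"] = flags
    counts = {name: 0 for name in LABELS}
    for lab in labels:
        counts[lab] += 1
    return out, counts
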