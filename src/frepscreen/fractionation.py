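"""Transcriptome-wide condensation and translation scoring, and qPCR -ddCt.

Sedimentation RNA-seq compares a transcript's abundance in the 20,000 g
condensate-enriched pellet against the total lysate: the condensation score
is the size-factor-normalized log2(pellet/total) ratio.  Because longer
transcripts partition into condensates regardless of stress, raw scores are
standardized within bins of 100 length-sorted transcripts (the length-binned
z-score); the change between heat shock and steady state (delta z) isolates
stress-dependent behavior.  Ribosome-association scores apply the same ratio
to a ribosomal fraction as a translation proxy.  Group contrasts (e.g.
Hsf1-regulon vs background) use the two-sample Wilcoxon rank-sum test with
Bonferroni correction.  The -ddCt calculator reproduces the qPCR readout:
pellet-vs-total delta-Ct of a target normalized to a reference gene, on the
same log2 pellet-enrichment scale (+1 = 2-fold pellet-enriched).
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
from scipy import stats

from .samples import parse_sample_name, sample_name
from .scoring import absolute_size_factors, normalized_log2_ratio


# ---------------------------------------------------------------------------
# condensation / ribosome-association scores
# ---------------------------------------------------------------------------


def condensation_score(
    total_counts: pd.Series,
    pellet_counts: pd.Series,
    sf_total: float,
    sf_pellet: float,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-transcript log2(pellet/total) after size-factor normalization."""
    score = normalized_log2_ratio(
        pellet_counts, total_counts, sf_pellet, sf_total, pseudocount
    )
    score.name = "condensation_log2fc"
    return score


def ribosome_association_score(
    total_counts: pd.Series,
    ribosome_counts: pd.Series,
    sf_total: float,
    sf_ribosome: float,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-transcript log2(ribosome/total): translational engagement proxy."""
    score = normalized_log2_ratio(
        ribosome_counts, total_counts, sf_ribosome, sf_total, pseudocount
    )
    score.name = "ribosome_log2fc"
    return score


# ---------------------------------------------------------------------------
# length-binned z-scores
# ---------------------------------------------------------------------------


def length_bin_zscore(
    scores: pd.Series,
    lengths: pd.Series,
    bin_size: int = 100,
    min_tail: int = 10,
) -> pd.DataFrame:
    """Standardize scores within bins of ``bin_size`` length-sorted transcripts.

    Transcripts are sorted by length (ties broken by identifier for
    determinism) and cut into consecutive bins of ``bin_size``; a final
    partial bin smaller than ``min_tail`` is merged into the previous bin.
    Within each bin z = (score - mean) / sd with the n-1 denominator; a
    zero-variance bin yields z = 0 for its members and a
    ``zero_variance_bin`` flag.

    Returns a frame aligned to the input index with ``bin_index``, ``z`` and
    ``flag`` columns.
    """
    if not scores.index.equals(lengths.index):
        raise ValueError("scores and lengths must share an index")
    n = len(scores)
    if n < 2:
        raise ValueError("need at least 2 transcripts")
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    values = scores.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("scores must be finite")

    order = np.lexsort((scores.index.to_numpy(), lengths.to_numpy()))
    starts = list(range(0, n, bin_size))
    ends = [min(s + bin_size, n) for s in starts]
    if len(starts) > 1 and ends[-1] - starts[-1] < min_tail:
        ends[-2] = ends[-1]
        starts.pop()
        ends.pop()

    bin_index = np.empty(n, dtype=int)
    z = np.empty(n, dtype=float)
    flag = np.full(n, "", dtype=object)
    for b, (lo, hi) in enumerate(zip(starts, ends)):
        members = order[lo:hi]
        x = values[members]
        mean = x.mean()
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        bin_index[members] = b
        if sd > 0:
            z[members] = (x - mean) / sd
        else:
            z[members] = 0.0
            flag[members] = "zero_variance_bin"
    return pd.DataFrame(
        {"bin_index": bin_index, "z": z, "flag": flag}, index=scores.index
    )


def delta_condensation(z_hot: pd.Series, z_basal: pd.Series) -> pd.Series:
    """Elementwise z(heat shock) - z(steady state) on aligned transcripts."""
    if not z_hot.index.equals(z_basal.index):
        raise ValueError("inputs must share an index")
    out = z_hot - z_basal
    out.name = "delta_condensation_z"
    return out


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def group_comparison(
    values: pd.Series,
    group_labels: pd.Series,
    background_label: str = "background",
) -> pd.DataFrame:
    """Rank-sum test of each group against the background group.

    Two-sided Wilcoxon rank-sum (Mann-Whitney U) per non-background group
    versus background; the normal approximation with tie correction is used
    except when both groups have <= 12 members and no ties, where the exact
    null is enumerated.  p-values are Bonferroni-multiplied by the number of
    tested groups and capped at 1.  ``location_shift`` is the group median
    minus the background median.  Empty groups (unused categorical levels)
    are kept with a ``skipped_empty`` flag.
    """
    if not values.index.equals(group_labels.index):
        raise ValueError("values and group_labels must share an index")
    background = values[group_labels == background_label].to_numpy(dtype=float)
    if background.size == 0:
        raise ValueError(f"background group {background_label!r} is empty")
    if hasattr(group_labels, "cat"):
        levels = [g for g in group_labels.cat.categories if g != background_label]
    else:
        levels = [g for g in pd.unique(group_labels) if g != background_label]

    rows = []
    tested = [g for g in levels if (group_labels == g).any()]
    n_tests = max(len(tested), 1)
    for group in levels:
        x = values[group_labels == group].to_numpy(dtype=float)
        if x.size == 0:
            rows.append((group, 0, np.nan, np.nan, np.nan, np.nan, "skipped_empty"))
            continue
        pooled = np.concatenate([x, background])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (len(x) <= 12 and len(background) <= 12 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, background, alternative="two-sided", method=method)
        p_adj = min(1.0, float(res.pvalue) * n_tests)
        shift = float(np.median(x) - np.median(background))
        rows.append(
            (group, len(x), float(res.statistic), float(res.pvalue), p_adj, shift, "")
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group", "n", "statistic", "p_raw", "p_bonferroni",
            "location_shift", "flag",
        ],
    )


# ---------------------------------------------------------------------------
# fractionation table pipeline
# ---------------------------------------------------------------------------


def pool_replicates(counts: pd.DataFrame) -> pd.DataFrame:
    """Sum replicate columns into one column per (background, temp, min, fraction).

    Columns already in pooled (4-field) form pass through unchanged; any
    ``length`` column is preserved in front.
    """
    pooled: dict[str, pd.Series] = {}
    length = counts["length"] if "length" in counts.columns else None
    for col in counts.columns:
        if col == "length":
            continue
        info = parse_sample_name(col)
        key = sample_name(info.background, info.temperature_c, info.minutes, info.fraction)
        if key in pooled:
            pooled[key] = pooled[key] + counts[col]
        else:
            pooled[key] = counts[col].copy()
    out = pd.DataFrame(pooled, index=counts.index)
    if length is not None:
        out.insert(0, "length", length)
    return out


def analyze_fractionation(
    counts: pd.DataFrame,
    *,
    background: str = "WT",
    conditions: tuple[tuple[int, int], tuple[int, int]] = ((30, 0), (42, 30)),
    bin_size: int = 100,
    pseudocount: float = 0.5,
    reference_depth: float | None = 2_000_000.0,
    min_common: int = 50,
) -> pd.DataFrame:
    """Condensation / ribosome scoring of a fractionated transcript table.

    ``counts`` holds a ``length`` column plus sample columns in the standard
    naming scheme (replicate-level columns are pooled by summation first).
    For each condition the pellet/total log2 ratio is computed with jointly
    estimated size factors, then standardized within length bins; the delta
    column contrasts the second condition against the first.  Ribosome
    fractions, when present, are scored the same way without binning.
    """
    if "length" not in counts.columns:
        raise ValueError("counts must carry a 'length' column")
    pooled = pool_replicates(counts)
    lengths = pooled["length"]
    samples = pooled.drop(columns=["length"])
    factors = absolute_size_factors(samples, reference_depth, min_common)

    out = pd.DataFrame(index=pooled.index)
    out["length"] = lengths
    z_cols: list[str] = []
    ribo_cols: list[str] = []
    for temp, minutes in conditions:
        tcol = sample_name(background, temp, minutes, "total")
        pcol = sample_name(background, temp, minutes, "pellet")
        for col in (tcol, pcol):
            if col not in samples.columns:
                raise ValueError(
                    f"missing sample column {col!r}; expected "
                    f"'<background>_<tempC>_<minutes>_<fraction>[_rep<k>]' columns"
                )
        score = condensation_score(
            samples[tcol], samples[pcol], factors[tcol], factors[pcol], pseudocount
        )
        zed = length_bin_zscore(score, lengths, bin_size=bin_size)
        out[f"condensation_{temp}"] = score
        out["bin_index"] = zed["bin_index"]
        out[f"condensation_z_{temp}"] = zed["z"]
        z_cols.append(f"condensation_z_{temp}")
        rcol = sample_name(background, temp, minutes, "ribosome")
        if rcol in samples.columns:
            out[f"ribosome_{temp}"] = ribosome_association_score(
                samples[tcol], samples[rcol], factors[tcol], factors[rcol], pseudocount
            )
            ribo_cols.append(f"ribosome_{temp}")
    if len(z_cols) == 2:
        out["delta_condensation_z"] = out[z_cols[1]] - out[z_cols[0]]
    if len(ribo_cols) == 2:
        out["delta_ribosome"] = out[ribo_cols[1]] - out[ribo_cols[0]]
    return out


# ---------------------------------------------------------------------------
# qPCR -ddCt condensation
# ---------------------------------------------------------------------------

_CT_COLUMN = re.compile(r"^ct\d+$")


def ddct_condensation(
    ct_table: pd.DataFrame,
    reference_gene: str = "ACT1",
    reference_strain: str | None = None,
) -> pd.DataFrame:
    """Condensation from qPCR Ct values: -ddCt of pellet vs total, vs a reference gene.

    Per well the median Ct over technical replicates (columns ``ct1``,
    ``ct2``, ...) is used.  For each (target, condition, strain):
    dCt_f = Ct_target,f - Ct_reference,f for both fractions, and
    condensation = -(dCt_pellet - dCt_total), i.e. log2 pellet enrichment of
    the target relative to the reference gene.  With ``reference_strain``
    set, per-strain condensation is additionally re-expressed relative to
    that strain (``condensation_vs_reference`` and its linear
    ``fold_vs_reference`` = 2^difference).
    """
    required = ("target", "fraction", "condition", "strain")
    missing = [c for c in required if c not in ct_table.columns]
    if missing:
        raise ValueError(f"ct_table missing columns: {missing}")
    ct_cols = [c for c in ct_table.columns if _CT_COLUMN.match(c)]
    if not ct_cols:
        raise ValueError("ct_table needs at least one ct<k> column")
    values = ct_table[ct_cols].to_numpy(dtype=float)
    if not (np.isfinite(values).all() and (values > 0).all()):
        raise ValueError("Ct values must be finite and > 0")

    wells = ct_table.copy()
    wells["ct_median"] = np.median(values, axis=1)
    pivot = wells.pivot_table(
        index=["target", "condition", "strain"],
        columns="fraction",
        values="ct_median",
        aggfunc="median",
    )

    rows = []
    for (target, condition, strain), row in pivot.iterrows():
        if target == reference_gene:
            continue
        for fraction in ("pellet", "total"):
            if fraction not in row.index or pd.isna(row[fraction]):
                raise ValueError(
                    f"missing {fraction} well for ({target!r}, {condition!r}, "
                    f"{strain!r})"
                )
        ref_key = (reference_gene, condition, strain)
        if ref_key not in pivot.index:
            raise ValueError(
                f"missing reference gene {reference_gene!r} wells for "
                f"({target!r}, {condition!r}, strain {strain!r})"
            )
        ref = pivot.loc[ref_key]
        for fraction in ("pellet", "total"):
            if fraction not in ref.index or pd.isna(ref[fraction]):
                raise ValueError(
                    f"missing reference {fraction} well for ({target!r}, "
                    f"{condition!r}, strain {strain!r})"
                )
        dct_pellet = row["pellet"] - ref["pellet"]
        dct_total = row["total"] - ref["total"]
        condensation = -(dct_pellet - dct_total)
        rows.append((target, condition, strain, condensation))
    out = pd.DataFrame(
        rows, columns=["target", "condition", "strain", "condensation"]
    )

    if reference_strain is not None:
        ref_rows = out[out["strain"] == reference_strain]
        if ref_rows.empty:
            raise ValueError(f"reference strain {reference_strain!r} not in table")
        baseline = ref_rows.set_index(["target", "condition"])["condensation"]
        keyed = out.set_index(["target", "condition"])
        diff = keyed["condensation"] - baseline.reindex(keyed.index)
        out["condensation_vs_reference"] = diff.to_numpy()
        out["fold_vs_reference"] = np.exp2(diff.to_numpy())
    return out
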