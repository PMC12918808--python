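"""Neighborhood-normalized scores (NNS) and gene-level FRep scores.

The FRep score quantifies how a CRISPRi knockdown changes partitioning of
the reporter mRNA between the condensate-enriched pellet fraction and total
lysate.  Per barcode, the size-factor-normalized log2(pellet/total) ratio is
standardized against the distribution of ratios among barcodes of similar
abundance (a sliding window over abundance rank, robust median/MAD center
and spread): the neighborhood-normalized score.  Positive scores mean the
knockdown increases reporter association with condensates; magnitudes are in
neighborhood standard deviations.  Barcode scores average to guide scores,
guide scores to gene scores, and replicate gene scores are combined with a
one-sample t-test against zero.

Normalization gauge.  Median-of-ratios size factors are only defined up to a
common scale; ``size_factors`` returns the conventional geometric-mean-1
factors.  The pipelines multiply them by (geometric mean of sample depths) /
``reference_depth`` so that normalized counts live on a fixed count scale:
the pseudocount and the minimum-abundance filter then have stable meaning,
and rescaling any single sample's raw counts is absorbed by its factor
exactly, leaving every downstream score bit-for-bit invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .library import GuideLibrary
from .samples import sample_name

MAD_TO_SD = 1.4826  # consistency factor: MAD -> sd under normality


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame, min_common: int = 50) -> pd.Series:
    """Median-of-ratios per-sample scale factors, geometric mean 1.

    The reference is the per-barcode geometric mean over samples, computed on
    barcodes nonzero in every sample; with fewer than ``min_common`` such
    barcodes the estimate falls back to total-count scaling.
    """
    if counts.shape[1] == 0:
        raise ValueError("count table has no samples")
    colsums = counts.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has all-zero counts")
    common = (counts > 0).all(axis=1)
    if int(common.sum()) >= min_common:
        logc = np.log(counts.loc[common].to_numpy(dtype=float))
        logref = logc.mean(axis=1)
        logf = np.median(logc - logref[:, None], axis=0)
    else:
        logf = np.log(colsums.to_numpy(dtype=float))
    logf = logf - logf.mean()
    return pd.Series(np.exp(logf), index=counts.columns, name="size_factor")


def depth_gauge(counts: pd.DataFrame) -> float:
    """Geometric mean of sample column sums (the table's depth scale)."""
    colsums = counts.sum(axis=0).to_numpy(dtype=float)
    if (colsums <= 0).any():
        raise ValueError("all samples need positive column sums")
    return float(np.exp(np.mean(np.log(colsums))))


def absolute_size_factors(
    counts: pd.DataFrame,
    reference_depth: float | None = None,
    min_common: int = 50,
) -> pd.Series:
    """Size factors pinned to a fixed count gauge.

    With ``reference_depth`` set, factors are relative factors times
    (depth gauge / reference_depth): normalized counts are then expressed at
    the reference depth, and scaling any one sample's raw counts by c scales
    exactly its own factor by c.  ``None`` keeps geometric-mean-1 factors.
    """
    factors = size_factors(counts, min_common=min_common)
    if reference_depth is not None:
        if reference_depth <= 0:
            raise ValueError("reference_depth must be > 0")
        factors = factors * (depth_gauge(counts) / reference_depth)
    return factors


def normalized_log2_ratio(
    numerator: pd.Series,
    denominator: pd.Series,
    sf_numerator: float,
    sf_denominator: float,
    pseudocount: float = 0.5,
) -> pd.Series:
    """log2((num/sf_num + pc) / (den/sf_den + pc)) on a shared index."""
    if not numerator.index.equals(denominator.index):
        raise ValueError("numerator and denominator must share an index")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    num = numerator.to_numpy(dtype=float) / float(sf_numerator) + pseudocount
    den = denominator.to_numpy(dtype=float) / float(sf_denominator) + pseudocount
    return pd.Series(np.log2(num / den), index=numerator.index)


def barcode_log_ratio(
    pellet: pd.Series,
    total: pd.Series,
    sf_pellet: float,
    sf_total: float,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-barcode pellet/total log2 ratio plus its reference abundance.

    The reference abundance — what the neighborhood is built over — is the
    arithmetic mean of the two normalized counts (the MA-plot convention).
    Using a symmetric function of both fractions keeps the null log-ratio
    distribution symmetric after abundance filtering: conditioning on the
    denominator alone truncates its lower tail and drags the ratio negative.
    """
    log_ratio = normalized_log2_ratio(pellet, total, sf_pellet, sf_total, pseudocount)
    reference = 0.5 * (
        pellet.to_numpy(dtype=float) / float(sf_pellet)
        + total.to_numpy(dtype=float) / float(sf_total)
    )
    out = pd.DataFrame(
        {"log_ratio": log_ratio, "reference_abundance": reference}, index=total.index
    )
    out.index.name = total.index.name or "barcode"
    return out


# ---------------------------------------------------------------------------
# neighborhood normalization
# ---------------------------------------------------------------------------


def neighborhood_normalize(
    rows: pd.DataFrame,
    window: int = 201,
    min_count: float = 20.0,
    scale_floor: float = 1e-8,
) -> pd.DataFrame:
    """Standardize each barcode's log ratio against its abundance neighborhood.

    Barcodes with reference abundance below ``min_count`` are dropped (their
    ratios are Poisson-noise dominated).  The rest are ordered by abundance;
    each barcode's neighborhood is a symmetric window of up to ``window``
    barcodes in that ordering, truncated at the ends.  Location is the window
    median, scale is 1.4826 x MAD floored at ``scale_floor``, and
    nns = (log_ratio - location) / scale.

    Returns the surviving rows, sorted by abundance, with ``nbhd_location``,
    ``nbhd_scale`` and ``nns`` columns added.
    """
    for col in ("log_ratio", "reference_abundance"):
        if col not in rows.columns:
            raise ValueError(f"rows must have a {col!r} column")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    kept = rows[rows["reference_abundance"] >= min_count]
    n = len(kept)
    if n < 3:
        raise ValueError(
            f"need at least 3 barcodes with reference_abundance >= {min_count}, "
            f"got {n}"
        )
    if window > n:
        raise ValueError(f"window {window} exceeds the {n} surviving barcodes")
    order = np.lexsort(
        (kept.index.to_numpy(), kept["reference_abundance"].to_numpy())
    )
    kept = kept.iloc[order].copy()
    lr = kept["log_ratio"].to_numpy(dtype=float)
    half = window // 2
    location = np.empty(n)
    scale = np.empty(n)
    for i in range(n):
        lo = 0 if i < half else i - half
        hi = min(n, i + half + 1)
        w = lr[lo:hi]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        location[i] = med
        scale[i] = max(MAD_TO_SD * mad, scale_floor)
    kept["nbhd_location"] = location
    kept["nbhd_scale"] = scale
    kept["nns"] = (lr - location) / scale
    return kept


# ---------------------------------------------------------------------------
# gene-level aggregation and replicate combination
# ---------------------------------------------------------------------------


def gene_frep_score(
    barcode_scores: pd.DataFrame,
    library: GuideLibrary,
    guide_agg: str = "mean",
    gene_agg: str = "mean",
) -> pd.Series:
    """Aggregate one replicate's barcode NNS to per-gene scores.

    Guide score = ``guide_agg`` over the guide's surviving barcodes; gene
    score = ``gene_agg`` over guides with at least one surviving barcode.
    Genes with no surviving guide are NaN.
    """
    if "nns" not in barcode_scores.columns:
        raise ValueError("barcode_scores must have an 'nns' column")
    ann = library.frame.set_index("barcode")[["guide_id", "gene"]]
    joined = barcode_scores[["nns"]].join(ann, how="inner")
    guide_scores = joined.groupby("guide_id")["nns"].agg(guide_agg)
    guide_gene = ann.drop_duplicates("guide_id").set_index("guide_id")["gene"]
    per_gene = guide_scores.groupby(guide_gene.reindex(guide_scores.index)).agg(gene_agg)
    out = per_gene.reindex(library.genes)
    out.index.name = "gene"
    out.name = "frep_score"
    return out


def combine_replicates(
    per_replicate: pd.DataFrame, p_floor: float = 1e-12
) -> pd.DataFrame:
    """Combine per-replicate gene scores with a one-sample t-test against 0.

    Input: genes x replicates.  Output columns: frep_score (mean), t_stat,
    p_value (two-sided, df = n-1), n_replicates, flag, neg_log10_p.
    Genes with < 2 replicate scores keep their mean but get no p-value
    (flag ``insufficient_replicates``); zero replicate variance floors the
    p-value at ``p_floor`` (flag ``zero_variance``).
    """
    n = per_replicate.notna().sum(axis=1)
    mean = per_replicate.mean(axis=1)
    sd = per_replicate.std(axis=1, ddof=1)

    t_stat = pd.Series(np.nan, index=per_replicate.index)
    p_value = pd.Series(np.nan, index=per_replicate.index)
    flag = pd.Series("", index=per_replicate.index, dtype=object)

    enough = n >= 2
    flag[~enough] = "insufficient_replicates"

    regular = enough & (sd > 0)
    t_vals = mean[regular] / (sd[regular] / np.sqrt(n[regular]))
    t_stat[regular] = t_vals
    p_value[regular] = 2.0 * stats.t.sf(np.abs(t_vals), df=n[regular] - 1)

    degenerate = enough & (sd == 0)
    flag[degenerate] = "zero_variance"
    t_stat[degenerate] = np.sign(mean[degenerate]) * np.inf
    t_stat[degenerate & (mean == 0)] = 0.0
    p_value[degenerate] = np.where(mean[degenerate] == 0, 1.0, p_floor)

    out = pd.DataFrame(
        {
            "frep_score": mean,
            "t_stat": t_stat,
            "p_value": p_value,
            "n_replicates": n.astype(int),
            "flag": flag,
        }
    )
    out["neg_log10_p"] = -np.log10(out["p_value"])
    out.index.name = "gene"
    return out


# ---------------------------------------------------------------------------
# screen-level pipeline
# ---------------------------------------------------------------------------


@dataclass
class ScreenScores:
    """Scored screen: per-barcode tables per replicate plus the gene table."""

    gene_table: pd.DataFrame
    per_replicate: pd.DataFrame
    barcode_scores: dict[int, pd.DataFrame]
    background: str
    temperature_c: int
    minutes: int

    @property
    def frep(self) -> pd.Series:
        return self.gene_table["frep_score"]


def score_screen(
    counts: pd.DataFrame,
    library: GuideLibrary,
    *,
    background: str = "WT",
    temperature_c: int = 30,
    minutes: int = 0,
    pseudocount: float = 0.5,
    window: int = 201,
    min_count: float = 20.0,
    scale_floor: float = 1e-8,
    reference_depth: float | None = 200_000.0,
    guide_agg: str = "mean",
    gene_agg: str = "mean",
    p_floor: float = 1e-12,
    min_common: int = 50,
) -> ScreenScores:
    """Full FRep scoring of one condition from a barcode x sample count table.

    Size factors are estimated jointly over all provided samples; each
    replicate's pellet/total pair is ratio-scored, neighborhood-normalized
    and aggregated to genes; replicates are then combined with the one-sample
    t-test.  The window shrinks automatically (staying odd) when fewer
    barcodes survive the abundance filter than the requested window.
    """
    factors = absolute_size_factors(counts, reference_depth, min_common)
    replicates = []
    rep = 1
    while True:
        pcol = sample_name(background, temperature_c, minutes, "pellet", rep)
        tcol = sample_name(background, temperature_c, minutes, "total", rep)
        if pcol in counts.columns and tcol in counts.columns:
            replicates.append((rep, pcol, tcol))
            rep += 1
        else:
            break
    if not replicates:
        pattern = sample_name(background, temperature_c, minutes, "pellet", 1)
        raise ValueError(
            f"no replicate sample pairs found; expected columns like {pattern!r} "
            f"and its matching total column"
        )

    per_rep: dict[int, pd.Series] = {}
    barcode_tables: dict[int, pd.DataFrame] = {}
    for rep, pcol, tcol in replicates:
        ratios = barcode_log_ratio(
            counts[pcol], counts[tcol], factors[pcol], factors[tcol], pseudocount
        )
        n_kept = int((ratios["reference_abundance"] >= min_count).sum())
        w = min(window, n_kept if n_kept % 2 == 1 else n_kept - 1)
        scored = neighborhood_normalize(ratios, w, min_count, scale_floor)
        barcode_tables[rep] = scored
        per_rep[rep] = gene_frep_score(scored, library, guide_agg, gene_agg)
    per_rep_df = pd.DataFrame(per_rep)
    gene_table = combine_replicates(per_rep_df, p_floor)
    return ScreenScores(
        gene_table=gene_table,
        per_replicate=per_rep_df,
        barcode_scores=barcode_tables,
        background=background,
        temperature_c=temperature_c,
        minutes=minutes,
    )


# ---------------------------------------------------------------------------
# screen-vs-screen comparison
# ---------------------------------------------------------------------------

INTERACTION_LABELS = ("shared", "aggravating", "alleviating", "neither")


@dataclass
class ScreenComparison:
    """Gene-matched comparison of two screens with interaction labels."""

    table: pd.DataFrame  # gene, score_a, score_b, label
    pearson_r: float
    hit_threshold: float
    delta_threshold: float


def compare_screens(
    scores_a: pd.Series,
    scores_b: pd.Series,
    hit_threshold: float = 2.0,
    delta_threshold: float = 1.0,
) -> ScreenComparison:
    """Correlate two screens' gene scores and label conditional interactions.

    shared: hit in both (both >= hit_threshold); aggravating: score rises by
    >= delta_threshold into hit range in screen B; alleviating: the mirror
    case in screen A; neither otherwise.
    """
    shared_genes = scores_a.dropna().index.intersection(scores_b.dropna().index)
    if len(shared_genes) < 3:
        raise ValueError(
            f"need at least 3 shared genes to compare screens, got {len(shared_genes)}"
        )
    a = scores_a.loc[shared_genes].astype(float)
    b = scores_b.loc[shared_genes].astype(float)
    r = float(stats.pearsonr(a, b).statistic)

    label = np.full(len(shared_genes), "neither", dtype=object)
    is_shared = (a >= hit_threshold) & (b >= hit_threshold)
    aggravating = ~is_shared & ((b - a) >= delta_threshold) & (b >= hit_threshold)
    alleviating = (
        ~is_shared & ~aggravating & ((a - b) >= delta_threshold) & (a >= hit_threshold)
    )
    label[is_shared.to_numpy()] = "shared"
    label[aggravating.to_numpy()] = "aggravating"
    label[alleviating.to_numpy()] = "alleviating"

    table = pd.DataFrame(
        {"score_a": a, "score_b": b, "label": label}, index=shared_genes
    )
    table.index.name = "gene"
    return ScreenComparison(
        table=table,
        pearson_r=r,
        hit_threshold=hit_threshold,
        delta_threshold=delta_threshold,
    )
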