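"""Synthetic inputs for every pipeline stage, with known ground truth.

The generators emulate the structure of a pooled CRISPRi fractionation
reporter screen in yeast: ~12 guide RNAs per gene, each guide linked to a
small number of unique 3'UTR barcodes, four biological replicates, and
paired total/pellet (condensate-enriched) fractions per sample.  Counts are
drawn from a log-normal baseline of barcode abundances pushed through a
negative-binomial observation model (variance = mu + dispersion * mu^2), the
standard noise family for pooled-screen sequencing.  Planted condensation
modulators act multiplicatively on the pellet-fraction means only, leaving
total-fraction expression untouched, so the truth channel is a pure
partitioning effect.

A separate generator produces fractionated transcriptome tables (total,
pellet and ribosome fractions at 30 and 42 degrees C) with a built-in
length-dependent condensation bias (longer transcripts sediment more,
stress or not) plus planted group shifts for heat-shock-factor-like (Hsf1),
general-stress (Msn2/4) and ribosomal-protein-gene (RPG) transcripts, and a
qPCR Ct generator for the -ddCt calculator.

All randomness flows from a single top-level seed; each operation draws from
an independent substream keyed by a fixed label, so calling operations in a
different order never changes their draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .barcodes import ReadLayout
from .library import GuideLibrary
from .samples import sample_name

# fixed substream labels (arbitrary but frozen; see module docstring)
_KEY_LIBRARY = 101
_KEY_SCREEN = 202
_KEY_READS = 303
_KEY_TRANSCRIPTOME = 404
_KEY_CT = 505

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Study-design knobs for the screen generator.

    Defaults are the screen's reference conditions: 300 genes x 12 guides x
    2 barcodes, 4 biological replicates, 2e5 expected reads per sample,
    log-normal barcode abundances (sigma=1, heavy-tailed), NB dispersion
    0.05, and 5% of genes planted as condensation modulators with a +1.5
    log2 pellet shift.
    """

    n_genes: int = 300
    guides_per_gene: int = 12
    barcodes_per_guide: int = 2
    barcode_length: int = 12
    n_replicates: int = 4
    depth_per_sample: float = 200_000.0
    abundance_logmean: float = 0.0
    abundance_logsd: float = 1.0
    nb_dispersion: float = 0.05
    frac_effect_genes: float = 0.05
    effect_logfc_mean: float = 1.5
    effect_logfc_sd: float = 0.0
    replicate_sd: float = 0.1
    background: str = "WT"
    temperature_c: int = 30
    minutes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "guides_per_gene", "barcodes_per_guide",
                     "barcode_length", "n_replicates"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.frac_effect_genes <= 1.0:
            raise ValueError("frac_effect_genes must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.depth_per_sample <= 0:
            raise ValueError("depth_per_sample must be > 0")
        if self.abundance_logsd < 0 or self.replicate_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if "_" in self.background:
            raise ValueError("background must not contain underscores")


@dataclass(frozen=True)
class GroundTruth:
    """Planted per-gene condensation effects (log2 pellet shift)."""

    effects: pd.Series  # gene -> effect_log2; exactly 0 for non-modulators
    modulators: frozenset[str]

    def effect(self, gene: str) -> float:
        return float(self.effects.get(gene, 0.0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.effects.index, "effect_log2": self.effects.to_numpy()}
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def _min_barcode_length(n_barcodes: int) -> int:
    length = 6
    while True:
        ball = 1 + 3 * length + 9 * length * (length - 1) // 2
        if 4**length >= 2 * n_barcodes * ball:
            return length
        length += 1


def simulate_guide_library(config: SimConfig) -> GuideLibrary:
    """Random guide library whose barcodes are pairwise Hamming distance >= 3.

    Distance >= 3 makes assignment with one allowed mismatch provably
    unambiguous.  Candidate barcodes are drawn uniformly and accepted greedily;
    a three-segment pigeonhole index keeps the distance check fast (any two
    barcodes closer than distance 3 must agree on a full third of the
    sequence).
    """
    rng = np.random.default_rng([config.seed, _KEY_LIBRARY])
    length = config.barcode_length
    n_bc = config.n_genes * config.guides_per_gene * config.barcodes_per_guide
    ball = 1 + 3 * length + 9 * length * (length - 1) // 2
    if 4**length < 2 * n_bc * ball:
        raise ValueError(
            f"barcode space too small: barcode_length={length} cannot hold "
            f"{n_bc} barcodes at pairwise Hamming distance >= 3; "
            f"use barcode_length >= {_min_barcode_length(n_bc)}"
        )
    cuts = (0, length // 3, 2 * length // 3, length)
    segments: list[dict[str, list[str]]] = [{}, {}, {}]
    accepted: list[str] = []
    attempts = 0
    max_attempts = 200 * n_bc + 10_000
    while len(accepted) < n_bc:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"barcode sampling did not converge; barcode_length={length} is "
                f"too small for {n_bc} barcodes at distance >= 3 "
                f"(use barcode_length >= {_min_barcode_length(n_bc)})"
            )
        cand = "".join(_BASES[rng.integers(0, 4, length)])
        near: set[str] = set()
        parts = [cand[cuts[i]: cuts[i + 1]] for i in range(3)]
        for i, part in enumerate(parts):
            near.update(segments[i].get(part, ()))
        ok = True
        for other in near:
            if sum(a != b for a, b in zip(cand, other)) < 3:
                ok = False
                break
        if not ok:
            continue
        accepted.append(cand)
        for i, part in enumerate(parts):
            segments[i].setdefault(part, []).append(cand)

    rows = []
    k = 0
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:04d}"
        for j in range(config.guides_per_gene):
            guide = f"{gene}_g{j + 1:02d}"
            for _ in range(config.barcodes_per_guide):
                rows.append((accepted[k], guide, gene, False))
                k += 1
    frame = pd.DataFrame(rows, columns=["barcode", "guide_id", "gene", "is_control"])
    return GuideLibrary(frame)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Counts with variance mu + dispersion * mu^2 (Poisson when dispersion=0)."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_screen(
    library: GuideLibrary, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Barcode x sample count table for one condition, plus the truth channel.

    For every replicate, total-fraction counts are NB draws around
    depth x relative abundance; pellet-fraction means are additionally scaled
    by 2^(effect_g + jitter), where jitter ~ N(0, replicate_sd) per gene and
    replicate models biological replicate-to-replicate wobble.
    """
    rng = np.random.default_rng([config.seed, _KEY_SCREEN])
    frame = library.frame
    n_bc = len(frame)
    genes = list(pd.unique(frame["gene"]))
    n_genes = len(genes)

    abundance = rng.lognormal(config.abundance_logmean, config.abundance_logsd, n_bc)
    rel = abundance / abundance.sum()

    n_mod = int(round(config.frac_effect_genes * n_genes))
    effects = pd.Series(0.0, index=pd.Index(genes, name="gene"))
    modulators: list[str] = []
    if n_mod > 0:
        modulators = list(rng.choice(genes, size=n_mod, replace=False))
        effects.loc[modulators] = (
            config.effect_logfc_mean
            + config.effect_logfc_sd * rng.standard_normal(n_mod)
        )
    gene_pos = {g: i for i, g in enumerate(genes)}
    gene_idx = frame["gene"].map(gene_pos).to_numpy()
    effect_bc = effects.to_numpy()[gene_idx]

    depth = config.depth_per_sample
    columns: dict[str, np.ndarray] = {}
    for rep in range(1, config.n_replicates + 1):
        jitter_gene = rng.normal(0.0, config.replicate_sd, n_genes)
        jitter_bc = jitter_gene[gene_idx]
        mu_total = depth * rel
        tname = sample_name(config.background, config.temperature_c,
                            config.minutes, "total", rep)
        columns[tname] = _nb_draw(rng, mu_total, config.nb_dispersion)
        mu_pellet = mu_total * np.exp2(effect_bc + jitter_bc)
        pname = sample_name(config.background, config.temperature_c,
                            config.minutes, "pellet", rep)
        columns[pname] = _nb_draw(rng, mu_pellet, config.nb_dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(frame["barcode"], name="barcode"))
    truth = GroundTruth(effects=effects, modulators=frozenset(modulators))
    return counts, truth


# ---------------------------------------------------------------------------
# read-level simulation
# ---------------------------------------------------------------------------


def simulate_reads(
    library: GuideLibrary,
    counts: Mapping[str, int] | pd.Series,
    layout: ReadLayout | None = None,
    error_rate: float = 0.0,
    seed: int = 0,
) -> Iterator[tuple[str, str]]:
    """Yield (read_id, sequence) pairs realising a count column exactly.

    Each read is flank5 + barcode + flank3 with i.i.d. per-base substitutions
    at ``error_rate`` (substitutions only; no indels).  Exactly sum(counts)
    reads are emitted, in barcode order, deterministically under ``seed``.
    """
    if layout is None:
        layout = ReadLayout(barcode_length=library.barcode_length)
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng([seed, _KEY_READS])
    items = counts.items() if hasattr(counts, "items") else counts
    base_index = {b: i for i, b in enumerate("ACGT")}
    read_no = 0
    chunk = 10_000
    for barcode, count in items:
        count = int(count)
        if count <= 0:
            continue
        if barcode not in library:
            raise ValueError(f"count for barcode {barcode!r} absent from library")
        template = layout.flank5 + barcode + layout.flank3
        if error_rate == 0.0:
            for _ in range(count):
                yield f"r{read_no:08d}", template
                read_no += 1
            continue
        idx_template = np.array([base_index[ch] for ch in template], dtype=np.int64)
        length = len(template)
        remaining = count
        while remaining > 0:
            n = min(chunk, remaining)
            remaining -= n
            mat = np.tile(idx_template, (n, 1))
            mask = rng.random((n, length)) < error_rate
            n_mut = int(mask.sum())
            if n_mut:
                # shift by 1..3 mod 4: uniform over the three other bases
                mat[mask] = (mat[mask] + rng.integers(1, 4, n_mut)) % 4
            for row in mat:
                yield f"r{read_no:08d}", "".join(_BASES[row])
                read_no += 1


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path) -> int:
    """Write (id, seq) pairs as 4-line FASTQ with placeholder 'I' qualities."""
    path = Path(path)
    n = 0
    with open(path, "w") as handle:
        for rid, seq in reads:
            handle.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# fractionated transcriptome simulation
# ---------------------------------------------------------------------------


def _default_group_fractions() -> dict[str, float]:
    return {"RPG": 0.02, "Hsf1": 0.02, "Msn2_4": 0.02}


def _default_cond_effects() -> dict[str, float]:
    # planted shifts of log2(pellet/total) at 42C, relative to background
    return {"RPG": 1.0, "Hsf1": -1.0, "Msn2_4": -0.5}


def _default_ribo_effects() -> dict[str, float]:
    # heat-induced transcripts stay translated; RPG transcripts shut down
    return {"RPG": -1.0, "Hsf1": 1.5, "Msn2_4": 0.5}


def _default_expr_effects() -> dict[str, float]:
    # transcriptional response at 42C (log2 expression shift)
    return {"RPG": -1.0, "Hsf1": 2.0, "Msn2_4": 1.0}


@dataclass
class TranscriptomeConfig:
    """Generator settings for fractionation RNA-seq tables.

    Condensation of transcript t under condition c is modelled on the
    log2(pellet/total) scale as

        base(c) + length_slope * (log2 len_t - mean log2 len)
                + group_effect(group_t, c) + propensity_t + eps_{t,c}

    where propensity is a stable per-transcript sedimentation tendency shared
    across conditions and eps is condition-specific noise.  The length term
    reproduces the observation that longer transcripts partition into
    condensates regardless of stress, which is the confound the length-binned
    z-score removes.
    """

    n_transcripts: int = 5000
    length_logmean: float = 7.0   # natural-log scale; median ~1100 nt
    length_logsd: float = 0.6
    group_fractions: dict[str, float] = field(default_factory=_default_group_fractions)
    length_slope: float = 1.2     # log2FC per log2(length) unit
    base_condensation_30: float = -1.0
    base_condensation_42: float = 0.0
    condensation_effects_42: dict[str, float] = field(default_factory=_default_cond_effects)
    propensity_sd: float = 0.7
    condition_sd: float = 0.5
    ribosome_base_30: float = 0.0
    ribosome_base_42: float = -1.0
    ribosome_effects_42: dict[str, float] = field(default_factory=_default_ribo_effects)
    expression_effects_42: dict[str, float] = field(default_factory=_default_expr_effects)
    abundance_logmean: float = 2.0
    abundance_logsd: float = 1.0
    nb_dispersion: float = 0.01
    depth_per_sample: float = 2_000_000.0
    n_replicates: int = 2
    background: str = "WT"
    background_group: str = "background"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 2:
            raise ValueError("n_transcripts must be >= 2")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        total = sum(self.group_fractions.values())
        if total > 1.0 + 1e-9:
            raise ValueError("group_fractions must sum to <= 1")
        if self.nb_dispersion < 0 or self.depth_per_sample <= 0:
            raise ValueError("bad count-model parameters")


_TRANSCRIPTOME_CONDITIONS = ((30, 0), (42, 30))  # (temperature C, minutes)


def simulate_fraction_transcriptome(
    config: TranscriptomeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts for total/pellet/ribosome fractions at 30C and 42C, plus truth.

    Returns ``(counts, truth)``: counts has a ``length`` column and one column
    per sample (standard naming scheme); truth records each transcript's
    group label and its realised latent condensation / ribosome-association
    log2 ratios per condition.
    """
    rng = np.random.default_rng([config.seed, _KEY_TRANSCRIPTOME])
    n = config.n_transcripts
    ids = pd.Index([f"TX{i + 1:05d}" for i in range(n)], name="transcript_id")

    lengths = np.clip(
        rng.lognormal(config.length_logmean, config.length_logsd, n), 100, None
    ).round().astype(int)

    labels = []
    for group, frac in config.group_fractions.items():
        labels.extend([group] * int(round(frac * n)))
    labels.extend([config.background_group] * (n - len(labels)))
    groups = np.array(labels, dtype=object)
    rng.shuffle(groups)

    log2len = np.log2(lengths)
    log2len_c = log2len - log2len.mean()
    propensity = rng.normal(0.0, config.propensity_sd, n)
    abundance = rng.lognormal(config.abundance_logmean, config.abundance_logsd, n)

    def group_vec(mapping: Mapping[str, float]) -> np.ndarray:
        return np.array([mapping.get(g, 0.0) for g in groups])

    cond_eff42 = group_vec(config.condensation_effects_42)
    ribo_eff42 = group_vec(config.ribosome_effects_42)
    expr_eff42 = group_vec(config.expression_effects_42)

    counts: dict[str, np.ndarray] = {}
    truth = pd.DataFrame({"group": groups, "length": lengths}, index=ids)
    for temp, minutes in _TRANSCRIPTOME_CONDITIONS:
        hot = temp == 42
        eps_c = rng.normal(0.0, config.condition_sd, n)
        eps_r = rng.normal(0.0, config.condition_sd, n)
        base_c = config.base_condensation_42 if hot else config.base_condensation_30
        base_r = config.ribosome_base_42 if hot else config.ribosome_base_30
        cond = (
            base_c
            + config.length_slope * log2len_c
            + (cond_eff42 if hot else 0.0)
            + propensity
            + eps_c
        )
        ribo = base_r + (ribo_eff42 if hot else 0.0) + propensity + eps_r
        expr = abundance * (np.exp2(expr_eff42) if hot else 1.0)
        rel = expr / expr.sum()
        truth[f"condensation_{temp}"] = cond
        truth[f"ribosome_{temp}"] = ribo
        mu_total = config.depth_per_sample * rel
        for rep in range(1, config.n_replicates + 1):
            for fraction, mu in (
                ("total", mu_total),
                ("pellet", mu_total * np.exp2(cond)),
                ("ribosome", mu_total * np.exp2(ribo)),
            ):
                name = sample_name(config.background, temp, minutes, fraction, rep)
                counts[name] = _nb_draw(rng, mu, config.nb_dispersion)

    table = pd.DataFrame(counts, index=ids)
    table.insert(0, "length", lengths)
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct simulation
# ---------------------------------------------------------------------------


@dataclass
class CtSimConfig:
    """Settings for the qPCR Ct generator: Ct = intercept - log2(abundance) + noise."""

    intercept: float = 38.0
    ct_sd: float = 0.2
    n_technical: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if self.ct_sd < 0:
            raise ValueError("ct_sd must be >= 0")


def simulate_ct_table(
    true_abundances: pd.DataFrame, config: CtSimConfig
) -> pd.DataFrame:
    """Ct table from true abundances (one row per well).

    ``true_abundances`` needs columns target, fraction, condition, strain,
    abundance (> 0).  Output repeats the keys and adds ct1..ctK columns, one
    per technical replicate, each intercept - log2(abundance) + N(0, ct_sd).
    """
    required = ("target", "fraction", "condition", "strain", "abundance")
    missing = [c for c in required if c not in true_abundances.columns]
    if missing:
        raise ValueError(f"true_abundances missing columns: {missing}")
    ab = true_abundances["abundance"].to_numpy(dtype=float)
    if not (ab > 0).all():
        raise ValueError("abundances must be > 0")
    rng = np.random.default_rng([config.seed, _KEY_CT])
    out = true_abundances.loc[:, ["target", "fraction", "condition", "strain"]].copy()
    base = config.intercept - np.log2(ab)
    for k in range(1, config.n_technical + 1):
        out[f"ct{k}"] = base + rng.normal(0.0, config.ct_sd, len(ab))
    return out
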