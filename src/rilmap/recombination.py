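"""Recombination-rate estimation (cM/Mb) with block-bootstrap intervals.

Within-scaffold rates divide the genetic span of a scaffold's markers by
its physical span. Global summaries combine mapped and unmapped portions of
the genome. Chromosome-level confidence intervals come from a block
bootstrap over scaffolds in genome order: blocks of consecutive scaffolds
with geometric lengths (mean 3) are resampled with circular wrapping, which
accommodates spatial autocorrelation of rate along a chromosome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from rilmap.linkmap import GeneticMap


@dataclass(frozen=True)
class RateSummary:
    mapped_rate: float
    unmapped_rate: float
    genomewide_rate: float


def scaffold_rates(gmap: GeneticMap, scaffold_spans: dict[str, int] | None = None) -> pd.DataFrame:
    """Per-scaffold cM/Mb point estimates from the genetic map.

    Only unbroken scaffolds carrying at least two map markers qualify. The
    genetic span is the cM range of the scaffold's markers within its
    linkage group; the physical span runs from the first window start to the
    last window end. Skipped scaffolds (single marker) are logged in the
    ``skipped`` attribute of the returned frame.
    """
    broken = set(gmap.breaks["scaffold_id"]) if len(gmap.breaks) else set()
    tab = gmap.marker_table()
    rows, skipped = [], []
    for (gid, sid), sub in tab.groupby(["group", "scaffold_id"], sort=False):
        if sid in broken:
            continue
        if len(sub) < 2:
            skipped.append(sid)
            continue
        cm = float(sub["position_cM"].max() - sub["position_cM"].min())
        bp = int(sub["end"].max() - sub["start"].min())
        rows.append((sid, gid, cm, bp, cm / (bp / 1e6)))
    out = pd.DataFrame(
        rows, columns=["scaffold_id", "group", "map_length_cM", "physical_length_bp", "rate_cM_per_Mb"]
    )
    out.attrs["skipped"] = skipped
    return out


def global_rates(
    total_map_cM: float, mapped_cM: float, mapped_bp: float, genome_bp: float
) -> RateSummary:
    """Mapped, unmapped and genome-wide recombination rates in cM/Mb.

    The unmapped rate distributes the residual map length over the genome
    outside mapped scaffolds; it is NaN when the genome is fully mapped with
    no leftover map length, and an error when leftover map length has no
    physical room.
    """
    if mapped_cM > total_map_cM:
        raise ValueError("mapped_cM exceeds total_map_cM")
    if mapped_bp > genome_bp:
        raise ValueError("mapped_bp exceeds genome_bp")
    leftover_cm = total_map_cM - mapped_cM
    leftover_bp = genome_bp - mapped_bp
    if leftover_bp <= 0:
        if leftover_cm > 0:
            raise ValueError("leftover map length with no unmapped sequence")
        unmapped = np.nan
    else:
        unmapped = leftover_cm / (leftover_bp / 1e6)
    return RateSummary(
        mapped_rate=mapped_cM / (mapped_bp / 1e6),
        unmapped_rate=unmapped,
        genomewide_rate=total_map_cM / (genome_bp / 1e6),
    )


def sample_block_lengths(mean_block: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Geometric block lengths on support {1, 2, ...} with the given mean."""
    return rng.geometric(1.0 / mean_block, size=n)


def _bootstrap_indices(n: int, mean_block: float, rng: np.random.Generator) -> np.ndarray:
    """One replicate: circularly wrapped blocks of consecutive scaffolds,
    concatenated until ≥ n and truncated to n."""
    idx_parts = []
    total = 0
    while total < n:
        m = max(1, int(np.ceil((n - total) / mean_block)))
        lengths = sample_block_lengths(mean_block, m, rng)
        starts = rng.integers(0, n, size=m)
        reps = np.repeat(starts, lengths)
        offs = np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
        idx_parts.append((reps + offs) % n)
        total += int(lengths.sum())
    return np.concatenate(idx_parts)[:n]


def block_bootstrap_ci(
    map_cM: np.ndarray,
    physical_bp: np.ndarray,
    mean_block: float = 3.0,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile block-bootstrap CI for a ratio-of-sums cM/Mb rate.

    The point estimate is Σ cM / Σ Mb over the scaffolds in genome order;
    each replicate resamples geometric blocks (mean ``mean_block``) of
    consecutive scaffolds with circular wrapping and recomputes the ratio.
    Returns (point, lo, hi) at the central (1−alpha) level.
    """
    cm = np.asarray(map_cM, dtype=float)
    mb = np.asarray(physical_bp, dtype=float) / 1e6
    n = len(cm)
    if n == 0:
        return np.nan, np.nan, np.nan
    point = cm.sum() / mb.sum()
    if n == 1:
        warnings.warn("single scaffold: CI collapses to the point estimate", stacklevel=2)
        return point, point, point
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = _bootstrap_indices(n, mean_block, rng)
        reps[b] = cm[idx].sum() / mb[idx].sum()
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return float(point), float(lo), float(hi)


def bootstrap_rate_table(
    rates: pd.DataFrame,
    mean_block: float = 3.0,
    n_boot: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-linkage-group rate CIs plus a global row (mirrors a per-chromosome
    summary table). ``rates`` must come from :func:`scaffold_rates` with
    scaffolds in genome order within each group."""
    rows = []
    for k, (gid, sub) in enumerate(rates.groupby("group", sort=True)):
        pt, lo, hi = block_bootstrap_ci(
            sub["map_length_cM"].to_numpy(),
            sub["physical_length_bp"].to_numpy(),
            mean_block,
            n_boot,
            alpha,
            seed + k,
        )
        rows.append((str(gid), pt, lo, hi, len(sub)))
    pt, lo, hi = block_bootstrap_ci(
        rates["map_length_cM"].to_numpy(),
        rates["physical_length_bp"].to_numpy(),
        mean_block,
        n_boot,
        alpha,
        seed + len(rows),
    )
    rows.append(("global", pt, lo, hi, len(rates)))
    return pd.DataFrame(rows, columns=["chromosome", "rate_cM_per_Mb", "ci_lo", "ci_hi", "n_scaffolds"])


def rate_density_correlation(
    rates: pd.DataFrame, density: pd.Series, min_bp: int = 500_000
) -> tuple[float, float]:
    """Pearson correlation between scaffold rate and gene density.

    Only scaffolds with physical length > ``min_bp`` qualify; returns
    (NaN, NaN) with fewer than three qualifying scaffolds or zero variance.
    """
    sub = rates[rates["physical_length_bp"] > min_bp]
    joined = sub.set_index("scaffold_id")["rate_cM_per_Mb"].to_frame().join(
        density.rename("density"), how="inner"
    )
    if len(joined) < 3:
        return np.nan, np.nan
    x = joined["rate_cM_per_Mb"].to_numpy()
    y = joined["density"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
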