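"""SNP filtering and window-based genotype calling for a RIL panel.

The calling path mirrors low-coverage genotyping-by-sequencing practice:
individual SNP calls per line are unreliable at depth ~1, so SNPs are first
filtered hard (five criteria plus a neighbour-consistency screen), then
aggregated within 50-kb scaffold windows into marker genotypes via the IM
allele frequency ``p`` among called SNPs.

Threshold semantics follow the strict inequalities of the calling rules:
a SNP call is IM when the IM base frequency exceeds 0.9, PR below 0.1, HET
otherwise; a window call is IM when p > 0.9, PR when p < 0.1, HET when
0.4 < p < 0.6, and missing otherwise. Depth and frequency filter bounds are
inclusive ("between").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rilmap.codes import GENO_LABELS, HET, IM, MISSING, PR
from rilmap.simdata import SnpTable


@dataclass
class GenotypeMatrix:
    """Marker × RIL genotype calls.

    ``markers`` has one row per 50-kb (by default) scaffold window with
    columns ``scaffold_id, window_index, start, end``; ``calls`` holds codes
    from :mod:`rilmap.codes`; ``p`` is the IM-allele frequency among called
    SNPs in the window (NaN where no SNP was called).
    """

    markers: pd.DataFrame
    ril_ids: list[str]
    calls: np.ndarray
    p: np.ndarray

    def __post_init__(self):
        if self.calls.shape != (len(self.markers), len(self.ril_ids)):
            raise ValueError("calls shape inconsistent with markers/rils")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def marker_names(self) -> list[str]:
        return [
            f"{s}:{w}" for s, w in zip(self.markers["scaffold_id"], self.markers["window_index"])
        ]

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.loc[mask].reset_index(drop=True),
            list(self.ril_ids),
            self.calls[mask],
            self.p[mask],
        )

    def subset_rils(self, cols: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.markers.copy(),
            [self.ril_ids[i] for i in cols],
            self.calls[:, cols],
            self.p[:, cols],
        )

    def to_long_tsv(self, path: str) -> None:
        names = self.marker_names()
        rows = []
        for m in range(self.n_markers):
            for r in range(self.n_rils):
                rows.append((names[m], self.ril_ids[r], GENO_LABELS[int(self.calls[m, r])]))
        pd.DataFrame(rows, columns=["marker", "ril_id", "genotype"]).to_csv(
            path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# Per-SNP genotype calls
# ---------------------------------------------------------------------------


def call_snp_genotypes(
    im_reads: np.ndarray | SnpTable,
    alt_reads: np.ndarray | None = None,
    im_hi: float = 0.9,
    pr_lo: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(SNP, RIL) genotype calls from allele depths.

    A RIL is called IM/IM when its IM-base sample frequency exceeds
    ``im_hi``, PR/PR below ``pr_lo``, heterozygous otherwise; zero reads give
    a missing call. Returns ``(calls, im_freq)`` with NaN frequency at
    missing cells.
    """
    if isinstance(im_reads, SnpTable):
        alt_reads = im_reads.alt_reads
        im_reads = im_reads.im_reads
    im_reads = np.asarray(im_reads)
    alt_reads = np.asarray(alt_reads)
    depth = im_reads + alt_reads
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, im_reads / np.maximum(depth, 1), np.nan)
    calls = np.full(im_reads.shape, HET, dtype=np.int8)
    calls[freq > im_hi] = IM
    calls[freq < pr_lo] = PR
    calls[depth == 0] = MISSING
    return calls, freq


# ---------------------------------------------------------------------------
# SNP filter cascade
# ---------------------------------------------------------------------------

FILTER_CRITERIA = (
    "biallelic",
    "im767_ambiguous",
    "total_depth",
    "alt_frequency",
    "het_fraction",
)


def filter_snps(
    snps: SnpTable,
    depth_min: int = 50,
    depth_max: int = 1000,
    freq_min: float = 0.2,
    freq_max: float = 0.8,
    het_max: float = 0.25,
    freq_weighting: str = "reads",
) -> tuple[SnpTable, pd.DataFrame]:
    """Apply the five-criterion SNP filter cascade.

    Criteria, evaluated in order with per-criterion rejection counts:

    1. two bases segregate (IM ≠ alt and both observed in reads);
    2. the IM767 parent call is unambiguous;
    3. total read depth across RILs within [depth_min, depth_max];
    4. alternative-base frequency across RILs within [freq_min, freq_max]
       (``freq_weighting='reads'`` pools reads; ``'rils'`` averages per-RIL
       alt fractions over RILs with data);
    5. fraction of RILs called heterozygous (among called RILs) below
       ``het_max``.

    Returns the retained table and a rejection log (criterion, n_rejected).
    """
    if freq_weighting not in ("reads", "rils"):
        raise ValueError("freq_weighting must be 'reads' or 'rils'")
    im_tot = snps.im_reads.sum(axis=1).astype(np.int64)
    alt_tot = snps.alt_reads.sum(axis=1).astype(np.int64)
    depth = im_tot + alt_tot

    alive = np.ones(snps.n_snps, dtype=bool)
    counts = []

    c1 = (snps.im_base != snps.alt_base) & (im_tot > 0) & (alt_tot > 0)
    counts.append(int(np.sum(alive & ~c1)))
    alive &= c1

    c2 = snps.im767 == "IM"
    counts.append(int(np.sum(alive & ~c2)))
    alive &= c2

    c3 = (depth >= depth_min) & (depth <= depth_max)
    counts.append(int(np.sum(alive & ~c3)))
    alive &= c3

    if freq_weighting == "reads":
        with np.errstate(invalid="ignore", divide="ignore"):
            alt_freq = np.where(depth > 0, alt_tot / np.maximum(depth, 1), np.nan)
    else:
        cell_depth = snps.im_reads + snps.alt_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            cell_frac = np.where(cell_depth > 0, snps.alt_reads / np.maximum(cell_depth, 1), np.nan)
            alt_freq = np.nanmean(cell_frac, axis=1)
    c4 = (alt_freq >= freq_min) & (alt_freq <= freq_max)
    counts.append(int(np.sum(alive & ~c4)))
    alive &= c4

    calls, _ = call_snp_genotypes(snps.im_reads, snps.alt_reads)
    called = calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (calls == HET).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), 0.0)
    c5 = het_frac < het_max
    counts.append(int(np.sum(alive & ~c5)))
    alive &= c5

    log = pd.DataFrame({"criterion": FILTER_CRITERIA, "n_rejected": counts})
    return snps.subset(alive), log


# ---------------------------------------------------------------------------
# Neighbour-consistency filter
# ---------------------------------------------------------------------------


def consistency_filter(
    snps: SnpTable,
    calls: np.ndarray,
    radius_bp: int = 50_000,
) -> tuple[SnpTable, np.ndarray, np.ndarray]:
    """Exclude SNPs whose calls disagree with neighbouring SNPs' calls.

    For each focal SNP, every (RIL, neighbour-SNP) pair within ``radius_bp``
    on the same scaffold where both calls are homozygous (IM or PR)
    contributes one comparison; the SNP is excluded when the disagreeing
    fraction exceeds 0.5. SNPs without neighbours are retained. All SNPs are
    judged against the original calls (single pass). Returns
    (filtered table, filtered calls, keep mask).
    """
    n = snps.n_snps
    keep = np.ones(n, dtype=bool)
    hom = (calls == IM) | (calls == PR)
    order = np.lexsort((snps.pos, snps.scaffold_ids))
    pos_s = snps.pos[order]
    scaf_s = snps.scaffold_ids[order]
    for start in _group_slices(scaf_s):
        sl_idx = order[start]
        p = pos_s[start]
        lo_idx = np.searchsorted(p, p - radius_bp, side="left")
        hi_idx = np.searchsorted(p, p + radius_bp, side="right")
        for k in range(len(p)):
            nb = np.concatenate([sl_idx[lo_idx[k] : k], sl_idx[k + 1 : hi_idx[k]]])
            if len(nb) == 0:
                continue
            focal = sl_idx[k]
            valid = hom[focal][None, :] & hom[nb]
            n_cmp = int(valid.sum())
            if n_cmp == 0:
                continue
            disagree = int((valid & (calls[nb] != calls[focal][None, :])).sum())
            if disagree / n_cmp > 0.5:
                keep[focal] = False
    return snps.subset(keep), calls[keep], keep


def _group_slices(sorted_keys: np.ndarray):
    """Yield slices of equal consecutive keys in a sorted key array."""
    n = len(sorted_keys)
    i = 0
    while i < n:
        j = i + 1
        while j < n and sorted_keys[j] == sorted_keys[i]:
            j += 1
        yield slice(i, j)
        i = j


# ---------------------------------------------------------------------------
# Window (marker) calling
# ---------------------------------------------------------------------------


def call_windows(
    snps: SnpTable,
    calls: np.ndarray,
    scaffold_lengths: dict[str, int],
    window_bp: int = 50_000,
    p_hi: float = 0.9,
    p_lo: float = 0.1,
    het_lo: float = 0.4,
    het_hi: float = 0.6,
) -> GenotypeMatrix:
    """Aggregate SNP calls into contiguous window markers.

    Windows tile each scaffold from coordinate 0; the final partial window
    is retained. Per window and RIL,
    ``p = (n_IM + 0.5 · n_HET) / n_called`` over called SNPs, and the marker
    is IM when p > ``p_hi``, PR when p < ``p_lo``, HET when
    ``het_lo`` < p < ``het_hi``, and missing otherwise (including empty
    windows). HET SNP calls count as half an IM allele.
    """
    n_rils = snps.n_rils
    marker_rows = []
    p_blocks = []
    for sid, length in scaffold_lengths.items():  # caller's scaffold order
        n_win = max(1, int(np.ceil(length / window_bp)))
        sel = np.flatnonzero(snps.scaffold_ids == sid)
        widx = (snps.pos[sel] // window_bp).astype(np.int64)
        c = calls[sel]
        n_im = np.zeros((n_win, n_rils))
        n_het = np.zeros((n_win, n_rils))
        n_called = np.zeros((n_win, n_rils))
        for code, acc in ((IM, n_im), (HET, n_het)):
            rows, cols = np.nonzero(c == code)
            np.add.at(acc, (widx[rows], cols), 1.0)
        rows, cols = np.nonzero(c != MISSING)
        np.add.at(n_called, (widx[rows], cols), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, (n_im + 0.5 * n_het) / np.maximum(n_called, 1), np.nan)
        p_blocks.append(p)
        for w in range(n_win):
            marker_rows.append((sid, w, w * window_bp, min((w + 1) * window_bp, length)))
    markers = pd.DataFrame(marker_rows, columns=["scaffold_id", "window_index", "start", "end"])
    p_all = np.vstack(p_blocks)
    out = classify_p(p_all, p_hi, p_lo, het_lo, het_hi)
    return GenotypeMatrix(markers=markers, ril_ids=list(snps.ril_ids), calls=out, p=p_all)


def classify_p(
    p: np.ndarray,
    p_hi: float = 0.9,
    p_lo: float = 0.1,
    het_lo: float = 0.4,
    het_hi: float = 0.6,
) -> np.ndarray:
    """Map window IM-allele frequencies to genotype codes (NaN → missing)."""
    out = np.full(np.shape(p), MISSING, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        out[p > p_hi] = IM
        out[p < p_lo] = PR
        out[(p > het_lo) & (p < het_hi)] = HET
    return out


# ---------------------------------------------------------------------------
# Mapping subset and segregation summaries
# ---------------------------------------------------------------------------


def select_mapping_set(
    matrix: GenotypeMatrix,
    n_rils: int = 100,
    completeness: float = 0.75,
) -> GenotypeMatrix:
    """Keep the ``n_rils`` most completely genotyped RILs, then markers
    called in at least ``completeness`` of them.

    Ties in missingness break by RIL id. If the panel has fewer than
    ``n_rils`` lines, all are kept with a warning.
    """
    if n_rils > matrix.n_rils:
        warnings.warn(
            f"requested {n_rils} RILs but panel has {matrix.n_rils}; keeping all", stacklevel=2
        )
        n_rils = matrix.n_rils
    missing = (matrix.calls == MISSING).sum(axis=0)
    order = sorted(range(matrix.n_rils), key=lambda i: (missing[i], matrix.ril_ids[i]))
    kept = np.array(sorted(order[:n_rils]))
    sub = matrix.subset_rils(kept)
    called_frac = (sub.calls != MISSING).mean(axis=1)
    return sub.subset_markers(called_frac >= completeness)


def summarize_segregation(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker IM allele frequency, HET fraction and missing fraction.

    The allele frequency counts a heterozygote as half an IM allele. Markers
    with no calls are flagged (``all_missing``) with NaN frequencies.
    """
    n_im = (matrix.calls == IM).sum(axis=1)
    n_pr = (matrix.calls == PR).sum(axis=1)
    n_het = (matrix.calls == HET).sum(axis=1)
    n_called = n_im + n_pr + n_het
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (n_im + 0.5 * n_het) / np.maximum(n_called, 1), np.nan)
        het_frac = np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)
    out = matrix.markers.copy()
    out["im_allele_freq"] = freq
    out["het_fraction"] = het_frac
    out["missing_fraction"] = 1.0 - n_called / matrix.n_rils
    out["all_missing"] = n_called == 0
    return out
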