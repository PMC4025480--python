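"""Synthetic selfed-RIL panels with low-coverage SNP data and phenotypes.

This module simulates the data-generating process that the rest of the
package infers from:

1. A genome layout: chromosomes carrying disjoint scaffolds (some of which
   may be unanchored in outputs), and optional inversion intervals.
2. A pedigree: each RIL descends from a single F1 (IM × PR) by repeated
   self-fertilisation with single-seed descent. Meioses place crossovers as
   a Poisson process along each chromosome (no interference, so downstream
   Haldane mapping is exact in expectation). An individual heterozygous
   across an inversion produces no recoverable crossovers inside it.
3. Reads: SNPs are scattered uniformly within scaffolds; each RIL gets
   Poisson-distributed read depth per SNP, each read drawn from a random
   haplotype and flipped with a base-error probability.
4. Phenotypes: replicate trait values built from QTL additive effects,
   RIL random deviates, grow-up and quantification-method offsets and
   residual noise, optionally exponentiated to a right-skewed scale so that
   log(x+1) recovers the linear model.

Ground truth (haplotypes, crossovers, QTL, variance components) is retained
in :class:`SimTruth` so every downstream estimator can be scored exactly.

Coordinates are 0-based, half-open throughout; positions are base pairs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rilmap.codes import HET, IM, MISSING, PR

UNANCHORED = "UNANCHORED"

_NUCS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Chromosome:
    id: str
    genetic_length_cM: float
    physical_length_bp: int


@dataclass(frozen=True)
class Scaffold:
    """A scaffold interval on a chromosome.

    ``anchored`` controls only whether exported tables reveal the chromosome
    assignment; the true location is always retained for scoring.
    """

    scaffold_id: str
    chromosome_id: str
    start_bp: int
    length_bp: int
    anchored: bool = True

    @property
    def end_bp(self) -> int:
        return self.start_bp + self.length_bp


@dataclass(frozen=True)
class GenomeLayout:
    chromosomes: tuple[Chromosome, ...]
    scaffolds: tuple[Scaffold, ...]
    inversions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self):
        chrom_ids = {c.id for c in self.chromosomes}
        if len(chrom_ids) != len(self.chromosomes):
            raise ValueError("duplicate chromosome ids")
        for c in self.chromosomes:
            if c.genetic_length_cM <= 0 or c.physical_length_bp <= 0:
                raise ValueError(f"chromosome {c.id} has non-positive length")
        by_chrom: dict[str, list[Scaffold]] = {}
        for s in self.scaffolds:
            if s.chromosome_id not in chrom_ids:
                raise ValueError(f"scaffold {s.scaffold_id} on unknown chromosome")
            if s.length_bp <= 0 or s.start_bp < 0:
                raise ValueError(f"scaffold {s.scaffold_id} has invalid span")
            by_chrom.setdefault(s.chromosome_id, []).append(s)
        for cid, scafs in by_chrom.items():
            clen = self.chromosome(cid).physical_length_bp
            spans = sorted((s.start_bp, s.end_bp) for s in scafs)
            for (a0, a1), (b0, _) in zip(spans, spans[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping scaffolds on chromosome {cid}")
            if spans and spans[-1][1] > clen:
                raise ValueError(f"scaffold beyond end of chromosome {cid}")
        for cid, s, e in self.inversions:
            clen = self.chromosome(cid).physical_length_bp
            if not (0 <= s < e <= clen):
                raise ValueError(f"inversion ({cid}, {s}, {e}) outside chromosome")

    def chromosome(self, cid: str) -> Chromosome:
        for c in self.chromosomes:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def scaffold(self, sid: str) -> Scaffold:
        for s in self.scaffolds:
            if s.scaffold_id == sid:
                return s
        raise KeyError(sid)

    def scaffold_lengths(self) -> dict[str, int]:
        return {s.scaffold_id: s.length_bp for s in self.scaffolds}

    def inversions_on(self, cid: str) -> list[tuple[int, int]]:
        return [(s, e) for c, s, e in self.inversions if c == cid]


def make_layout(
    n_chromosomes: int = 14,
    chrom_cM: float = 125.0,
    chrom_bp: int = 32_000_000,
    scaffold_bp: int = 2_000_000,
    inversions: Sequence[tuple[int, int, int]] = (),
    unanchored_fraction: float = 0.0,
    seed: int | None = None,
) -> GenomeLayout:
    """Build a regular layout: equal chromosomes tiled by equal scaffolds.

    ``inversions`` are (chromosome index, start_bp, end_bp) triples. With
    ``unanchored_fraction`` > 0 a random subset of scaffolds is marked
    unanchored (requires ``seed``).
    """
    rng = np.random.default_rng(seed)
    chroms, scafs = [], []
    for i in range(n_chromosomes):
        cid = f"chr{i + 1}"
        chroms.append(Chromosome(cid, chrom_cM, chrom_bp))
        n_scaf = int(np.ceil(chrom_bp / scaffold_bp))
        for j in range(n_scaf):
            start = j * scaffold_bp
            length = min(scaffold_bp, chrom_bp - start)
            scafs.append(Scaffold(f"{cid}_s{j}", cid, start, length))
    if unanchored_fraction > 0:
        k = int(round(unanchored_fraction * len(scafs)))
        drop = set(rng.choice(len(scafs), size=k, replace=False).tolist())
        scafs = [
            Scaffold(s.scaffold_id, s.chromosome_id, s.start_bp, s.length_bp, anchored=i not in drop)
            for i, s in enumerate(scafs)
        ]
    invs = tuple((f"chr{ci + 1}", int(s), int(e)) for ci, s, e in inversions)
    return GenomeLayout(tuple(chroms), tuple(scafs), invs)


def study_layout(seed: int = 0) -> GenomeLayout:
    """A layout emulating the study system: 14 chromosomes totalling ~450 Mb
    and ~1750 cM, tiled by scaffolds of heterogeneous size (≤ 4.9 Mb), with
    three multi-Mb inversions on chromosomes 5, 8 and 10."""
    rng = np.random.default_rng(seed)
    chroms, scafs = [], []
    cms = rng.uniform(72, 167, 14)
    cms *= 1750.0 / cms.sum()
    for i in range(14):
        cid = f"chr{i + 1}"
        bp = int(450e6 / 14)
        chroms.append(Chromosome(cid, float(cms[i]), bp))
        pos = 0
        j = 0
        while pos < bp:
            length = int(min(rng.uniform(0.2e6, 4.9e6), bp - pos))
            scafs.append(Scaffold(f"{cid}_s{j}", cid, pos, length))
            pos += length
            j += 1
    invs = tuple(
        (f"chr{c}", int(10e6), int(10e6 + span))
        for c, span in ((5, 3.0e6), (8, 4.1e6), (10, 2.9e6))
    )
    return GenomeLayout(tuple(chroms), tuple(scafs), invs)


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

# A haplotype along one chromosome: (ends, parents); segment i covers
# [ends[i-1], ends[i]) with parental origin parents[i] in {IM, PR}.
Haplotype = tuple[np.ndarray, np.ndarray]


def _pure_hap(parent: int, length_bp: int) -> Haplotype:
    return np.array([length_bp], dtype=np.int64), np.array([parent], dtype=np.int8)


def _parent_at(hap: Haplotype, pos: float) -> int:
    ends, parents = hap
    return int(parents[np.searchsorted(ends, pos, side="right")])


def _parents_at(hap: Haplotype, pos: np.ndarray) -> np.ndarray:
    ends, parents = hap
    return parents[np.searchsorted(ends, pos, side="right")]


def _gamete(
    h1: Haplotype,
    h2: Haplotype,
    chrom: Chromosome,
    inversions: list[tuple[int, int]],
    rng: np.random.Generator,
    inversion_escape_rate: float,
) -> tuple[Haplotype, np.ndarray]:
    """One meiosis: crossover positions ~ Poisson(cM/100) uniform on the
    chromosome; crossovers inside an inversion the individual is heterozygous
    for are suppressed. Returns the gamete and the retained crossovers."""
    L = chrom.physical_length_bp
    n_xo = rng.poisson(chrom.genetic_length_cM / 100.0)
    if n_xo == 0:
        # gamete is an intact copy of one haplotype; haplotypes are immutable
        # after creation so the arrays can be shared
        return (h1, h2)[int(rng.integers(2))], np.empty(0)
    xs = np.sort(rng.uniform(0.0, L, n_xo)) if n_xo else np.empty(0)
    if len(xs) and inversions:
        keep = np.ones(len(xs), dtype=bool)
        for s, e in inversions:
            if _parent_at(h1, s) != _parent_at(h2, s):  # inversion heterozygote
                inside = (xs >= s) & (xs < e)
                if inversion_escape_rate > 0:
                    inside &= rng.random(len(xs)) >= inversion_escape_rate
                keep &= ~inside
        xs = xs[keep]
    cur = int(rng.integers(2))
    haps = (h1, h2)
    bounds = np.concatenate([xs, [L]])
    out_ends: list[int] = []
    out_par: list[int] = []
    lo = 0.0
    for b in bounds:
        ends, parents = haps[cur]
        i0 = np.searchsorted(ends, lo, side="right")
        i1 = np.searchsorted(ends, b, side="left")
        for i in range(i0, i1 + 1):
            seg_end = min(float(ends[i]), float(b))
            p = int(parents[i])
            if out_par and out_par[-1] == p:
                out_ends[-1] = int(np.ceil(seg_end))
            else:
                out_ends.append(int(np.ceil(seg_end)))
                out_par.append(p)
        lo = b
        cur ^= 1
    out_ends[-1] = L
    return (np.array(out_ends, dtype=np.int64), np.array(out_par, dtype=np.int8)), xs


@dataclass
class SimTruth:
    """Ground truth of a simulated RIL panel.

    ``ril_haplotypes[i][chrom_id]`` is the pair of haplotypes of RIL ``i``;
    ``crossover_log`` records (ril, generation, chromosome_id, gamete,
    positions) for every meiosis, including those with zero crossovers.
    """

    layout: GenomeLayout
    ril_ids: list[str]
    ril_haplotypes: list[dict[str, tuple[Haplotype, Haplotype]]]
    crossover_log: list[tuple[int, int, str, int, np.ndarray]]
    n_selfing_generations: int
    qtl_spec: tuple[tuple[str, int, float], ...] = ()
    variance_components: tuple[float, float, float] = (1.0, 0.25, 1.0)
    seed: int | None = None

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def true_genotype(self, ril: int, chromosome_id: str, bp: float) -> int:
        h1, h2 = self.ril_haplotypes[ril][chromosome_id]
        p1, p2 = _parent_at(h1, bp), _parent_at(h2, bp)
        if p1 == p2:
            return int(p1)
        return HET

    def true_genotypes_at(self, chromosome_id: str, positions: np.ndarray) -> np.ndarray:
        """Genotype codes, shape (n_rils, len(positions))."""
        positions = np.asarray(positions)
        out = np.empty((self.n_rils, len(positions)), dtype=np.int8)
        for i in range(self.n_rils):
            h1, h2 = self.ril_haplotypes[i][chromosome_id]
            p1 = _parents_at(h1, positions)
            p2 = _parents_at(h2, positions)
            g = np.where(p1 == p2, p1, HET).astype(np.int8)
            out[i] = g
        return out

    def het_fraction(self, ril: int) -> float:
        """Fraction of genome base pairs where the two haplotypes disagree."""
        tot = het = 0
        for c in self.layout.chromosomes:
            h1, h2 = self.ril_haplotypes[ril][c.id]
            cuts = np.unique(np.concatenate([h1[0], h2[0]]))
            lo = 0
            for hi in cuts:
                mid = (lo + hi) / 2
                if _parent_at(h1, mid) != _parent_at(h2, mid):
                    het += hi - lo
                lo = hi
            tot += c.physical_length_bp
        return het / tot

    def to_json(self, path: str) -> None:
        def hap(h: Haplotype):
            return {"ends": h[0].tolist(), "parents": h[1].tolist()}

        obj = {
            "ril_ids": self.ril_ids,
            "n_selfing_generations": self.n_selfing_generations,
            "qtl_spec": [list(q) for q in self.qtl_spec],
            "variance_components": list(self.variance_components),
            "seed": self.seed,
            "haplotypes": [
                {cid: [hap(h1), hap(h2)] for cid, (h1, h2) in d.items()}
                for d in self.ril_haplotypes
            ],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def simulate_pedigree(
    layout: GenomeLayout,
    n_rils: int,
    n_selfing_generations: int,
    seed: int,
    *,
    qtl_spec: Sequence[tuple[str, int, float]] = (),
    variance_components: tuple[float, float, float] = (1.0, 0.25, 1.0),
    inversion_escape_rate: float = 0.0,
) -> SimTruth:
    """Simulate ``n_rils`` lines by F1 selfing + single-seed descent.

    ``n_selfing_generations`` counts selfing meioses: 1 gives an F2 panel,
    7 gives F8. Each generation produces two independent gametes from the
    same individual. A line in the F_{g+1} generation has expected residual
    heterozygosity (1/2)^g per base pair.
    """
    if n_rils <= 0:
        raise ValueError("n_rils must be positive")
    if n_selfing_generations < 1:
        raise ValueError("need at least one selfing generation")
    if seed is None:
        raise ValueError("seed is required (reproducibility contract)")
    rng = np.random.default_rng(seed)
    haplos: list[dict[str, tuple[Haplotype, Haplotype]]] = []
    xo_log: list[tuple[int, int, str, int, np.ndarray]] = []
    for ril in range(n_rils):
        indiv = {
            c.id: (_pure_hap(IM, c.physical_length_bp), _pure_hap(PR, c.physical_length_bp))
            for c in layout.chromosomes
        }
        for gen in range(n_selfing_generations):
            nxt = {}
            for c in layout.chromosomes:
                invs = layout.inversions_on(c.id)
                h1, h2 = indiv[c.id]
                g1, x1 = _gamete(h1, h2, c, invs, rng, inversion_escape_rate)
                g2, x2 = _gamete(h1, h2, c, invs, rng, inversion_escape_rate)
                xo_log.append((ril, gen, c.id, 0, x1))
                xo_log.append((ril, gen, c.id, 1, x2))
                nxt[c.id] = (g1, g2)
            indiv = nxt
        haplos.append(indiv)
    return SimTruth(
        layout=layout,
        ril_ids=[f"RIL{r:04d}" for r in range(n_rils)],
        ril_haplotypes=haplos,
        crossover_log=xo_log,
        n_selfing_generations=n_selfing_generations,
        qtl_spec=tuple((str(c), int(p), float(a)) for c, p, a in qtl_spec),
        variance_components=tuple(float(v) for v in variance_components),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


@dataclass
class SnpTable:
    """Per-SNP allele-depth data over a RIL panel (rows = SNPs).

    ``im_reads``/``alt_reads`` have shape (n_snps, n_rils). ``pos`` is the
    0-based position within the scaffold. ``im767`` records whether the
    IM-parent base call was unambiguous at the site.
    """

    scaffold_ids: np.ndarray
    pos: np.ndarray
    im_base: np.ndarray
    alt_base: np.ndarray
    im767: np.ndarray
    ril_ids: list[str]
    im_reads: np.ndarray
    alt_reads: np.ndarray

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    def total_depth(self) -> np.ndarray:
        return self.im_reads.sum(axis=1) + self.alt_reads.sum(axis=1)

    def subset(self, mask: np.ndarray) -> "SnpTable":
        return SnpTable(
            self.scaffold_ids[mask],
            self.pos[mask],
            self.im_base[mask],
            self.alt_base[mask],
            self.im767[mask],
            list(self.ril_ids),
            self.im_reads[mask],
            self.alt_reads[mask],
        )


def simulate_reads(
    truth: SimTruth,
    layout: GenomeLayout,
    snp_density_per_kb: float,
    mean_depth: float,
    base_error: float,
    seed: int,
) -> SnpTable:
    """Simulate per-SNP allele depths over the panel.

    SNP positions fall uniformly within scaffolds at ``snp_density_per_kb``
    expected SNPs per kb; per (RIL, SNP) read depth is Poisson(mean_depth);
    each read reports the allele of a uniformly chosen haplotype, flipped
    with probability ``base_error``.
    """
    if not (0 <= base_error < 0.5):
        raise ValueError("base_error must be in [0, 0.5)")
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    n_rils = truth.n_rils
    scaf_col, pos_col, im_rows, alt_rows = [], [], [], []
    for s in layout.scaffolds:
        n_snp = rng.poisson(snp_density_per_kb * s.length_bp / 1000.0)
        if n_snp == 0:
            continue
        pos = np.unique(rng.integers(0, s.length_bp, n_snp))
        chrom_pos = s.start_bp + pos
        # parental origin of each haplotype at each SNP, (n_rils, n_snp)
        p1 = np.empty((n_rils, len(pos)), dtype=np.int8)
        p2 = np.empty_like(p1)
        for i in range(n_rils):
            h1, h2 = truth.ril_haplotypes[i][s.chromosome_id]
            p1[i] = _parents_at(h1, chrom_pos)
            p2[i] = _parents_at(h2, chrom_pos)
        depth = rng.poisson(mean_depth, size=p1.shape)
        from_h1 = rng.binomial(depth, 0.5)
        reads_im_hap = from_h1 * (p1 == IM) + (depth - from_h1) * (p2 == IM)
        reads_pr_hap = depth - reads_im_hap
        im_reads = rng.binomial(reads_im_hap, 1.0 - base_error) + rng.binomial(
            reads_pr_hap, base_error
        )
        alt_reads = depth - im_reads
        scaf_col.append(np.repeat(s.scaffold_id, len(pos)))
        pos_col.append(pos)
        im_rows.append(im_reads.T)
        alt_rows.append(alt_reads.T)
    if not pos_col:
        raise ValueError("no SNPs simulated; increase snp_density_per_kb")
    n_total = sum(len(p) for p in pos_col)
    bases = rng.integers(0, 4, size=(n_total, 2))
    bases[:, 1] = (bases[:, 0] + 1 + rng.integers(0, 3, n_total)) % 4
    return SnpTable(
        scaffold_ids=np.concatenate(scaf_col),
        pos=np.concatenate(pos_col).astype(np.int64),
        im_base=_NUCS[bases[:, 0]],
        alt_base=_NUCS[bases[:, 1]],
        im767=np.repeat("IM", n_total),
        ril_ids=list(truth.ril_ids),
        im_reads=np.vstack(im_rows).astype(np.int32),
        alt_reads=np.vstack(alt_rows).astype(np.int32),
    )


def true_window_genotypes(truth: SimTruth, window_bp: int = 50_000):
    """Error-free window genotype matrix straight from the simulated truth.

    Windows tile each scaffold from 0; the call is the true genotype at the
    window midpoint. Used for pipeline checks that isolate mapping logic
    from genotype-calling noise. Returns a
    :class:`rilmap.genotypes.GenotypeMatrix`.
    """
    from rilmap.genotypes import GenotypeMatrix

    layout = truth.layout
    rows = []
    call_blocks = []
    for s in layout.scaffolds:
        n_win = max(1, int(np.ceil(s.length_bp / window_bp)))
        starts = np.arange(n_win) * window_bp
        ends = np.minimum(starts + window_bp, s.length_bp)
        mids = s.start_bp + (starts + ends) / 2
        calls = truth.true_genotypes_at(s.chromosome_id, mids)  # (n_rils, n_win)
        call_blocks.append(calls.T)
        for w in range(n_win):
            rows.append((s.scaffold_id, w, int(starts[w]), int(ends[w])))
    markers = pd.DataFrame(rows, columns=["scaffold_id", "window_index", "start", "end"])
    calls = np.vstack(call_blocks)
    p = np.full(calls.shape, np.nan)
    p[calls == IM] = 1.0
    p[calls == PR] = 0.0
    p[calls == HET] = 0.5
    return GenotypeMatrix(markers=markers, ril_ids=list(truth.ril_ids), calls=calls, p=p)


# ---------------------------------------------------------------------------
# Phenotype simulation
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    truth: SimTruth,
    n_growups: int,
    n_reps: int,
    skew_transform: bool,
    seed: int,
    *,
    trait_name: str = "trait",
    grand_mean: float = 2.0,
    method_offset: float = 0.0,
    ril_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate replicate trait measurements for the panel.

    Each replicate value on the linear scale is
    ``grand_mean + Σ QTL effects + RIL deviate + grow-up offset + method
    offset + residual`` with variances taken from
    ``truth.variance_components = (V_ril, V_growup, V_error)``. QTL genotypes
    are coded +a (IM/IM), −a (PR/PR), 0 (HET). With ``skew_transform`` the
    value is ``expm1`` of the linear value, producing the right-skewed
    concentration scale on which ``log(x+1)`` recovers the linear model;
    rare negative concentrations are censored at 0 (below-detection reads).
    """
    v_ril, v_growup, v_error = truth.variance_components
    if min(v_ril, v_growup, v_error) < 0:
        raise ValueError("variance components must be nonnegative")
    rng = np.random.default_rng(seed)
    ids = list(ril_ids) if ril_ids is not None else list(truth.ril_ids)
    idx = {r: i for i, r in enumerate(truth.ril_ids)}
    growup_off = rng.normal(0.0, np.sqrt(v_growup), n_growups)
    ril_dev = rng.normal(0.0, np.sqrt(v_ril), len(ids))
    qtl_part = np.zeros(len(ids))
    for cid, bp, a in truth.qtl_spec:
        for j, r in enumerate(ids):
            g = truth.true_genotype(idx[r], cid, bp)
            qtl_part[j] += a if g == IM else (-a if g == PR else 0.0)
    rows = []
    for j, r in enumerate(ids):
        gu = j % n_growups  # RIL nested within grow-up
        for rep in range(n_reps):
            method = "HPLC" if rng.random() < 0.5 else "UHPLC"
            y = (
                grand_mean
                + qtl_part[j]
                + ril_dev[j]
                + growup_off[gu]
                + (method_offset if method == "UHPLC" else 0.0)
                + rng.normal(0.0, np.sqrt(v_error))
            )
            rows.append((r, f"growup{gu + 1}", method, rep + 1, y))
    df = pd.DataFrame(rows, columns=["ril_id", "growup", "method", "replicate", trait_name])
    if skew_transform:
        df[trait_name] = np.maximum(np.expm1(df[trait_name]), 0.0)
    return df


# ---------------------------------------------------------------------------
# YAML config entry point
# ---------------------------------------------------------------------------


def simulate_from_config(config: str | Mapping) -> tuple[SimTruth, SnpTable]:
    """Run pedigree + read simulation from a YAML file or mapping.

    The config must carry an explicit ``seed``. Recognised keys: ``layout``
    (arguments of :func:`make_layout`), ``n_rils``, ``n_selfing_generations``,
    ``snp_density_per_kb``, ``mean_depth``, ``base_error``.
    """
    if isinstance(config, str):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "seed" not in config:
        raise ValueError("config must specify an explicit seed")
    seed = int(config["seed"])
    layout = make_layout(**config.get("layout", {}))
    truth = simulate_pedigree(
        layout,
        int(config.get("n_rils", 100)),
        int(config.get("n_selfing_generations", 7)),
        seed,
    )
    snps = simulate_reads(
        truth,
        layout,
        float(config.get("snp_density_per_kb", 1.0)),
        float(config.get("mean_depth", 1.0)),
        float(config.get("base_error", 0.001)),
        seed + 1,
    )
    return truth, snps
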