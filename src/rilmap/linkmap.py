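"""Linkage map construction for selfed RIL panels.

Pairwise linkage between markers is summarised by the RIL recombination
fraction R̂ (fraction of informative lines with discordant homozygous
calls) and a binomial LOD score against free recombination (R = 0.5).
Markers are grouped by single linkage at an R threshold, scaffolds whose
windows land in different groups are broken into fragments, and fragments
are ordered within each group by minimising the sum of adjacent
recombination fractions (SARF) — markers within a fragment stay frozen in
physical order, so the optimisation permutes and orients whole fragments.

Repeated selfing inflates the observed RIL recombination fraction relative
to the meiotic rate: R = 2r/(1+2r) at fixation (Haldane–Waddington), so map
distances use the inverse r = R/(2(1−R)) followed by the Haldane map
function d = −50·ln(1−2r) cM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from rilmap.codes import GENO_LABELS, signed
from rilmap.genotypes import GenotypeMatrix

LOG10_2 = float(np.log10(2.0))


# ---------------------------------------------------------------------------
# Pairwise recombination fraction and LOD
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseLinkage:
    r_hat: float
    lod: float
    n_informative: int


def pairwise_matrices(
    matrix: GenotypeMatrix, with_lod: bool = True
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """All-pairs (R̂, LOD, n_informative) over the markers of ``matrix``.

    Heterozygous and missing calls are excluded; a pair is informative in a
    RIL when both markers carry homozygous calls. R̂ = k/n truncated at 0.5;
    the LOD is ``k·log10(R) + (n−k)·log10(1−R) + n·log10 2`` at the
    (truncated) maximum-likelihood R. Pairs with fewer than two informative
    lines get NaN R̂ and zero LOD. ``with_lod=False`` skips the LOD matrix
    (returned as None) for map construction, which only needs R̂.
    """
    X = signed(matrix.calls)  # markers × rils, ±1 hom / 0 otherwise
    A = (X != 0).astype(np.float64)
    N = A @ A.T
    S = X @ X.T
    K = (N - S) / 2.0
    bad = N < 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r_ml = np.minimum(K / N, 0.5)
    lod = None
    if with_lod:
        with np.errstate(invalid="ignore", divide="ignore"):
            lod = (
                np.where(K > 0, K * np.log10(np.maximum(r_ml, 1e-300)), 0.0)
                + np.where(N - K > 0, (N - K) * np.log10(1.0 - r_ml), 0.0)
                + N * LOG10_2
            )
        lod = np.where(bad, 0.0, np.maximum(lod, 0.0))
    R = r_ml
    R[bad] = np.nan
    return R, lod, N.astype(np.int64)


def pairwise_linkage(matrix: GenotypeMatrix, i: int, j: int) -> PairwiseLinkage:
    """Linkage summary for one marker pair (see :func:`pairwise_matrices`)."""
    x = signed(matrix.calls[i])
    y = signed(matrix.calls[j])
    use = (x != 0) & (y != 0)
    n = int(use.sum())
    if n < 2:
        return PairwiseLinkage(np.nan, 0.0, n)
    k = int(np.sum(x[use] != y[use]))
    r = min(k / n, 0.5)
    lod = (k * np.log10(r) if k else 0.0) + (n - k) * np.log10(1 - r) + n * LOG10_2
    return PairwiseLinkage(r, max(lod, 0.0), n)


# ---------------------------------------------------------------------------
# Grouping and scaffold breaking
# ---------------------------------------------------------------------------


def group_markers(
    R: np.ndarray, N: np.ndarray, r_threshold: float = 0.15, min_informative: int = 2
) -> np.ndarray:
    """Single-linkage components of the graph { R̂ ≤ threshold }.

    Group labels are renumbered deterministically: descending group size,
    ties by smallest member marker index.
    """
    with np.errstate(invalid="ignore"):
        adj = (R <= r_threshold) & (N >= min_informative)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    first = np.full(n_comp, len(labels))
    for i, lab in enumerate(labels):
        first[lab] = min(first[lab], i)
    order = sorted(range(n_comp), key=lambda c: (-sizes[c], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=np.int64)


def break_scaffolds(
    markers: pd.DataFrame, labels: np.ndarray
) -> tuple[np.ndarray, pd.DataFrame]:
    """Split scaffolds whose windows fall in more than one linkage group.

    Markers of one scaffold (in window order) are cut into maximal runs of
    equal group label; each run becomes a fragment ``scaffold.k``. Returns
    the per-marker fragment id and a break log.
    """
    frag = np.empty(len(markers), dtype=object)
    rows = []
    for sid, idx in markers.groupby("scaffold_id", sort=False).groups.items():
        idx = np.asarray(idx)[np.argsort(markers.loc[idx, "window_index"].to_numpy())]
        runs = []
        start = 0
        for k in range(1, len(idx) + 1):
            if k == len(idx) or labels[idx[k]] != labels[idx[start]]:
                runs.append(idx[start:k])
                start = k
        for k, run in enumerate(runs):
            name = sid if len(runs) == 1 else f"{sid}.{k}"
            frag[run] = name
            if len(runs) > 1:
                rows.append(
                    (
                        sid,
                        name,
                        int(labels[run[0]]),
                        int(markers.loc[run[0], "window_index"]),
                        int(markers.loc[run[-1], "window_index"]),
                    )
                )
    breaks = pd.DataFrame(rows, columns=["scaffold_id", "fragment", "group", "first_window", "last_window"])
    return frag, breaks


# ---------------------------------------------------------------------------
# Marker ordering (seriation under scaffold-order constraints)
# ---------------------------------------------------------------------------


def _junction_table(ends, R: np.ndarray) -> np.ndarray:
    """J[i, oi, j, oj]: R̂ between block i's trailing end (orientation oi)
    and block j's leading end (orientation oj); NaN pairs cost 0.5."""
    nb = len(ends)
    tail = np.array([[e[1], e[0]] for e in ends])  # i, oi → marker
    head = np.array([[e[0], e[1]] for e in ends])  # j, oj → marker
    J = R[tail[:, :, None, None], head[None, None, :, :]]
    return np.where(np.isnan(J), 0.5, J)


def _orient_dp(order: list[int], J: np.ndarray) -> tuple[float, list[int]]:
    """Optimal block orientations for a fixed block sequence (2-state DP)."""
    if len(order) == 1:
        return 0.0, [0]
    cost = (0.0, 0.0)
    back: list[tuple[int, int]] = []
    for prev, cur in zip(order, order[1:]):
        j = J[prev, :, cur, :]  # (op, oc)
        c00 = cost[0] + j[0, 0]
        c10 = cost[1] + j[1, 0]
        c01 = cost[0] + j[0, 1]
        c11 = cost[1] + j[1, 1]
        b0 = 0 if c00 <= c10 else 1
        b1 = 0 if c01 <= c11 else 1
        cost = (min(c00, c10), min(c01, c11))
        back.append((b0, b1))
    oc = 0 if cost[0] <= cost[1] else 1
    total = cost[oc]
    orients = [oc]
    for bk in reversed(back):
        oc = bk[oc]
        orients.append(oc)
    orients.reverse()
    return float(total), orients


def _greedy_order(start: int, J: np.ndarray, n_blocks: int) -> list[int]:
    order = [start]
    used = {start}
    cur, ocur = start, 0
    for _ in range(n_blocks - 1):
        best = None
        for j in range(n_blocks):
            if j in used:
                continue
            for oj in (0, 1):
                key = (J[cur, ocur, j, oj], j, oj)
                if best is None or key < best:
                    best = key
        _, j, oj = best
        order.append(j)
        used.add(j)
        cur, ocur = j, oj
    return order


def order_markers(
    marker_ids: np.ndarray,
    fragments: np.ndarray,
    R: np.ndarray,
    scaffold_order_constraint: bool = True,
    n_restarts: int = 20,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Order the markers of one linkage group by minimum SARF.

    Markers sharing a scaffold fragment form a frozen block (physical
    order); block sequences are built greedily from ``n_restarts`` random
    starts and refined by 2-opt, with per-sequence optimal orientations from
    a two-state dynamic program. Returns the ordered global marker indices
    and the achieved SARF (internal block adjacencies included).
    """
    marker_ids = np.asarray(marker_ids)
    if len(marker_ids) == 1:
        return marker_ids.copy(), 0.0
    if scaffold_order_constraint:
        blocks = []
        seen: dict[object, list[int]] = {}
        for m in marker_ids:
            seen.setdefault(fragments[m], []).append(int(m))
        blocks = [sorted(v) for v in seen.values()]
    else:
        blocks = [[int(m)] for m in marker_ids]
    internal = 0.0
    for blk in blocks:
        for a, b in zip(blk, blk[1:]):
            r = R[a, b]
            internal += 0.5 if np.isnan(r) else float(r)
    ends = [(blk[0], blk[-1]) for blk in blocks]
    nb = len(blocks)
    if nb == 1:
        return np.array(blocks[0]), internal
    J = _junction_table(ends, R)

    rng = np.random.default_rng(seed)
    best_cost = np.inf
    best_order: list[int] | None = None
    best_orients: list[int] | None = None
    for k in range(max(1, n_restarts)):
        if k < nb:  # greedy tours from distinct starting blocks
            order = _greedy_order(k, J, nb)
        else:  # diversify with random initial sequences
            order = list(rng.permutation(nb))
        cost, orients = _orient_dp(order, J)
        improved = True
        while improved:
            improved = False
            # 2-opt segment reversals
            for i in range(nb - 1):
                for j in range(i + 1, nb):
                    cand = order[:i] + order[i : j + 1][::-1] + order[j + 1 :]
                    c, o = _orient_dp(cand, J)
                    if c < cost - 1e-12:
                        order, cost, orients = cand, c, o
                        improved = True
            # or-opt single-block relocations
            for i in range(nb):
                for j in range(nb):
                    if j == i:
                        continue
                    cand = order[:i] + order[i + 1 :]
                    cand = cand[:j] + [order[i]] + cand[j:]
                    if cand == order:
                        continue
                    c, o = _orient_dp(cand, J)
                    if c < cost - 1e-12:
                        order, cost, orients = cand, c, o
                        improved = True
        key = (tuple(order), tuple(orients))
        if cost < best_cost - 1e-12 or (
            abs(cost - best_cost) <= 1e-12 and key < (tuple(best_order), tuple(best_orients))
        ):
            best_cost, best_order, best_orients = cost, order, orients

    seq: list[int] = []
    for b, o in zip(best_order, best_orients):
        seq.extend(blocks[b] if o == 0 else blocks[b][::-1])
    if seq[0] > seq[-1]:  # canonical direction
        seq.reverse()
    return np.array(seq, dtype=np.int64), float(best_cost + internal)


# ---------------------------------------------------------------------------
# Map distances (selfed-RIL correction + Haldane)
# ---------------------------------------------------------------------------


def meiotic_r_from_R(R: float | np.ndarray) -> float | np.ndarray:
    """Invert the Haldane–Waddington fixation formula R = 2r/(1+2r)."""
    return R / (2.0 * (1.0 - R))


def selfing_discordance(r: float, generations: int) -> float:
    """Exact discordance between doubly homozygous lines after finite selfing.

    Evolves the two-locus diplotype distribution of an F1 (coupling
    heterozygote) through ``generations`` rounds of selfing at meiotic
    recombination fraction ``r`` and returns the probability that a line
    homozygous at both loci carries discordant parental alleles. Converges
    to the fixation value 2r/(1+2r) as generations grow; at F8 the value is
    ~3–5% lower for tightly linked loci, which compresses dense maps built
    with the fixation correction.
    """
    haps = ((0, 0), (0, 1), (1, 0), (1, 1))

    def gametes(hi: int, ki: int) -> dict[tuple[int, int], float]:
        out: dict[tuple[int, int], float] = {}
        pair = (haps[hi], haps[ki])
        for fi in (0, 1):
            for si in (0, 1):
                p = 0.5 * ((1 - r) if fi == si else r)
                g = (pair[fi][0], pair[si][1])
                out[g] = out.get(g, 0.0) + p
        return out

    states = [(i, j) for i in range(4) for j in range(i, 4)]
    idx = {s: i for i, s in enumerate(states)}
    T = np.zeros((len(states), len(states)))
    for (i, j), si in idx.items():
        gs = gametes(i, j)
        for g1, p1 in gs.items():
            for g2, p2 in gs.items():
                a, b = sorted((haps.index(g1), haps.index(g2)))
                T[idx[(a, b)], si] += p1 * p2
    v = np.zeros(len(states))
    v[idx[(0, 3)]] = 1.0  # F1: AB/ab
    for _ in range(generations):
        v = T @ v
    p_hom = p_disc = 0.0
    for (i, j), si in idx.items():
        h1, h2 = haps[i], haps[j]
        if h1[0] == h2[0] and h1[1] == h2[1]:
            p_hom += v[si]
            if h1[0] != h1[1]:
                p_disc += v[si]
    return p_disc / p_hom


@lru_cache(maxsize=8)
def _finite_selfing_inverse(generations: int, n_grid: int = 400):
    """Monotone interpolant r(R) for the finite-generation discordance."""
    r_grid = np.linspace(0.0, 0.5, n_grid)
    R_grid = np.array([selfing_discordance(r, generations) for r in r_grid])

    def inv(R: np.ndarray) -> np.ndarray:
        return np.interp(R, R_grid, r_grid)

    return inv


def haldane_cM(r: float | np.ndarray, r_cap: float = 0.49) -> float | np.ndarray:
    """Haldane map distance d = −50·ln(1−2r) cM; r capped to keep d finite."""
    r = np.minimum(r, r_cap)
    return -50.0 * np.log(1.0 - 2.0 * r)


def estimate_positions(
    ordered_ids: np.ndarray, R: np.ndarray, selfing_generations: int | None = None
) -> np.ndarray:
    """Cumulative cM positions along an ordered marker list.

    Adjacent R̂ → meiotic r by the selfed-RIL inverse (the fixation formula
    by default, or the exact finite-generation chain when
    ``selfing_generations`` is given), then the Haldane map function;
    undefined adjacent pairs contribute zero distance.
    """
    inv = _finite_selfing_inverse(selfing_generations) if selfing_generations else None
    pos = np.zeros(len(ordered_ids))
    for k in range(1, len(ordered_ids)):
        r_hat = R[ordered_ids[k - 1], ordered_ids[k]]
        if np.isnan(r_hat):
            d = 0.0
        else:
            r_hat = min(float(r_hat), 0.499)
            r = float(inv(r_hat)) if inv else meiotic_r_from_R(r_hat)
            d = float(haldane_cM(r))
        pos[k] = pos[k - 1] + d
    return pos


# ---------------------------------------------------------------------------
# The genetic map
# ---------------------------------------------------------------------------


@dataclass
class LinkageGroup:
    group_id: int
    marker_ids: np.ndarray  # indices into the source matrix, map order
    positions_cM: np.ndarray
    sarf: float

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def length_cM(self) -> float:
        return float(self.positions_cM[-1]) if len(self.positions_cM) else 0.0


@dataclass
class GeneticMap:
    groups: list[LinkageGroup]
    markers: pd.DataFrame  # marker metadata incl. 'fragment' column
    breaks: pd.DataFrame
    matrix: GenotypeMatrix | None = None

    @property
    def n_markers(self) -> int:
        return sum(g.n_markers for g in self.groups)

    def total_length_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    def mean_adjacent_spacing_cM(self) -> float:
        """Mean adjacent marker spacing = total length / (markers − groups)."""
        gaps = sum(g.n_markers - 1 for g in self.groups if g.n_markers > 1)
        return self.total_length_cM() / gaps if gaps else np.nan

    def marker_table(self) -> pd.DataFrame:
        rows = []
        for g in self.groups:
            for k, (m, cm) in enumerate(zip(g.marker_ids, g.positions_cM)):
                meta = self.markers.iloc[m]
                rows.append(
                    (
                        g.group_id,
                        k,
                        int(m),
                        meta["scaffold_id"],
                        meta.get("fragment", meta["scaffold_id"]),
                        int(meta["window_index"]),
                        int(meta["start"]),
                        int(meta["end"]),
                        float(cm),
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "group",
                "order",
                "marker_id",
                "scaffold_id",
                "fragment",
                "window_index",
                "start",
                "end",
                "position_cM",
            ],
        )

    def to_tsv(self, path: str) -> None:
        """Wide map export: three header rows (group, cM, marker id) then one
        row of genotype codes per RIL."""
        if self.matrix is None:
            raise ValueError("map export needs the genotype matrix")
        tab = self.marker_table()
        names = [
            f"{s}:{w}" for s, w in zip(tab["scaffold_id"], tab["window_index"])
        ]
        with open(path, "w") as fh:
            fh.write("linkage_group\t" + "\t".join(str(g) for g in tab["group"]) + "\n")
            fh.write("position_cM\t" + "\t".join(f"{x:.3f}" for x in tab["position_cM"]) + "\n")
            fh.write("marker\t" + "\t".join(names) + "\n")
            for r, rid in enumerate(self.matrix.ril_ids):
                codes = [
                    GENO_LABELS[int(self.matrix.calls[m, r])] for m in tab["marker_id"]
                ]
                fh.write(rid + "\t" + "\t".join(codes) + "\n")


def build_map(
    matrix: GenotypeMatrix,
    r_threshold: float = 0.15,
    n_restarts: int = 20,
    seed: int = 0,
    scaffold_order_constraint: bool = True,
    selfing_generations: int | None = None,
) -> GeneticMap:
    """Full map construction: pairwise linkage → grouping → scaffold breaking
    → constrained ordering → cM positions."""
    R, _, N = pairwise_matrices(matrix, with_lod=False)
    labels = group_markers(R, N, r_threshold)
    fragments, breaks = break_scaffolds(matrix.markers, labels)
    markers = matrix.markers.copy()
    markers["fragment"] = fragments
    groups = []
    for gid in range(int(labels.max()) + 1):
        ids = np.flatnonzero(labels == gid)
        ordered, sarf = order_markers(
            ids,
            fragments,
            R,
            scaffold_order_constraint=scaffold_order_constraint,
            n_restarts=n_restarts,
            seed=seed + gid,
        )
        pos = estimate_positions(ordered, R, selfing_generations=selfing_generations)
        groups.append(LinkageGroup(gid, ordered, pos, sarf))
    return GeneticMap(groups=groups, markers=markers, breaks=breaks, matrix=matrix)


def heatmap_matrices(
    gmap: GeneticMap, group_id: int, R: np.ndarray | None = None, LOD: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Square R̂ and LOD matrices for one linkage group in map order.

    Conventionally read with R̂ below the diagonal and LOD above; both full
    symmetric matrices are returned (diagonal R̂ = 0).
    """
    if R is None or LOD is None:
        if gmap.matrix is None:
            raise ValueError("need pairwise matrices or the source genotype matrix")
        R, LOD, _ = pairwise_matrices(gmap.matrix)
    grp = next(g for g in gmap.groups if g.group_id == group_id)
    ids = grp.marker_ids
    names = [
        f"{gmap.markers.iloc[m]['scaffold_id']}:{gmap.markers.iloc[m]['window_index']}" for m in ids
    ]
    r_sub = R[np.ix_(ids, ids)].copy()
    np.fill_diagonal(r_sub, 0.0)
    lod_sub = LOD[np.ix_(ids, ids)]
    return (
        pd.DataFrame(r_sub, index=names, columns=names),
        pd.DataFrame(lod_sub, index=names, columns=names),
    )


def linkage_heatmap_export(gmap: GeneticMap, group_id: int, prefix: str) -> None:
    r_df, lod_df = heatmap_matrices(gmap, group_id)
    r_df.to_csv(f"{prefix}.rhat.tsv", sep="\t")
    lod_df.to_csv(f"{prefix}.lod.tsv", sep="\t")
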