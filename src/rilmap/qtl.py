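"""QTL mapping by multiple-imputation interval mapping on RIL means.

Phenotype preprocessing follows the study design: replicate trait values
are log(x+1)-transformed, fixed effects of grow-up batch and quantification
method are removed by least squares, variance is partitioned into among-RIL
and within-RIL components by method of moments on the nested (RIL within
grow-up) layout, and per-RIL means of the residuals become the mapping
phenotype.

Genotype scans use the multiple-imputation flavour of interval mapping:
missing (and residual heterozygous) marker genotypes are imputed from the
conditional distribution of a two-state Markov chain along each linkage
group, whose step probabilities derive from map distances through the
inverse Haldane function and the selfed-RIL fixation formula
R = 2r/(1+2r). Per imputation the LOD at a marker is the regression LOD
(n/2)·log10(RSS0/RSS1) with genotypes coded ±1; imputations combine as
log10 of the mean of 10^LOD. Genome-wide significance comes from
permutation of the RIL means against intact genotype rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy import stats

from rilmap.codes import HET, IM, MISSING, PR, signed
from rilmap.genotypes import GenotypeMatrix
from rilmap.linkmap import GeneticMap

LN10 = float(np.log(10.0))


# ---------------------------------------------------------------------------
# Phenotype preprocessing
# ---------------------------------------------------------------------------


def transform(values) -> np.ndarray:
    """log(x+1) transform of raw (nonnegative) concentrations."""
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("raw trait values must be nonnegative")
    return np.log1p(arr)


@dataclass
class VarianceDecomposition:
    v_ril: float
    v_error: float
    intercept: float
    growup_effects: dict[str, float]
    method_effects: dict[str, float]
    truncated: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def within_ril_sd(self) -> float:
        return float(np.sqrt(self.v_error))


def _fixed_design(table: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    gu_levels = sorted(table["growup"].astype(str).unique())
    me_levels = sorted(table["method"].astype(str).unique())
    cols = [np.ones(len(table))]
    for g in gu_levels[1:]:
        cols.append((table["growup"].astype(str) == g).to_numpy(float))
    for m in me_levels[1:]:
        cols.append((table["method"].astype(str) == m).to_numpy(float))
    return np.column_stack(cols), gu_levels, me_levels


def variance_components(table: pd.DataFrame, trait: str) -> VarianceDecomposition:
    """Nested ANOVA variance components for one (transformed) trait.

    Grow-up and method fixed effects are estimated by least squares; V_ril
    and V_error come from expected mean squares of the one-way (RIL) layout
    on the residuals, with the unbalanced-design coefficient
    c = (N − Σ nᵢ²/N)/(g−1). A negative among-RIL estimate is truncated to
    zero and flagged.
    """
    y = table[trait].to_numpy(float)
    X, gu_levels, me_levels = _fixed_design(table)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    gu_eff = {
        g: (float(beta[1 + gu_levels.index(g) - 1]) if g != gu_levels[0] else 0.0)
        for g in gu_levels
    }
    me_off = 1 + len(gu_levels) - 1
    me_eff = {
        m: (float(beta[me_off + me_levels.index(m) - 1]) if m != me_levels[0] else 0.0)
        for m in me_levels
    }

    groups = table["ril_id"].to_numpy()
    uniq, inv = np.unique(groups, return_inverse=True)
    n_i = np.bincount(inv).astype(float)
    N = float(len(y))
    g = len(uniq)
    means = np.bincount(inv, weights=resid) / n_i
    grand = resid.mean()
    flags: list[str] = []
    df_within = N - g
    if df_within <= 0:
        flags.append("no replication: within-RIL variance inestimable")
        return VarianceDecomposition(np.nan, np.nan, float(beta[0]), gu_eff, me_eff, False, flags)
    ss_within = float(np.sum((resid - means[inv]) ** 2))
    ms_within = ss_within / df_within
    ss_among = float(np.sum(n_i * (means - grand) ** 2))
    ms_among = ss_among / (g - 1)
    c = (N - np.sum(n_i**2) / N) / (g - 1)
    v_ril = (ms_among - ms_within) / c
    truncated = v_ril < 0
    if truncated:
        flags.append("negative among-RIL component truncated to 0")
        v_ril = 0.0
    return VarianceDecomposition(
        float(v_ril), float(ms_within), float(beta[0]), gu_eff, me_eff, truncated, flags
    )


def ril_means(table: pd.DataFrame, trait: str, decomposition: VarianceDecomposition) -> pd.Series:
    """Per-RIL mean residual after removing grow-up and method effects."""
    y = table[trait].to_numpy(float)
    fit = (
        decomposition.intercept
        + table["growup"].astype(str).map(decomposition.growup_effects).to_numpy(float)
        + table["method"].astype(str).map(decomposition.method_effects).to_numpy(float)
    )
    resid = pd.Series(y - fit, index=table["ril_id"].to_numpy())
    return resid.groupby(level=0).mean().rename(trait)


def preprocess_phenotypes(
    table: pd.DataFrame, traits: list[str]
) -> tuple[pd.DataFrame, dict[str, VarianceDecomposition]]:
    """Transform each trait, fit the nested ANOVA, and build RIL means.

    Returns a RIL × trait frame of mean residuals and the per-trait variance
    decompositions.
    """
    decomps: dict[str, VarianceDecomposition] = {}
    means: dict[str, pd.Series] = {}
    work = table.copy()
    for t in traits:
        work[t] = transform(work[t])
        decomps[t] = variance_components(work, t)
        means[t] = ril_means(work, t, decomps[t])
    return pd.DataFrame(means), decomps


def trait_correlations(means: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations (and p-values) over shared RILs."""
    traits = list(means.columns)
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if j <= i:
                continue
            sub = means[[a, b]].dropna()
            if len(sub) < 3 or sub[a].std() == 0 or sub[b].std() == 0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                p.loc[a, b] = p.loc[b, a] = np.nan
                continue
            rr, pp = stats.pearsonr(sub[a], sub[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


# ---------------------------------------------------------------------------
# Genotype imputation along the map
# ---------------------------------------------------------------------------


@dataclass
class ImputationSet:
    """Complete (IM/PR) genotype imputations on the map's marker frame.

    ``frame`` has one row per map marker in scan order (group, position_cM,
    marker_id); ``geno`` has shape (n_imputations, n_markers, n_rils) with
    only IM/PR codes; observed homozygous calls are fixed across
    imputations.
    """

    frame: pd.DataFrame
    ril_ids: list[str]
    geno: np.ndarray
    seed: int
    fully_missing: list[str] = field(default_factory=list)

    @property
    def n_imputations(self) -> int:
        return self.geno.shape[0]

    def subset_rils(self, ids: list[str]) -> "ImputationSet":
        pos = [self.ril_ids.index(r) for r in ids]
        return ImputationSet(
            self.frame, list(ids), self.geno[:, :, pos], self.seed, list(self.fully_missing)
        )


def _step_flip_prob(d_cM: np.ndarray) -> np.ndarray:
    """Map distance → RIL discordance probability between adjacent markers."""
    r = 0.5 * (1.0 - np.exp(-np.asarray(d_cM, float) / 50.0))  # inverse Haldane
    return 2.0 * r / (1.0 + 2.0 * r)  # selfed-RIL fixation


def impute_genotypes(
    matrix: GenotypeMatrix,
    gmap: GeneticMap,
    n_imputations: int = 32,
    seed: int = 0,
) -> ImputationSet:
    """Draw complete genotype imputations conditional on flanking markers.

    Along each linkage group, unobserved calls (missing, and heterozygous
    calls which are treated as missing for the two-state chain) are sampled
    from the Markov chain with step discordance probabilities derived from
    map distances, conditioning on the nearest non-missing markers on both
    sides (one side at group ends). RILs with no observed marker on a group
    are sampled from the unconditional chain and flagged.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for grp in gmap.groups:
        frames.append(
            pd.DataFrame(
                {
                    "group": grp.group_id,
                    "position_cM": grp.positions_cM,
                    "marker_id": grp.marker_ids,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    n_rils = matrix.n_rils
    m = len(frame)
    geno = np.empty((n_imputations, m, n_rils), dtype=np.int8)
    fully_missing: set[str] = set()
    row0 = 0
    for grp in gmap.groups:
        ids = grp.marker_ids
        k = len(ids)
        flips = _step_flip_prob(np.diff(grp.positions_cM)) if k > 1 else np.empty(0)
        obs = matrix.calls[ids]  # k × n_rils
        known = (obs == IM) | (obs == PR)
        for r in range(n_rils):
            col = obs[:, r]
            kn = np.flatnonzero(known[:, r])
            out = np.empty((n_imputations, k), dtype=np.int8)
            if len(kn) == 0:
                fully_missing.add(matrix.ril_ids[r])
                state = rng.integers(0, 2, size=n_imputations).astype(np.int8)
                out[:, 0] = np.where(state == 0, IM, PR)
                for t in range(1, k):
                    flip = rng.random(n_imputations) < flips[t - 1]
                    state = np.where(flip, 1 - state, state)
                    out[:, t] = np.where(state == 0, IM, PR)
            else:
                out[:, kn] = col[kn]
                # leading tail: backward from the first known marker
                first = kn[0]
                state = np.repeat(col[first], n_imputations).astype(np.int8)
                for t in range(first - 1, -1, -1):
                    flip = rng.random(n_imputations) < flips[t]
                    state = np.where(flip, np.int8(1) - state, state)
                    out[:, t] = state
                # trailing tail: forward from the last known marker
                last = kn[-1]
                state = np.repeat(col[last], n_imputations).astype(np.int8)
                for t in range(last + 1, k):
                    flip = rng.random(n_imputations) < flips[t - 1]
                    state = np.where(flip, np.int8(1) - state, state)
                    out[:, t] = state
                # interior runs between consecutive known flanks
                for a, b in zip(kn, kn[1:]):
                    if b - a == 1:
                        continue
                    # q[t]: flip prob of the composed chain from t to b
                    q = np.empty(b - a + 1)
                    q[-1] = 0.0
                    for t in range(b - 1, a, -1):
                        f = flips[t]
                        q[t - a] = f * (1 - q[t - a + 1]) + (1 - f) * q[t - a + 1]
                    state = np.repeat(col[a], n_imputations).astype(np.int8)
                    right = int(col[b])
                    for t in range(a + 1, b):
                        f = flips[t - 1]
                        qq = q[t - a]
                        # posterior flip probability given left state and right flank
                        p_flip_path = np.where(
                            (1 - state) == right, f * (1 - qq), f * qq
                        )
                        p_stay_path = np.where(state == right, (1 - f) * (1 - qq), (1 - f) * qq)
                        denom = p_flip_path + p_stay_path
                        p_flip = np.where(denom > 0, p_flip_path / np.maximum(denom, 1e-300), 0.5)
                        flip = rng.random(n_imputations) < p_flip
                        state = np.where(flip, np.int8(1) - state, state)
                        out[:, t] = state
            geno[:, row0 : row0 + k, r] = out
        row0 += k
    return ImputationSet(frame, list(matrix.ril_ids), geno, seed, sorted(fully_missing))


# ---------------------------------------------------------------------------
# Interval-mapping scans
# ---------------------------------------------------------------------------


@dataclass
class ScanResult:
    frame: pd.DataFrame  # group, position_cM, marker_id
    lod: np.ndarray
    n_imputations: int
    thresholds: dict[float, float] | None = None
    perm_max_lods: np.ndarray | None = None

    def peak(self) -> tuple[int, float]:
        i = int(np.argmax(self.lod))
        return i, float(self.lod[i])

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["lod"] = self.lod
        return out


def _align(imputations: ImputationSet, pheno: pd.Series) -> tuple[ImputationSet, np.ndarray]:
    shared = [r for r in imputations.ril_ids if r in pheno.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} RILs are both genotyped and phenotyped")
    return imputations.subset_rils(shared), pheno.loc[shared].to_numpy(float)


def _covariate_projector(Z: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of span{1, Z}; drops collinear columns."""
    X = np.ones((n, 1)) if Z is None or Z.size == 0 else np.column_stack([np.ones(n), Z])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank < X.shape[1]:
        warnings.warn("collinear covariates dropped in conditional scan", stacklevel=3)
    return U[:, :rank]


def _scan_lods(
    imputations: ImputationSet, y: np.ndarray, model_rows: list[int] | None = None
) -> np.ndarray:
    """Per-imputation regression LODs combined as log10-mean-10^LOD.

    ``model_rows`` (frame row indices) enter both null and alternative
    models as covariates, giving the conditional (add-QTL) scan.
    """
    n_imp, m, n = imputations.geno.shape
    lods = np.empty((n_imp, m))
    for i in range(n_imp):
        G = signed(imputations.geno[i])  # m × n, ±1
        Z = signed(imputations.geno[i][model_rows]).T if model_rows else None
        Q = _covariate_projector(Z, n)
        y_r = y - Q @ (Q.T @ y)
        rss0 = float(y_r @ y_r)
        G_r = G - (G @ Q) @ Q.T
        num = G_r @ y_r
        den = np.einsum("ij,ij->i", G_r, G_r)
        with np.errstate(invalid="ignore", divide="ignore"):
            rss1 = rss0 - np.where(den > 1e-12, num**2 / np.maximum(den, 1e-12), 0.0)
            rss1 = np.maximum(rss1, rss0 * 1e-300)
            lods[i] = (n / 2.0) * np.log10(np.maximum(rss0, 1e-300) / rss1)
    lods = np.maximum(lods, 0.0)
    return logsumexp(lods * LN10, axis=0) / LN10 - np.log10(n_imp)


def scan(imputations: ImputationSet, pheno: pd.Series) -> ScanResult:
    """Genome scan of LOD scores for one trait (RIL means)."""
    imps, y = _align(imputations, pheno)
    lod = _scan_lods(imps, y)
    return ScanResult(imputations.frame.copy(), lod, imputations.n_imputations)


def add_qtl(
    imputations: ImputationSet, pheno: pd.Series, model_rows: list[int]
) -> ScanResult:
    """Conditional scan controlling for the QTL already in the model."""
    if not model_rows:
        raise ValueError("model is empty; use scan()")
    imps, y = _align(imputations, pheno)
    lod = _scan_lods(imps, y, model_rows=list(model_rows))
    return ScanResult(imputations.frame.copy(), lod, imputations.n_imputations)


def permutation_thresholds(
    imputations: ImputationSet,
    pheno: pd.Series,
    n_perm: int = 1000,
    alphas: tuple[float, ...] = (0.05, 0.10),
    seed: int = 0,
) -> tuple[dict[float, float], np.ndarray]:
    """Genome-wide LOD thresholds from phenotype permutations.

    RIL mean phenotypes are shuffled against intact genotype rows; the
    genome-wide maximum combined LOD of each permutation forms the null
    distribution, and the threshold at level α is its (1−α) quantile.
    """
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small for tail quantiles", stacklevel=2)
    imps, y = _align(imputations, pheno)
    rng = np.random.default_rng(seed)
    n = len(y)
    yc = y - y.mean()
    y2 = float(yc @ yc)
    Y = np.empty((n, n_perm))
    for p in range(n_perm):
        Y[:, p] = yc[rng.permutation(n)]
    n_imp, m, _ = imps.geno.shape
    log_acc = np.full((m, n_perm), -np.inf)
    for i in range(n_imp):
        G = signed(imps.geno[i])
        Gc = G - G.mean(axis=1, keepdims=True)
        g2 = np.einsum("ij,ij->i", Gc, Gc)
        cross = Gc @ Y
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(g2[:, None] > 1e-12, cross**2 / (np.maximum(g2, 1e-12)[:, None] * y2), 0.0)
            lod = -(n / 2.0) * np.log10(np.maximum(1.0 - r2, 1e-300))
        log_acc = np.logaddexp(log_acc, lod * LN10)
    comb = log_acc / LN10 - np.log10(n_imp)
    max_lods = comb.max(axis=0)
    thr = {float(a): float(np.quantile(max_lods, 1.0 - a)) for a in alphas}
    return thr, max_lods


# ---------------------------------------------------------------------------
# Intervals, effects and the QTL model
# ---------------------------------------------------------------------------


def lod_interval(
    result: ScanResult, group, drop: float = 1.8
) -> tuple[float, float, float, bool]:
    """1.8-LOD support interval around the peak of one linkage group.

    Expands from the peak while LOD ≥ peak − drop; returns (lo_cM, hi_cM,
    % of the group's map length, flat_flag). A profile entirely within
    ``drop`` of its peak spans the whole group and is flagged flat.
    """
    sel = result.frame["group"] == group
    pos = result.frame.loc[sel, "position_cM"].to_numpy(float)
    lod = result.lod[sel.to_numpy()]
    peak = int(np.argmax(lod))
    thr = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= thr:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= thr:
        hi += 1
    length = pos.max() - pos.min()
    flat = lo == 0 and hi == len(lod) - 1 and lod.min() >= thr
    pct = 100.0 * (pos[hi] - pos[lo]) / length if length > 0 else 100.0
    return float(pos[lo]), float(pos[hi]), float(pct), bool(flat)


def qtl_effects(
    model_rows: list[int],
    imputations: ImputationSet,
    pheno: pd.Series,
    decomposition: VarianceDecomposition,
) -> pd.DataFrame:
    """Per-QTL class difference in within-RIL SD units and % variance.

    The effect is the full IM/IM − PR/PR class difference of RIL means,
    averaged over imputations, divided by the within-RIL SD
    (√V_error of the nested ANOVA). % variance is 100·SS_QTL/SS_total from
    the single-QTL linear model, averaged over imputations.
    """
    imps, y = _align(imputations, pheno)
    n_imp = imps.n_imputations
    rows = []
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    for row in model_rows:
        diffs, pcts = [], []
        for i in range(n_imp):
            g = imps.geno[i][row]
            im_mask, pr_mask = g == IM, g == PR
            if im_mask.any() and pr_mask.any():
                diffs.append(y[im_mask].mean() - y[pr_mask].mean())
            x = signed(g)
            xc = x - x.mean()
            den = float(xc @ xc)
            if den > 1e-12:
                pcts.append(100.0 * (float(xc @ (y - y.mean())) ** 2 / den) / ss_tot)
        effect = float(np.mean(diffs)) if diffs else np.nan
        if not diffs:
            warnings.warn("a genotype class is absent at a QTL peak; effect undefined", stacklevel=2)
        rows.append(
            (
                row,
                effect / decomposition.within_ril_sd if diffs else np.nan,
                float(np.mean(pcts)) if pcts else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=["frame_row", "effect_in_sd", "pct_variance"])


def find_qtl(
    imputations: ImputationSet,
    pheno: pd.Series,
    decomposition: VarianceDecomposition,
    n_perm: int = 1000,
    alpha: float = 0.05,
    drop: float = 1.8,
    seed: int = 0,
    max_qtl: int = 10,
) -> pd.DataFrame:
    """Full per-trait QTL workflow: scan, threshold, conditional search,
    intervals and effects.

    Peaks exceeding the genome-wide ``alpha`` permutation threshold enter
    the model one at a time (conditional add-QTL scans find further peaks);
    each reported QTL carries its peak LOD, permutation p-value, LOD-drop
    interval (and % of chromosome), class-difference effect in within-RIL SD
    units, and % variance explained.
    """
    thr, max_lods = permutation_thresholds(
        imputations, pheno, n_perm=n_perm, alphas=(alpha,), seed=seed
    )
    threshold = thr[alpha]
    model_rows: list[int] = []
    scans: list[ScanResult] = []
    while len(model_rows) < max_qtl:
        res = (
            scan(imputations, pheno)
            if not model_rows
            else add_qtl(imputations, pheno, model_rows)
        )
        lod_masked = res.lod.copy()
        for r in model_rows:  # don't re-pick markers already in the model
            lod_masked[r] = -np.inf
        i = int(np.argmax(lod_masked))
        if lod_masked[i] <= threshold:
            if not model_rows:
                scans.append(res)
            break
        model_rows.append(i)
        scans.append(res)
    rows = []
    eff = qtl_effects(model_rows, imputations, pheno, decomposition) if model_rows else None
    for k, row in enumerate(model_rows):
        res = scans[k]
        grp = res.frame.loc[row, "group"]
        lo, hi, pct, _flat = lod_interval(res, grp, drop=drop)
        peak_lod = float(res.lod[row])
        pval = float(np.mean(max_lods >= peak_lod))
        rows.append(
            (
                grp,
                float(res.frame.loc[row, "position_cM"]),
                int(res.frame.loc[row, "marker_id"]),
                peak_lod,
                pval,
                lo,
                hi,
                pct,
                float(eff.loc[k, "effect_in_sd"]),
                float(eff.loc[k, "pct_variance"]),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "position_cM",
            "marker_id",
            "lod",
            "p_value",
            "interval_lo_cM",
            "interval_hi_cM",
            "pct_chromosome",
            "effect_in_sd",
            "pct_variance",
        ],
    )
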