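"""Signed co-expression networks and module statistics.

Implements the weighted co-expression workflow used for the liver/brain
transcriptomes: CPM-based gene filtering, sample-outlier removal by
average-linkage clustering, top-variable-gene selection, biweight
midcorrelation (bicor), soft-threshold selection by scale-free topology
fit, signed adjacency → topological overlap → module detection, module
eigengenes, module membership (kME), module–trait association with the
Student asymptotic approximation and BH correction, hub-gene extraction,
a bootstrap module-stability score, and Fisher's exact module-overlap
test.

Expression matrices are genes × samples pandas DataFrames throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .permstats import bh_adjust

__all__ = [
    "filter_and_transform",
    "remove_outlier_samples",
    "top_variable",
    "bicor",
    "bicor_matrix",
    "pick_soft_power",
    "detect_modules",
    "module_eigengenes",
    "kme",
    "module_trait",
    "hub_genes",
    "bootstrap_stability",
    "fisher_overlap",
    "StabilityReport",
    "OverlapResult",
    "UNASSIGNED",
]

UNASSIGNED = "unassigned"


# ---------------------------------------------------------------------------
# preprocessing


def filter_and_transform(counts: pd.DataFrame, cpm_min: float = 1.0, min_frac: float = 0.2) -> pd.DataFrame:
    """CPM-filter raw counts and return log2-stabilised expression.

    Keeps genes with CPM > ``cpm_min`` (strict) in at least
    ceil(min_frac · n_samples) samples. Retained counts are scaled by
    median-of-ratios size factors (robust to a minority of strongly
    co-varying genes, unlike total-count scaling) and transformed to
    log2(scaled + 1) — this package's variance-stabilising step for
    downstream network analysis.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    libsize = arr.sum(axis=0)
    if (libsize == 0).any():
        bad = counts.columns[libsize == 0].tolist()
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = arr / libsize[None, :] * 1e6
    need = math.ceil(min_frac * counts.shape[1])
    keep = (cpm > cpm_min).sum(axis=1) >= need
    kept = arr[keep]

    # median-of-ratios size factors over genes expressed in every sample
    positive = (kept > 0).all(axis=1)
    if positive.sum() >= 10:
        logk = np.log(kept[positive])
        ref = logk.mean(axis=1, keepdims=True)  # geometric-mean reference
        sf = np.exp(np.median(logk - ref, axis=0))
    else:  # too few universally expressed genes: total-count fallback
        sf = libsize / np.exp(np.mean(np.log(libsize)))
    scaled = kept / sf[None, :]
    return pd.DataFrame(
        np.log2(scaled + 1.0), index=counts.index[keep], columns=counts.columns
    )


def remove_outlier_samples(expr: pd.DataFrame, height_cutoff: float) -> pd.DataFrame:
    """Drop outlying samples by average-linkage clustering.

    Samples are clustered on Euclidean distance of their expression
    profiles; the tree is cut at ``height_cutoff`` and only the largest
    branch is retained. Removed sample ids are reported via a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    X = expr.to_numpy(dtype=float).T  # samples × genes
    Z = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=height_cutoff, criterion="distance")
    sizes = np.bincount(labels)
    best = int(np.argmax(sizes))
    keep = labels == best
    if keep.sum() < 3:
        raise ValueError(
            f"height cutoff {height_cutoff} leaves only {int(keep.sum())} sample(s)"
        )
    dropped = expr.columns[~keep].tolist()
    if dropped:
        warnings.warn(f"removed outlier samples: {dropped}", UserWarning)
    return expr.loc[:, keep]


def top_variable(expr: pd.DataFrame, n: int = 5000) -> pd.DataFrame:
    """Keep the ``n`` most variable genes (ties broken by gene id)."""
    if n >= expr.shape[0]:
        if n > expr.shape[0]:
            warnings.warn(
                f"requested {n} genes but only {expr.shape[0]} available; keeping all"
            )
        return expr.copy()
    var = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-var[g], g))
    return expr.loc[order[:n]]


# ---------------------------------------------------------------------------
# biweight midcorrelation


def _biweight_transform(x: np.ndarray):
    """Median/MAD biweight-transformed vector; None when MAD is zero."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return None
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    return (x - med) * w


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors.

    Uses Tukey biweights around the median with the 9·MAD scaling; when a
    vector has zero MAD the computation falls back to Pearson correlation
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("bicor needs two equal-length 1-D vectors of length >= 3")
    xt = _biweight_transform(x)
    yt = _biweight_transform(y)
    if xt is None or yt is None:
        warnings.warn("zero MAD; falling back to Pearson correlation", UserWarning)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("undefined correlation: constant vector")
        return float(np.corrcoef(x, y)[0, 1])
    nx, ny = np.linalg.norm(xt), np.linalg.norm(yt)
    if nx == 0 or ny == 0:
        raise ValueError("undefined correlation: zero weighted norm")
    return float(np.clip(xt @ yt / (nx * ny), -1.0, 1.0))


def _bicor_transform_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise biweight transform, normalised to unit norm.

    Rows with zero MAD fall back to centred/normalised (Pearson) rows.
    """
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero = (mad == 0).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    T = dev * w
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} row(s) with zero MAD; Pearson fallback", UserWarning
        )
        cent = X[zero] - X[zero].mean(axis=1, keepdims=True)
        T[zero] = cent
    norms = np.linalg.norm(T, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("undefined correlation: zero weighted norm row(s)")
    return T / norms


def bicor_matrix(X: pd.DataFrame | np.ndarray, Y: pd.DataFrame | np.ndarray | None = None) -> np.ndarray:
    """All-pairs bicor between rows of X (and rows of Y if given)."""
    Xa = np.asarray(X, dtype=float)
    Tx = _bicor_transform_rows(Xa)
    Ty = Tx if Y is None else _bicor_transform_rows(np.asarray(Y, dtype=float))
    return np.clip(Tx @ Ty.T, -1.0, 1.0)


# ---------------------------------------------------------------------------
# soft power and modules


@dataclass
class SoftPowerResult:
    power: int
    r2: float
    achieved_target: bool
    table: pd.DataFrame  # per-power fit index and mean connectivity


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Equal-width binning of k; the index is −sign(slope)·R² of the linear
    regression of log10(frequency) on log10(mean k) over non-empty bins.
    """
    k = np.asarray(k, dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("degenerate connectivity: all values equal")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=k, minlength=n_bins)
    ok = freq > 0
    mean_k = sums[ok] / freq[ok]
    if ok.sum() < 3 or np.any(mean_k <= 0):
        raise ValueError("too few usable connectivity bins")
    lx, ly = np.log10(mean_k), np.log10(freq[ok] / freq.sum())
    slope, _, r, _, _ = stats.linregress(lx, ly)
    return float(-np.sign(slope) * r**2)


def pick_soft_power(
    expr: pd.DataFrame,
    powers: range | list[int] = range(1, 21),
    r2_target: float = 0.80,
) -> SoftPowerResult:
    """Lowest soft-thresholding power with scale-free fit R² above target.

    The candidate adjacency at each power is the signed Pearson similarity
    ((1 + cor)/2)^β; connectivity k_i is the row sum without the diagonal.
    If no power reaches the target, the best-fitting power is returned with
    ``achieved_target=False`` and a warning.
    """
    if expr.shape[0] < 50:
        raise ValueError("need at least 50 genes to assess scale-free fit")
    X = expr.to_numpy(dtype=float)
    cor = np.corrcoef(X)
    sim = (1.0 + cor) / 2.0
    np.fill_diagonal(sim, 0.0)
    rows = []
    for beta in powers:
        a = sim**beta
        k = a.sum(axis=1)
        try:
            r2 = _scale_free_r2(k)
        except ValueError:
            rows.append({"power": int(beta), "r2": np.nan, "mean_k": float(k.mean())})
            continue
        rows.append({"power": int(beta), "r2": r2, "mean_k": float(k.mean())})
    table = pd.DataFrame(rows)
    passing = table[table["r2"] > r2_target]
    if len(passing):
        best = passing.iloc[0]
        return SoftPowerResult(int(best["power"]), float(best["r2"]), True, table)
    best = table.loc[table["r2"].idxmax()]
    warnings.warn(
        f"no power reached scale-free R² > {r2_target}; best is "
        f"β={int(best['power'])} (R²={best['r2']:.3f})",
        UserWarning,
    )
    return SoftPowerResult(int(best["power"]), float(best["r2"]), False, table)


def _tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency with zero diagonal."""
    k = adj.sum(axis=1)
    shared = adj @ adj
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + adj) / (kmin + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    return tom


def _merge_by_eigengene(expr: pd.DataFrame, assignment: pd.Series, merge_height: float) -> pd.Series:
    """Iteratively fuse the closest module pair while eigengene correlation
    is at least 1 − merge_height."""
    assignment = assignment.copy()
    while True:
        mods = [m for m in assignment.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            return assignment
        eig = module_eigengenes(expr, assignment)
        C = np.corrcoef(eig.to_numpy())
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < 1.0 - merge_height:
            return assignment
        keep_label, drop_label = sorted([eig.index[i], eig.index[j]])
        assignment[assignment == drop_label] = keep_label


def detect_modules(
    expr: pd.DataFrame,
    beta: int,
    min_size: int = 30,
    merge_height: float = 0.25,
    cut_height: float | None = None,
    kme_min: float = 0.6,
) -> pd.Series:
    """Detect signed co-expression modules.

    Pipeline: signed bicor adjacency ((1 + bicor)/2)^β → topological
    overlap similarity → average-linkage clustering of the TOM
    dissimilarity → static tree cut → eigengene-based module assembly.
    The default cut is the lowest tree height that maximises the number of
    branches of at least min_size/2 genes; those branches seed modules,
    same-module fragments are fused while their eigengenes correlate at
    ≥ 1 − merge_height, and every gene is then (re)assigned to the module
    it has the highest kME with, provided that kME exceeds ``kme_min``
    (genes below stay "unassigned" — the analogue of a minimum-membership
    rule). Modules ending below ``min_size`` are dissolved. Pass
    ``cut_height`` to override the automatic cut. Returns a gene-indexed
    Series of module labels ("M1", "M2", … by decreasing size).
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    genes = expr.index
    assignment = pd.Series(UNASSIGNED, index=genes, name="module", dtype=object)
    if min_size > len(genes):
        warnings.warn("min_size exceeds gene count; all genes unassigned", UserWarning)
        return assignment
    adj = ((1.0 + bicor_matrix(expr)) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    diss = 1.0 - _tom_similarity(adj)
    np.fill_diagonal(diss, 0.0)
    cond = squareform(diss, checks=False)
    Z = hierarchy.linkage(cond, method="average")

    seed_min = max(5, min_size // 2)
    if cut_height is None:
        cuts = hierarchy.cut_tree(Z)
        n_valid = np.array(
            [(np.bincount(cuts[:, c]) >= seed_min).sum() for c in range(cuts.shape[1])]
        )
        labels = cuts[:, int(np.argmax(n_valid))] + 1
    else:
        labels = hierarchy.fcluster(Z, t=cut_height, criterion="distance")

    k = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) >= seed_min:
            k += 1
            assignment.iloc[idx] = f"seed{k}"
    if k == 0:
        warnings.warn("no branch reached the seed size; all genes unassigned", UserWarning)
        return assignment

    assignment = _merge_by_eigengene(expr, assignment, merge_height)

    # kME re-assignment sweep: every gene joins its best-correlated module
    # if the membership is strong enough, otherwise remains unassigned
    eig = module_eigengenes(expr, assignment)
    K = kme(expr, eig)
    best = K.idxmax(axis=1)
    bestv = K.max(axis=1)
    assignment = pd.Series(
        np.where(bestv > kme_min, best, UNASSIGNED), index=genes, name="module", dtype=object
    )
    for m in [m for m in assignment.unique() if m != UNASSIGNED]:
        if (assignment == m).sum() < 2:
            assignment[assignment == m] = UNASSIGNED
    if (assignment != UNASSIGNED).any():
        assignment = _merge_by_eigengene(expr, assignment, merge_height)
    for m in [m for m in assignment.unique() if m != UNASSIGNED]:
        if (assignment == m).sum() < min_size:
            assignment[assignment == m] = UNASSIGNED
    if not (assignment != UNASSIGNED).any():
        warnings.warn("no module reached min_size; all genes unassigned", UserWarning)
        return assignment
    # relabel by decreasing size for stable naming
    mods = [m for m in assignment.unique() if m != UNASSIGNED]
    mods.sort(key=lambda m: (-(assignment == m).sum(), m))
    rename = {m: f"M{i + 1}" for i, m in enumerate(mods)}
    return assignment.map(lambda m: rename.get(m, UNASSIGNED)).rename("module")


# ---------------------------------------------------------------------------
# eigengenes, kME, trait association


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component of each module (modules × samples).

    Genes are standardised across samples before the SVD; each eigengene's
    sign is oriented so it correlates positively with the module's mean
    expression profile.
    """
    mods = sorted(m for m in assignment.unique() if m != UNASSIGNED)
    rows = {}
    for m in mods:
        sub = expr.loc[assignment[assignment == m].index].to_numpy(dtype=float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {m} has fewer than 2 genes")
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError(f"module {m} contains constant gene(s)")
        Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(Z, full_matrices=False)
        e = vt[0]
        ref = Z.mean(axis=0)
        if np.corrcoef(e, ref)[0, 1] < 0:
            e = -e
        rows[m] = e
    return pd.DataFrame(rows, index=expr.columns).T


def kme(expr: pd.DataFrame, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """Module membership: bicor of every gene with every module eigengene."""
    if list(expr.columns) != list(eigengenes.columns):
        eigengenes = eigengenes.loc[:, expr.columns]
    K = bicor_matrix(expr.to_numpy(dtype=float), eigengenes.to_numpy(dtype=float))
    return pd.DataFrame(K, index=expr.index, columns=eigengenes.index)


def module_trait(eigengenes: pd.DataFrame, group_labels: pd.Series | np.ndarray) -> pd.DataFrame:
    """Module–trait association table.

    Each experimental group becomes a one-vs-rest binary indicator; the
    association is bicor(eigengene, indicator) with a two-sided p from the
    Student approximation t = r·sqrt((n−2)/(1−r²)) on n−2 df, and BH
    adjustment across all module × trait cells.
    """
    g = pd.Series(np.asarray(group_labels), index=eigengenes.columns)
    n = eigengenes.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")
    rows = []
    for trait in sorted(g.unique()):
        ind = (g == trait).to_numpy(dtype=float)
        if ind.sum() < 2 or ind.sum() > n - 2:
            warnings.warn(f"group {trait!r} too small for association; skipped", UserWarning)
            continue
        for m in eigengenes.index:
            r = bicor(eigengenes.loc[m].to_numpy(), ind)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r**2))
                p = 2.0 * stats.t.sf(abs(t), df=n - 2)
            rows.append({"module": m, "trait": trait, "r": r, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def hub_genes(
    kme_table: pd.DataFrame, assignment: pd.Series, threshold: float = 0.8
) -> dict[str, list[str]]:
    """Per-module genes with |kME| to their own module strictly above threshold."""
    out: dict[str, list[str]] = {}
    for m in kme_table.columns:
        members = assignment.index[assignment == m]
        vals = kme_table.loc[members, m]
        out[m] = sorted(vals.index[vals.abs() > threshold])
    return out


# ---------------------------------------------------------------------------
# bootstrap stability


@dataclass
class StabilityReport:
    per_bootstrap: np.ndarray  # mean own-module kME per bootstrap draw
    score: float
    n_boot: int
    seed: int
    redraws: int = 0

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "redraws": self.redraws,
            "per_bootstrap": self.per_bootstrap.tolist(),
        }


def _mean_own_module_kme(expr: pd.DataFrame, assignment: pd.Series) -> float:
    eig = module_eigengenes(expr, assignment)
    K = kme(expr, eig)
    assigned = assignment[assignment != UNASSIGNED]
    vals = [K.at[g, m] for g, m in assigned.items()]
    return float(np.mean(vals))


def bootstrap_stability(
    expr: pd.DataFrame,
    assignment: pd.Series,
    n_boot: int = 50,
    seed: int = 0,
    resampler=None,
) -> StabilityReport:
    """Bootstrap module-stability score.

    Samples (columns) are resampled with replacement ``n_boot`` times;
    eigengenes and kME are recomputed with the original module assignments
    kept fixed; each bootstrap contributes the mean own-module kME across
    assigned genes, and the score is the average of those means. Draws with
    fewer than 3 distinct samples are redrawn (logged on the report).
    ``resampler``, if given, maps (rng, n_samples) to column indices —
    useful for deterministic checks.
    """
    if expr.shape[1] < 4:
        raise ValueError("need at least 4 samples to bootstrap")
    rng = np.random.default_rng(seed)
    means = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            if resampler is not None:
                idx = np.asarray(resampler(rng, expr.shape[1]))
            else:
                idx = rng.integers(0, expr.shape[1], size=expr.shape[1])
            if len(np.unique(idx)) >= 3:
                break
            redraws += 1
        boot = expr.iloc[:, idx]
        boot.columns = [f"bs{j}" for j in range(len(idx))]  # duplicates renamed
        means[b] = _mean_own_module_kme(boot, assignment)
    return StabilityReport(
        per_bootstrap=means, score=float(means.mean()), n_boot=n_boot, seed=seed, redraws=redraws
    )


# ---------------------------------------------------------------------------
# module overlap


@dataclass(frozen=True)
class OverlapResult:
    a: int  # |A ∩ B|
    b: int  # |A \ B|
    c: int  # |B \ A|
    d: int  # rest of universe
    odds_ratio: float
    p: float
    universe_size: int

    def shared_pct(self, of: str = "A") -> float:
        """Overlap as a percentage of set A (or B)."""
        denom = self.a + (self.b if of == "A" else self.c)
        return 100.0 * self.a / denom if denom else float("nan")


def fisher_overlap(setA, setB, universe) -> OverlapResult:
    """Two-sided Fisher's exact test for the overlap of two gene sets.

    The 2×2 table is built from membership in A and B over the supplied
    universe; OR = ad/bc (∞ when bc = 0 with ad > 0); the p-value sums
    hypergeometric probabilities of tables at least as extreme.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(setA) & universe, set(setB) & universe
    if set(setA) - universe or set(setB) - universe:
        raise ValueError("setA/setB must be subsets of the universe")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = a * d / (b * c)
    return OverlapResult(a=a, b=b, c=c, d=d, odds_ratio=odds, p=float(p), universe_size=len(universe))
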