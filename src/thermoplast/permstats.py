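"""Permutation inference for the behavioural experiments.

Implements the experiment-level tests: a permutation ANCOVA with a nuisance
covariate (Freedman–Lane residual permutation), a permutation ANOVA for a
split-plot repeated-measures design (between-subject acclimation group ×
within-subject test temperature), simple-main-effect post hocs with Holm
adjustment, Holm/Benjamini–Hochberg corrections, and Wilcoxon rank tests.

p-values use the add-one estimator p = (b + 1)/(m + 1) where b counts
permuted statistics ≥ the observed one (ties count, conservatively). When
no permuted statistic reaches the observed value the result is flagged
``below_floor`` and the reporting floor 1/m is attached, matching the
"p < 2 × 10⁻⁵" style of reporting at m = 50,000.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermTestResult",
    "SplitPlotResult",
    "perm_ancova",
    "perm_splitplot",
    "posthoc_simple_effects",
    "holm_adjust",
    "bh_adjust",
    "rank_tests",
]


@dataclass(frozen=True)
class PermTestResult:
    statistic: float
    df_num: int | None
    df_den: int | None
    n_perm: int
    exceed_count: int
    p_est: float
    p_floor: float
    below_floor: bool
    seed: int
    statistic_name: str = "F"

    def report_p(self) -> str:
        """Publication-style p string: '< 1/m' when below the floor."""
        return f"< {self.p_floor:g}" if self.below_floor else f"{self.p_est:g}"

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "n_perm": self.n_perm,
            "exceed_count": self.exceed_count,
            "p_est": self.p_est,
            "p_floor": self.p_floor,
            "below_floor": self.below_floor,
            "seed": self.seed,
        }


def _p_from_counts(b: int, m: int, seed: int, stat, df_num, df_den, name="F") -> PermTestResult:
    return PermTestResult(
        statistic=float(stat),
        df_num=df_num,
        df_den=df_den,
        n_perm=m,
        exceed_count=int(b),
        p_est=(b + 1) / (m + 1),
        p_floor=1.0 / m,
        below_floor=(b == 0),
        seed=seed,
    )


def _design(*columns) -> np.ndarray:
    return np.column_stack([np.ones(len(columns[0])), *columns])


def perm_ancova(y, group, covariate, m: int = 50_000, seed: int = 123) -> PermTestResult:
    """Permutation ANCOVA of a group effect adjusted for one covariate.

    F compares the covariate-only (reduced) model against the group +
    covariate (full) model: F = ((RSS_r − RSS_f)/q) / (RSS_f/(n − p)). The
    null distribution follows Freedman–Lane: residuals of the reduced model
    are permuted, added back to the reduced-model fit, and F recomputed,
    so the covariate's contribution is preserved under the null.
    """
    y = np.asarray(y, dtype=float)
    covariate = np.asarray(covariate, dtype=float)
    group = np.asarray(group)
    if not (len(y) == len(group) == len(covariate)):
        raise ValueError("y, group and covariate must have equal length")
    if m < 1:
        raise ValueError("m must be >= 1")
    levels, codes = np.unique(group, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        raise ValueError(f"singleton group(s): {levels[counts < 2]}")
    if np.ptp(covariate) == 0:
        raise ValueError("degenerate design: covariate is constant")

    n = len(y)
    G = np.zeros((n, len(levels) - 1))
    for k in range(1, len(levels)):
        G[codes == k, k - 1] = 1.0
    X_red = _design(covariate)
    X_full = np.column_stack([X_red, G])
    q = len(levels) - 1
    p_full = X_full.shape[1]
    if n <= p_full:
        raise ValueError("not enough observations for the full model")

    Qr, _ = np.linalg.qr(X_red)
    Qf, _ = np.linalg.qr(X_full)

    def f_stat(Y):
        # Y: (n,) or (n, m)
        Y2 = Y if Y.ndim == 2 else Y[:, None]
        tot = np.sum(Y2**2, axis=0)
        rss_r = tot - np.sum((Qr.T @ Y2) ** 2, axis=0)
        rss_f = tot - np.sum((Qf.T @ Y2) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((rss_r - rss_f) / q) / (rss_f / (n - p_full))
        return np.nan_to_num(F, nan=0.0, posinf=np.inf)

    F_obs = float(f_stat(y)[0])
    fit_red = Qr @ (Qr.T @ y)
    resid = y - fit_red
    rng = np.random.default_rng(seed)
    # permute reduced-model residuals in manageable blocks
    b = 0
    block = max(1, min(m, int(2e7) // max(n, 1)))
    done = 0
    while done < m:
        k = min(block, m - done)
        idx = np.argsort(rng.random((k, n)), axis=1)  # k independent permutations
        Ystar = fit_red[None, :] + resid[idx]
        b += int(np.sum(f_stat(Ystar.T) >= F_obs))
        done += k
    return _p_from_counts(b, m, seed, F_obs, q, n - p_full)


# ---------------------------------------------------------------------------
# split-plot permutation ANOVA


@dataclass(frozen=True)
class SplitPlotResult:
    between: PermTestResult
    within: PermTestResult
    interaction: PermTestResult
    n_subjects: int
    n_between_levels: int
    n_within_levels: int


def _splitplot_layout(y, subject, between, within):
    """Pivot long data to a complete (subject × within-level) matrix."""
    df = pd.DataFrame(
        {"y": np.asarray(y, dtype=float), "subject": subject, "between": between, "within": within}
    )
    wide = df.pivot_table(index="subject", columns="within", values="y", aggfunc="mean")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"subjects missing within-subject levels: {bad}")
    grp = df.groupby("subject")["between"].agg(lambda s: s.iloc[0])
    if (df.groupby("subject")["between"].nunique() > 1).any():
        raise ValueError("a subject appears under more than one between-subject level")
    grp = grp.loc[wide.index]
    _, gcodes = np.unique(grp.to_numpy(), return_inverse=True)
    return wide.to_numpy(), gcodes, list(wide.columns)


def _splitplot_f(Y, gcodes, n_groups):
    """Split-plot F statistics for data matrices Y.

    Y: (S, W) or (B, S, W) batch. Returns (F_between, F_within, F_inter),
    each scalar or (B,).
    """
    Y = np.asarray(Y, dtype=float)
    batch = Y.ndim == 3
    if not batch:
        Y = Y[None]
    B, S, W = Y.shape
    counts = np.bincount(gcodes, minlength=n_groups).astype(float)  # subjects per group

    grand = Y.mean(axis=(1, 2))  # (B,)
    subj_mean = Y.mean(axis=2)  # (B, S)
    within_mean = Y.mean(axis=1)  # (B, W)
    # group means over subjects (B, G) and cell means (B, G, W)
    group_sum = np.zeros((B, n_groups))
    cell_sum = np.zeros((B, n_groups, W))
    np.add.at(group_sum, (slice(None), gcodes), subj_mean)
    np.add.at(cell_sum, (slice(None), gcodes), Y)
    group_mean = group_sum / counts[None, :]
    cell_mean = cell_sum / counts[None, :, None]

    ss_between = W * np.sum(counts[None, :] * (group_mean - grand[:, None]) ** 2, axis=1)
    ss_subj = W * np.sum((subj_mean - group_mean[:, gcodes]) ** 2, axis=1)
    ss_within = S * np.sum((within_mean - grand[:, None]) ** 2, axis=1)
    inter = (
        cell_mean
        - group_mean[:, :, None]
        - within_mean[:, None, :]
        + grand[:, None, None]
    )
    ss_inter = np.sum(counts[None, :, None] * inter**2, axis=(1, 2))
    ss_err = (
        np.sum((Y - subj_mean[:, :, None] - cell_mean[:, gcodes, :]
                + group_mean[:, gcodes, None]) ** 2, axis=(1, 2))
    )

    df_b = n_groups - 1
    df_s = S - n_groups
    df_w = W - 1
    df_i = df_b * df_w
    df_e = df_s * df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        F_b = (ss_between / df_b) / (ss_subj / df_s)
        F_w = (ss_within / df_w) / (ss_err / df_e)
        F_i = (ss_inter / df_i) / (ss_err / df_e)
    F_b, F_w, F_i = (np.nan_to_num(F, nan=0.0, posinf=np.inf) for F in (F_b, F_w, F_i))
    if not batch:
        return float(F_b[0]), float(F_w[0]), float(F_i[0])
    return F_b, F_w, F_i


def perm_splitplot(y, subject, between, within, m: int = 50_000, seed: int = 123) -> SplitPlotResult:
    """Permutation ANOVA for a split-plot repeated-measures design.

    Classical F statistics: the between-subject effect is tested against
    the subjects-within-groups mean square; the within-subject effect and
    the interaction against the within-subject error mean square.
    Permutation schemes — between: whole-subject profiles are permuted
    across between-group labels; within/interaction: within-level labels
    are independently permuted inside each subject, with one shared
    permutation per iteration for both statistics.
    """
    Y, gcodes, _ = _splitplot_layout(y, subject, between, within)
    S, W = Y.shape
    n_groups = int(gcodes.max()) + 1
    if n_groups < 2:
        raise ValueError("need at least 2 between-subject levels")
    F_b, F_w, F_i = _splitplot_f(Y, gcodes, n_groups)

    rng = np.random.default_rng(seed)
    block = max(1, min(m, int(5e6) // (S * W)))

    # between-subject F depends only on subject means, so its permutation
    # null (relabelling whole-subject profiles) vectorises at subject level
    subj_mean = Y.mean(axis=1)
    counts = np.bincount(gcodes, minlength=n_groups).astype(float)
    Mind = np.zeros((S, n_groups))
    Mind[np.arange(S), gcodes] = 1.0
    grand = subj_mean.mean()
    df_b, df_s = n_groups - 1, S - n_groups

    def f_between_means(sm):  # sm: (k, S)
        gm = (sm @ Mind) / counts[None, :]
        ss_b = np.sum(counts[None, :] * (gm - grand) ** 2, axis=1)
        ss_s = np.sum(sm**2, axis=1) - np.sum(counts[None, :] * gm**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_b / df_b) / (ss_s / df_s)
        return np.nan_to_num(F, nan=0.0, posinf=np.inf)

    b_between = b_within = b_inter = 0
    done = 0
    while done < m:
        k = min(block, m - done)
        # between: permute subject profiles across group labels
        perm_g = np.argsort(rng.random((k, S)), axis=1)
        b_between += int(np.sum(f_between_means(subj_mean[perm_g]) >= F_b))
        # within/interaction: shared within-subject label permutation
        perm_w = np.argsort(rng.random((k, S, W)), axis=2)
        Yp = np.take_along_axis(np.broadcast_to(Y, (k, S, W)), perm_w, axis=2)
        _, Fw_perm, Fi_perm = _splitplot_f(Yp, gcodes, n_groups)
        b_within += int(np.sum(Fw_perm >= F_w))
        b_inter += int(np.sum(Fi_perm >= F_i))
        done += k

    df_w = W - 1
    return SplitPlotResult(
        between=_p_from_counts(b_between, m, seed, F_b, df_b, df_s),
        within=_p_from_counts(b_within, m, seed, F_w, df_w, df_s * df_w),
        interaction=_p_from_counts(b_inter, m, seed, F_i, df_b * df_w, df_s * df_w),
        n_subjects=S,
        n_between_levels=n_groups,
        n_within_levels=W,
    )


def posthoc_simple_effects(
    y, subject, between, within, m: int = 50_000, seed: int = 123
) -> pd.DataFrame:
    """Simple main effects of the between factor at each within level.

    At each within level a two-sample permutation test on |Δ group mean| is
    run; Holm's step-down correction is applied across the within levels.
    Returns a frame with columns within_level, abs_mean_diff, p_raw,
    p_holm, below_floor, p_floor.
    """
    Y, gcodes, wlevels = _splitplot_layout(y, subject, between, within)
    if gcodes.max() + 1 != 2:
        raise ValueError("simple-effect post hocs are defined for 2 between-subject levels")
    rng = np.random.default_rng(seed)
    rows = []
    for w, level in enumerate(wlevels):
        v = Y[:, w]
        obs = abs(v[gcodes == 0].mean() - v[gcodes == 1].mean())
        perms = np.argsort(rng.random((m, len(v))), axis=1)
        vp = v[perms]  # (m, S)
        g0 = gcodes == 0
        d = np.abs(vp[:, g0].mean(axis=1) - vp[:, ~g0].mean(axis=1))
        b = int(np.sum(d >= obs))
        rows.append(
            {
                "within_level": level,
                "abs_mean_diff": obs,
                "p_raw": (b + 1) / (m + 1),
                "below_floor": b == 0,
                "p_floor": 1.0 / m,
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def holm_adjust(p) -> np.ndarray:
    """Holm step-down familywise-error adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be a 1-D vector in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="holm")[1]


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must be a 1-D vector in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def rank_tests(x, y, paired: bool) -> dict:
    """Two-sided Wilcoxon signed-rank (paired) or rank-sum (unpaired) test.

    Exact enumeration when n ≤ 12 without ties; tie-corrected normal
    approximation otherwise. All-zero paired differences raise, as the
    statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            raise ValueError("all paired differences are zero; statistic undefined")
        d = d[d != 0]
        has_ties = len(np.unique(np.abs(d))) < len(d)
        method = "exact" if (len(d) <= 12 and not has_ties) else "approx"
        res = stats.wilcoxon(d, alternative="two-sided", method=method, correction=method == "approx")
        name = "signed_rank_W"
    else:
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (max(len(x), len(y)) <= 12 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        name = "rank_sum_U"
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "statistic_name": name}
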