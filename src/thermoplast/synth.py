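"""Seeded synthetic-data generators with known ground truth.

Three generators produce every input the analysis modules consume:

* :func:`gen_thermal_dataset` — per-individual critical thermal limits
  (zero-performance anchors) plus sprint speed at a series of test
  temperatures, drawn from Kamykowski curves with individual-level
  parameter variation;
* :func:`gen_expression_dataset` — a gene × sample count matrix with
  planted co-expression modules (shared latent factors) of which one is
  shifted between experimental groups;
* :func:`gen_genome_fixture` — a toy genome with strand-balanced,
  non-overlapping genes, ATAC-style peaks, a differential-peak table,
  motif footprint scores and DEG/DSG lists, with planted peak–gene and
  footprint–promoter links.

Every generator is a pure function of its config and seed; each call
derives one private :class:`numpy.random.Generator` stream so repeated
calls are byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tpc import TPCParams, TRAIT_COLUMNS, kamykowski_performance

__all__ = [
    "SynthThermalConfig",
    "SynthExprConfig",
    "SynthGenomeConfig",
    "TruthRecord",
    "gen_thermal_dataset",
    "gen_expression_dataset",
    "gen_genome_fixture",
]

_PARAMS = ("tmin", "tmax", "a", "b", "c")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """One private RNG stream per generator call, keyed by a stream name."""
    return np.random.default_rng(np.random.SeedSequence([seed, abs(hash_stable(stream))]))


def hash_stable(s: str) -> int:
    """Deterministic (process-independent) 31-bit hash of a short string."""
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class TruthRecord:
    """Ground-truth values planted by a generator, serialisable to JSON."""

    kind: str
    data: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            if isinstance(o, TPCParams):
                return {k: getattr(o, k) for k in _PARAMS}
            raise TypeError(type(o))

        Path(path).write_text(json.dumps({"kind": self.kind, "data": self.data}, default=default, indent=1))


# ---------------------------------------------------------------------------
# thermal traits


@dataclass
class SynthThermalConfig:
    """Study-like thermal trait layout: 2 acclimation groups, per-individual
    TPCs with Topt in the high 30s °C and Pmax near 0.73 / 0.85 m/s."""

    n_groups: int = 2
    n_individuals_per_group: int = 15
    pop_params_per_group: tuple[TPCParams, ...] = (
        TPCParams(tmin=5.5, tmax=43.5, a=0.85, b=0.06, c=0.9),
        TPCParams(tmin=6.0, tmax=44.5, a=0.9, b=0.08, c=1.4),
    )
    sd_individual: dict[str, float] = field(
        default_factory=lambda: {"tmin": 0.7, "tmax": 0.7, "a": 0.06, "b": 0.008, "c": 0.12}
    )
    sd_obs: float = 0.05
    test_temperatures: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0, 35.0, 37.0)
    ramp_rate_range: tuple[float, float] = (0.7, 1.7)
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals_per_group < 2:
            raise ValueError("n_individuals_per_group must be >= 2")
        if len(self.pop_params_per_group) < self.n_groups:
            raise ValueError("pop_params_per_group must supply one TPCParams per group")
        if any(v <= 0 for v in self.sd_individual.values()):
            raise ValueError("sd_individual entries must all be > 0")
        if self.sd_obs < 0:
            raise ValueError("sd_obs must be >= 0")
        tt = np.asarray(self.test_temperatures)
        if tt.size == 0 or np.any(np.diff(tt) <= 0):
            raise ValueError("test_temperatures must be strictly increasing")
        if not self.ramp_rate_range[0] < self.ramp_rate_range[1]:
            raise ValueError("ramp_rate_range must be an increasing pair")


def gen_thermal_dataset(cfg: SynthThermalConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a long trait table plus its ground truth.

    Per individual: one CTmin and one CTmax anchor row (performance 0 at the
    individual's own critical limit, with a uniform ramp-rate covariate) and
    one sprint row per test temperature, y = clamp0(curve) + Gaussian noise
    (re-clamped at 0 since speeds cannot be negative). Individual parameters
    are population values plus independent Gaussian deviations, truncated to
    keep the curve valid.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "thermal")
    rows = []
    truth_ind: dict[str, dict] = {}
    for g in range(cfg.n_groups):
        pop = cfg.pop_params_per_group[g]
        group = f"group{g + 1}"
        for i in range(cfg.n_individuals_per_group):
            ind = f"{group}_ind{i + 1:02d}"
            while True:  # redraw until the parameter set is a valid curve
                vals = {
                    k: getattr(pop, k) + cfg.sd_individual[k] * rng.standard_normal()
                    for k in _PARAMS
                }
                if vals["tmin"] < vals["tmax"] and min(vals["a"], vals["b"], vals["c"]) > 0:
                    break
            theta = TPCParams(**vals)
            truth_ind[ind] = {"group": group, **vals}
            for kind, temp in (("ctmin_anchor", theta.tmin), ("ctmax_anchor", theta.tmax)):
                rows.append(
                    (ind, group, kind, temp, 0.0, float(rng.uniform(*cfg.ramp_rate_range)))
                )
            for T in cfg.test_temperatures:
                y = kamykowski_performance(T, theta) + cfg.sd_obs * rng.standard_normal()
                rows.append((ind, group, "sprint", float(T), max(0.0, float(y)), np.nan))
    table = pd.DataFrame(rows, columns=list(TRAIT_COLUMNS))
    truth = TruthRecord(
        kind="thermal",
        data={
            "population": {
                f"group{g + 1}": {k: getattr(cfg.pop_params_per_group[g], k) for k in _PARAMS}
                for g in range(cfg.n_groups)
            },
            "individuals": truth_ind,
            "sd_obs": cfg.sd_obs,
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# expression


@dataclass
class SynthExprConfig:
    """Planted-module RNA-seq-like counts: latent factors shared within
    modules, one module's factor shifted between two sample groups."""

    n_genes: int = 2000
    n_samples_per_group: int = 8
    n_groups: int = 2
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (100, 100, 100)
    module_group_effect: float = 2.0
    within_module_corr: float = 0.8
    library_size: float = 5e5
    dispersion: float | None = None  # None -> Poisson; else NB with this 1/size
    latent_scale: float = 0.5  # log-scale amplitude of the latent signal
    module_var_boost: float = 1.8  # SD multiplier for module genes (keeps corr)
    seed: int = 0

    def validate(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes must have n_modules entries")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if not 0 <= self.within_module_corr < 1:
            raise ValueError("within_module_corr must lie in [0, 1)")
        if self.n_samples_per_group < 2:
            raise ValueError("n_samples_per_group must be >= 2")


def gen_expression_dataset(
    cfg: SynthExprConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (counts genes×samples, sample table, truth).

    Genes in module m share a latent factor f_m with loading
    sqrt(within_module_corr), so pairwise latent correlation is approximately
    the configured value. Module 1's factor mean is shifted by
    ``module_group_effect`` (latent SD units) in the last group. The latent
    matrix is mapped through an exponential link onto gene baseline
    abundances and counts drawn Poisson (or negative binomial when a
    dispersion is configured).
    """
    cfg.validate()
    rng = _rng(cfg.seed, "expression")
    n_samp = cfg.n_samples_per_group * cfg.n_groups
    samples = [
        f"g{g + 1}_s{i + 1:02d}" for g in range(cfg.n_groups) for i in range(cfg.n_samples_per_group)
    ]
    group = np.repeat([f"group{g + 1}" for g in range(cfg.n_groups)], cfg.n_samples_per_group)
    genes = [f"gene{i + 1:05d}" for i in range(cfg.n_genes)]

    module_of = np.full(cfg.n_genes, "unassigned", dtype=object)
    pos = 0
    # orthogonalised module factors: planted modules are mutually
    # uncorrelated by construction — and uncorrelated with the group
    # indicator before the planted shift is added — so the truth record's
    # independence claims hold exactly even at small sample counts
    ind = (group == f"group{cfg.n_groups}").astype(float)
    ind = ind - ind.mean()
    raw = rng.standard_normal((n_samp, cfg.n_modules))
    basis = np.column_stack([ind, raw - raw.mean(axis=0, keepdims=True)])
    q, _ = np.linalg.qr(basis)
    q = q[:, 1 : cfg.n_modules + 1]  # drop the indicator direction
    factors = (q / q.std(axis=0, ddof=0)).T  # (n_modules, n_samp), unit variance
    for m, size in enumerate(cfg.module_sizes):
        if m == 0 and cfg.module_group_effect != 0:
            factors[m] = factors[m] + cfg.module_group_effect * (
                group == f"group{cfg.n_groups}"
            )
        module_of[pos : pos + size] = f"M{m + 1}"
        pos += size

    rho = cfg.within_module_corr
    latent = rng.standard_normal((cfg.n_genes, n_samp))
    for m, size in enumerate(cfg.module_sizes):
        sl = slice(sum(cfg.module_sizes[:m]), sum(cfg.module_sizes[: m + 1]))
        latent[sl] = cfg.module_var_boost * (
            np.sqrt(rho) * factors[m][None, :] + np.sqrt(1 - rho) * latent[sl]
        )

    base = rng.lognormal(mean=0.0, sigma=1.2, size=cfg.n_genes)
    rel = base / base.sum()
    lam = cfg.library_size * rel[:, None] * np.exp(cfg.latent_scale * latent)
    if cfg.dispersion is None:
        counts = rng.poisson(lam)
    else:
        size = 1.0 / cfg.dispersion
        counts = rng.negative_binomial(size, size / (size + lam))

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    sample_df = pd.DataFrame({"sample_id": samples, "group": group})
    truth = TruthRecord(
        kind="expression",
        data={
            "module_of": {g: m for g, m in zip(genes, module_of)},
            "trait_linked_module": "M1" if cfg.module_group_effect != 0 else None,
            "latent": latent,
            "factors": factors,
            "within_module_corr": rho,
        },
    )
    return counts_df, sample_df, truth


# ---------------------------------------------------------------------------
# genome fixture


@dataclass
class SynthGenomeConfig:
    """Toy genome: non-overlapping strand-balanced genes, peaks, footprints."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 1_000_000})
    n_genes: int = 50
    n_peaks: int = 200
    n_diff_peaks: int = 30
    n_linked_genes: int = 10  # genes given a planted differential peak in their 5-kb window
    n_deg: int = 15
    n_deg_footprint: int = 6  # DEGs given a promoter footprint with |fold change| > 2
    motif_ids: tuple[str, ...] = ("MOTIF_A", "MOTIF_B", "MOTIF_C")
    gene_length_range: tuple[int, int] = (500, 3000)
    peak_length_range: tuple[int, int] = (150, 500)
    flank: int = 5000
    promoter_up: int = 1000
    promoter_down: int = 100
    seed: int = 0

    def validate(self) -> None:
        if self.n_linked_genes > self.n_genes or self.n_deg > self.n_genes:
            raise ValueError("planted subset larger than n_genes")
        if self.n_deg_footprint > self.n_deg:
            raise ValueError("n_deg_footprint exceeds n_deg")
        if self.n_diff_peaks > self.n_peaks:
            raise ValueError("n_diff_peaks exceeds n_peaks")


def _place_genes(cfg: SynthGenomeConfig, rng) -> pd.DataFrame:
    chroms = list(cfg.chrom_sizes)
    sizes = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    n_per = np.maximum(1, np.round(cfg.n_genes * sizes / sizes.sum()).astype(int))
    while n_per.sum() > cfg.n_genes:
        n_per[np.argmax(n_per)] -= 1
    while n_per.sum() < cfg.n_genes:
        n_per[np.argmax(sizes)] += 1
    rows = []
    gi = 0
    for chrom, n in zip(chroms, n_per):
        clen = cfg.chrom_sizes[chrom]
        lengths = rng.integers(*cfg.gene_length_range, size=n, endpoint=True)
        # need room for genes plus >= 2*flank spacing so windows stay informative
        slack = clen - lengths.sum() - (n + 1) * 2 * cfg.flank
        if slack < 0:
            raise ValueError(
                f"cannot place {n} non-overlapping genes on {chrom} (length {clen})"
            )
        gaps = rng.multinomial(int(slack), np.full(n + 1, 1 / (n + 1)))
        pos = 0
        for k in range(n):
            pos += gaps[k] + 2 * cfg.flank
            start = int(pos)
            end = start + int(lengths[k])
            strand = "+" if gi % 2 == 0 else "-"
            rows.append((chrom, start, end, f"gene{gi + 1:04d}", 0, strand))
            pos = end
            gi += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "score", "strand"])


def gen_genome_fixture(cfg: SynthGenomeConfig) -> dict:
    """Generate the toy genome bundle.

    Returns a dict with keys ``genes`` (BED6-like frame), ``peaks``
    (narrowPeak frame), ``diff_peaks``, ``footprints``, ``deg``, ``dsg``
    and ``truth``. Genes are strand-alternating and non-overlapping with
    ≥2×flank spacing; a chosen subset of genes receives a planted
    differential peak inside its ±flank window; a chosen subset of DEGs
    receives a promoter footprint whose fold change exceeds 2. The truth
    record is recomputed from the emitted intervals by a direct scan, so it
    also reflects any coincidental overlaps of the background peaks.
    """
    cfg.validate()
    rng = _rng(cfg.seed, "genome")
    genes = _place_genes(cfg, rng)

    # peaks: planted differential peaks inside chosen gene windows, the rest
    # uniform over each chromosome
    linked = list(rng.choice(genes["gene_id"], size=cfg.n_linked_genes, replace=False))
    peak_rows = []

    def add_peak(chrom, start, end, name, diff):
        summit = int((end - start) // 2)
        peak_rows.append(
            (chrom, int(start), int(end), name, int(rng.integers(100, 1000)), ".",
             float(rng.uniform(2, 20)), float(rng.uniform(2, 10)), float(rng.uniform(1, 8)),
             summit, diff)
        )

    n_bg_diff = cfg.n_diff_peaks - cfg.n_linked_genes
    if n_bg_diff < 0:
        raise ValueError("n_diff_peaks must be >= n_linked_genes")
    for j, gid in enumerate(linked):
        g = genes.loc[genes["gene_id"] == gid].iloc[0]
        length = int(rng.integers(*cfg.peak_length_range, endpoint=True))
        lo = max(0, g.start - cfg.flank)
        hi = min(cfg.chrom_sizes[g.chrom], g.end + cfg.flank) - length
        start = int(rng.integers(lo, hi))
        add_peak(g.chrom, start, start + length, f"peak_planted{j + 1:03d}", True)

    chroms = list(cfg.chrom_sizes)
    probs = np.array([cfg.chrom_sizes[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    n_bg = cfg.n_peaks - cfg.n_linked_genes
    for j in range(n_bg):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        length = int(rng.integers(*cfg.peak_length_range, endpoint=True))
        start = int(rng.integers(0, cfg.chrom_sizes[chrom] - length))
        add_peak(chrom, start, start + length, f"peak_bg{j + 1:04d}", j < n_bg_diff)

    peaks = pd.DataFrame(
        peak_rows,
        columns=["chrom", "start", "end", "name", "score", "strand", "signalValue",
                 "pValue", "qValue", "peak", "is_differential"],
    )
    diff_mask = peaks["is_differential"].astype(bool)
    diff_peaks = peaks[diff_mask].drop(columns="is_differential").reset_index(drop=True)
    peaks = peaks.drop(columns="is_differential")

    # DEG/DSG lists; a subset of DEGs gets a strong promoter footprint
    deg = list(rng.choice(genes["gene_id"], size=cfg.n_deg, replace=False))
    dsg = list(rng.choice(genes["gene_id"], size=max(1, cfg.n_deg // 2), replace=False))
    fp_hits = list(rng.choice(deg, size=cfg.n_deg_footprint, replace=False))

    fp_rows = []
    gene_ix = genes.set_index("gene_id")

    def promoter(g):
        if g.strand == "+":
            lo, hi = g.start - cfg.promoter_up, g.start + cfg.promoter_down
        else:
            lo, hi = g.end - cfg.promoter_down, g.end + cfg.promoter_up
        clen = cfg.chrom_sizes[g.chrom]
        return max(0, lo), min(clen, hi)

    for j, gid in enumerate(fp_hits):
        g = gene_ix.loc[gid]
        lo, hi = promoter(g)
        start = int(rng.integers(lo, hi - 12))
        motif = cfg.motif_ids[j % len(cfg.motif_ids)]
        log2fc = float(rng.uniform(1.2, 3.0)) * (1 if rng.random() < 0.5 else -1)
        a = float(rng.uniform(1, 5))
        fp_rows.append((motif, g.chrom, start, start + 12, a, a * 2.0**log2fc, log2fc))
    # weak / off-promoter background footprints
    for j in range(4 * len(cfg.motif_ids)):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        start = int(rng.integers(0, cfg.chrom_sizes[chrom] - 12))
        motif = cfg.motif_ids[j % len(cfg.motif_ids)]
        log2fc = float(rng.uniform(-0.9, 0.9))
        a = float(rng.uniform(1, 5))
        fp_rows.append((motif, chrom, start, start + 12, a, a * 2.0**log2fc, log2fc))
    footprints = pd.DataFrame(
        fp_rows,
        columns=["motif_id", "chrom", "start", "end", "score_condA", "score_condB", "log2fc"],
    )

    # truth recomputed from emitted records by a direct interval scan
    def overlaps(a_lo, a_hi, b_lo, b_hi):
        return a_lo < b_hi and b_lo < a_hi

    dpg_truth = set()
    for g in genes.itertuples():
        lo = max(0, g.start - cfg.flank)
        hi = min(cfg.chrom_sizes[g.chrom], g.end + cfg.flank)
        for p in diff_peaks.itertuples():
            if p.chrom == g.chrom and overlaps(lo, hi, p.start, p.end):
                dpg_truth.add(g.gene_id)
                break
    fp_truth = set()
    for gid in deg:
        g = gene_ix.loc[gid]
        lo, hi = promoter(g)
        for f in footprints.itertuples():
            if (
                f.chrom == g.chrom
                and overlaps(lo, hi, f.start, f.end)
                and abs(f.log2fc) > 1.0  # raw fold change > 2
            ):
                fp_truth.add(gid)
                break

    truth = TruthRecord(
        kind="genome",
        data={
            "planted_linked_genes": sorted(linked),
            "dpg_genes": sorted(dpg_truth),
            "deg": sorted(deg),
            "dsg": sorted(dsg),
            "footprint_filtered_degs": sorted(fp_truth),
        },
    )
    return {
        "genes": genes,
        "peaks": peaks,
        "diff_peaks": diff_peaks,
        "footprints": footprints,
        "deg": deg,
        "dsg": dsg,
        "truth": truth,
    }
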