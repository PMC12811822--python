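"""Configuration, validation and end-to-end orchestration.

A run is described by a small YAML/dict config (stage selection, per-stage
parameter blocks, global seed). Stages execute in dependency order
(simulate → tpc / perm / coexpr / windows); every stage derives its own RNG
seed from the global seed by a stable string hash, so identical configs
produce byte-identical outputs and digests.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpr, permstats, synth, tpc, windows as win
from .synth import hash_stable

__all__ = ["RunConfig", "RunReport", "StageReport", "run_pipeline", "validate_inputs", "load_config"]

STAGES = ("simulate", "tpc", "perm", "coexpr", "windows")

_ALLOWED = {
    "": {"seed", "stages", "simulate", "tpc", "perm", "coexpr", "windows"},
    "simulate": {"thermal", "expression", "genome"},
    "simulate.thermal": {
        "n_groups", "n_individuals_per_group", "sd_obs", "test_temperatures", "seed",
    },
    "simulate.expression": {
        "n_genes", "n_samples_per_group", "n_modules", "module_sizes",
        "module_group_effect", "within_module_corr", "library_size", "seed",
    },
    "simulate.genome": {
        "n_genes", "n_peaks", "n_diff_peaks", "n_linked_genes", "n_deg",
        "n_deg_footprint", "seed",
    },
    "tpc": {"chains", "warmup", "draws", "seed"},
    "perm": {"n_perm", "seed"},
    "coexpr": {
        "cpm_min", "min_frac", "top_n", "r2_target", "min_size", "merge_height",
        "n_boot", "height_cutoff", "seed",
    },
    "windows": {"flank", "promoter_up", "promoter_down", "fc_threshold"},
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 123
    stages: tuple[str, ...] = STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _validate_keys(raw, "")
        stages = tuple(raw.get("stages", STAGES))
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")
        params = {k: raw.get(k, {}) for k in STAGES}
        return cls(seed=int(raw.get("seed", 123)), stages=stages, params=params)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 2654435761 + hash_stable(stage)) % (2**31 - 1)


def _validate_keys(block: dict, prefix: str) -> None:
    allowed = _ALLOWED.get(prefix)
    if allowed is None:
        return
    for key in block:
        if key not in allowed:
            where = prefix or "top level"
            raise ValueError(f"unknown config key {key!r} in {where}")
        sub = f"{prefix}.{key}" if prefix else key
        if sub in _ALLOWED and isinstance(block[key], dict):
            _validate_keys(block[key], sub)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.from_dict(raw)


@dataclass
class StageReport:
    stage: str
    status: str  # completed | failed | skipped
    wall_time_s: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)  # file -> sha256
    warnings: list[str] = field(default_factory=list)
    error: str | None = None


@dataclass
class RunReport:
    stages: list[StageReport] = field(default_factory=list)

    def digests(self) -> dict[str, str]:
        out = {}
        for s in self.stages:
            out.update(s.outputs)
        return out

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage": s.stage,
                    "status": s.status,
                    "wall_time_s": round(s.wall_time_s, 3),
                    "outputs": s.outputs,
                    "warnings": s.warnings,
                    "error": s.error,
                }
                for s in self.stages
            ]
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, float_format="%.10g", **kw)


# ---------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["simulate"]
    tcfg = synth.SynthThermalConfig(seed=cfg.stage_seed("simulate.thermal"), **p.get("thermal", {}))
    traits, truth_t = synth.gen_thermal_dataset(tcfg)
    _write_csv(traits, out / "traits.csv", index=False)
    truth_t.to_json(out / "truth_thermal.json")

    ecfg_kw = dict(p.get("expression", {}))
    if "module_sizes" in ecfg_kw:
        ecfg_kw["module_sizes"] = tuple(ecfg_kw["module_sizes"])
    ecfg = synth.SynthExprConfig(seed=cfg.stage_seed("simulate.expression"), **ecfg_kw)
    counts, samples, truth_e = synth.gen_expression_dataset(ecfg)
    _write_csv(counts, out / "counts.tsv", sep="\t", index_label="gene_id")
    _write_csv(samples, out / "samples.csv", index=False)
    synth.TruthRecord(
        kind="expression",
        data={k: v for k, v in truth_e.data.items() if k != "latent" and k != "factors"},
    ).to_json(out / "truth_expression.json")

    gcfg = synth.SynthGenomeConfig(seed=cfg.stage_seed("simulate.genome"), **p.get("genome", {}))
    bundle = synth.gen_genome_fixture(gcfg)
    win.write_bed6(bundle["genes"], out / "genes.bed")
    win.write_gff3_genes(bundle["genes"], out / "genes.gff3")
    win.write_narrowpeak(bundle["peaks"], out / "peaks.narrowPeak")
    win.write_narrowpeak(bundle["diff_peaks"], out / "diff_peaks.narrowPeak")
    _write_csv(bundle["footprints"], out / "footprints.tsv", sep="\t", index=False)
    (out / "deg.txt").write_text("\n".join(bundle["deg"]) + "\n")
    (out / "dsg.txt").write_text("\n".join(bundle["dsg"]) + "\n")
    bundle["truth"].to_json(out / "truth_genome.json")
    (out / "chrom_sizes.json").write_text(json.dumps(gcfg.chrom_sizes))
    return sorted(out.glob("*"))


def _stage_tpc(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["tpc"]
    traits = pd.read_csv(out / "traits.csv")
    mcfg = tpc.MCMCConfig(
        chains=p.get("chains", 4),
        warmup=p.get("warmup", 1000),
        draws=p.get("draws", 1000),
        seed=p.get("seed", cfg.stage_seed("tpc")),
    )
    written = []
    summaries = {}
    for group, sub in traits.groupby("group"):
        draws = tpc.fit_hierarchical_tpc(sub, mcmc_cfg=mcfg)
        derived = tpc.derive_pmax_topt(draws)
        bands = tpc.posterior_curve_bands(
            draws, np.linspace(draws.bounds.init["tmin"], draws.bounds.init["tmax"], 61)
        )
        _write_csv(draws.summary(), out / f"tpc_{group}_summary.csv", index=False)
        _write_csv(bands, out / f"tpc_{group}_bands.csv", index=False)
        _write_csv(derived.to_frame(), out / f"tpc_{group}_derived.csv", index=False)
        summaries[group] = {
            "pmax_median": float(np.median(derived.pmax)),
            "topt_median": float(np.median(derived.topt)),
            "converged": draws.converged,
            "max_rhat": float(np.nanmax(list(draws.rhat.values()))),
        }
        written += [
            out / f"tpc_{group}_summary.csv",
            out / f"tpc_{group}_bands.csv",
            out / f"tpc_{group}_derived.csv",
        ]
    (out / "tpc_report.json").write_text(json.dumps(summaries, indent=1, sort_keys=True))
    return written + [out / "tpc_report.json"]


def _stage_perm(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["perm"]
    m = p.get("n_perm", 50_000)
    seed = p.get("seed", cfg.stage_seed("perm"))
    traits = pd.read_csv(out / "traits.csv")
    report = {}
    for kind, label in (("ctmin_anchor", "ctmin"), ("ctmax_anchor", "ctmax")):
        sub = traits[traits["kind"] == kind]
        res = permstats.perm_ancova(
            sub["temperature_c"], sub["group"], sub["ramp_rate_c_per_min"], m=m, seed=seed
        )
        report[f"ancova_{label}"] = res.to_dict()
    sprint = traits[traits["kind"] == "sprint"]
    sp = permstats.perm_splitplot(
        sprint["performance_ms"], sprint["individual_id"], sprint["group"],
        sprint["temperature_c"], m=m, seed=seed,
    )
    report["splitplot"] = {
        "between": sp.between.to_dict(),
        "within": sp.within.to_dict(),
        "interaction": sp.interaction.to_dict(),
    }
    ph = permstats.posthoc_simple_effects(
        sprint["performance_ms"], sprint["individual_id"], sprint["group"],
        sprint["temperature_c"], m=m, seed=seed,
    )
    _write_csv(ph, out / "posthoc.csv", index=False)
    (out / "perm_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return [out / "perm_report.json", out / "posthoc.csv"]


def _stage_coexpr(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["coexpr"]
    counts = pd.read_csv(out / "counts.tsv", sep="\t", index_col="gene_id")
    samples = pd.read_csv(out / "samples.csv")
    expr = coexpr.filter_and_transform(
        counts, cpm_min=p.get("cpm_min", 1.0), min_frac=p.get("min_frac", 0.2)
    )
    expr = coexpr.remove_outlier_samples(expr, height_cutoff=p.get("height_cutoff", 1e6))
    expr = coexpr.top_variable(expr, n=p.get("top_n", 5000))
    power = coexpr.pick_soft_power(expr, r2_target=p.get("r2_target", 0.80))
    assignment = coexpr.detect_modules(
        expr, power.power, min_size=p.get("min_size", 30),
        merge_height=p.get("merge_height", 0.25),
    )
    eig = coexpr.module_eigengenes(expr, assignment)
    K = coexpr.kme(expr, eig)
    groups = samples.set_index("sample_id").loc[expr.columns, "group"]
    mt = coexpr.module_trait(eig, groups)
    hubs = coexpr.hub_genes(K, assignment)
    stab = coexpr.bootstrap_stability(
        expr, assignment, n_boot=p.get("n_boot", 50), seed=p.get("seed", cfg.stage_seed("coexpr"))
    )
    assignment.to_frame().to_csv(out / "modules.tsv", sep="\t")
    _write_csv(eig, out / "eigengenes.tsv", sep="\t")
    _write_csv(K, out / "kme.tsv", sep="\t")
    _write_csv(mt, out / "module_trait.csv", index=False)
    (out / "coexpr_report.json").write_text(
        json.dumps(
            {
                "soft_power": power.power,
                "scale_free_r2": round(power.r2, 6),
                "n_modules": len(set(assignment) - {coexpr.UNASSIGNED}),
                "hub_counts": {m: len(g) for m, g in hubs.items()},
                "stability": stab.to_dict(),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [
        out / "modules.tsv", out / "eigengenes.tsv", out / "kme.tsv",
        out / "module_trait.csv", out / "coexpr_report.json",
    ]


def _stage_windows(cfg: RunConfig, out: Path) -> list[Path]:
    p = cfg.params["windows"]
    chrom_sizes = json.loads((out / "chrom_sizes.json").read_text())
    genes = win.read_bed6(out / "genes.bed")
    peaks = win.read_narrowpeak(out / "peaks.narrowPeak")
    diff_peaks = win.read_narrowpeak(out / "diff_peaks.narrowPeak")
    footprints = win.read_footprints(out / "footprints.tsv")
    deg = (out / "deg.txt").read_text().split()
    dsg = (out / "dsg.txt").read_text().split()

    flanks = win.gene_flank_windows(genes, flank=p.get("flank", 5000), chrom_sizes=chrom_sizes)
    proms = win.promoter_windows(
        genes, up=p.get("promoter_up", 1000), down=p.get("promoter_down", 100),
        chrom_sizes=chrom_sizes,
    )
    dpg = win.classify_dpg(diff_peaks, flanks)
    cover_deg = win.peak_coverage_fraction(deg, peaks, flanks)
    cover_dsg = win.peak_coverage_fraction(dsg, peaks, flanks)
    filtered = win.footprint_promoter_filter(
        deg, footprints, proms, fc_threshold=p.get("fc_threshold", 2.0)
    )
    win.write_bed6(flanks.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]],
                   out / "gene_windows.bed")
    win.write_bed6(proms.assign(score=0)[["chrom", "start", "end", "gene_id", "score", "strand"]],
                   out / "promoters.bed")
    (out / "windows_report.json").write_text(
        json.dumps(
            {
                "n_dpg": len(dpg),
                "dpg": sorted(dpg),
                "deg_peak_coverage": cover_deg,
                "dsg_peak_coverage": cover_dsg,
                "footprint_filtered_degs": sorted(filtered),
                "dpg_overlap_deg": sorted(set(dpg) & set(deg)),
                "dpg_overlap_dsg": sorted(set(dpg) & set(dsg)),
            },
            indent=1,
            sort_keys=True,
        )
    )
    return [out / "gene_windows.bed", out / "promoters.bed", out / "windows_report.json"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "tpc": _stage_tpc,
    "perm": _stage_perm,
    "coexpr": _stage_coexpr,
    "windows": _stage_windows,
}
_DEPS = {"tpc": "simulate", "perm": "simulate", "coexpr": "simulate", "windows": "simulate"}


def run_pipeline(config: RunConfig | dict, out_dir) -> RunReport:
    """Execute the selected stages into ``out_dir``; returns a RunReport.

    A failed stage is recorded and dependent stages are skipped; identical
    config + seed produce identical output digests.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    failed: set[str] = set()
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        dep = _DEPS.get(stage)
        if dep and (dep in failed or (dep not in cfg.stages and not (out / "traits.csv").exists())):
            report.stages.append(StageReport(stage=stage, status="skipped",
                                             error=f"dependency {dep!r} unavailable"))
            continue
        t0 = time.perf_counter()
        entry = StageReport(stage=stage, status="completed")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                files = _STAGE_FN[stage](cfg, out)
            entry.warnings = [str(w.message) for w in caught]
            entry.outputs = {f.name: _sha256(Path(f)) for f in files if Path(f).is_file()}
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            entry.status = "failed"
            entry.error = f"{type(exc).__name__}: {exc}"
            failed.add(stage)
        entry.wall_time_s = time.perf_counter() - t0
        report.stages.append(entry)
    (out / "run_report.json").write_text(json.dumps(report.to_dict(), indent=1))
    return report


# ---------------------------------------------------------------------------
# input validation

_FORMAT_READERS = {
    "bed6": win.read_bed6,
    "narrowpeak": win.read_narrowpeak,
    "gff3": win.read_gff3_genes,
    "footprints": win.read_footprints,
    "traits": lambda p: _check_traits(pd.read_csv(p)),
    "counts": lambda p: _check_counts(pd.read_csv(p, sep="\t", index_col=0)),
}


def _check_traits(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in tpc.TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing column(s): {missing}")
    bad = set(df["kind"]) - set(tpc.OBS_KINDS)
    if bad:
        raise ValueError(f"unknown observation kind(s): {sorted(bad)}")
    return df


def _check_counts(df: pd.DataFrame) -> pd.DataFrame:
    if (df.to_numpy() < 0).any():
        raise ValueError("negative counts")
    return df


def validate_inputs(paths: dict[str, tuple[str, str]]) -> pd.DataFrame:
    """Check each file against its declared format.

    ``paths`` maps a label to (path, format) with format one of
    bed6 | narrowpeak | gff3 | footprints | traits | counts. Failures are
    report rows, not exceptions.
    """
    rows = []
    for label, (path, fmt) in paths.items():
        if fmt not in _FORMAT_READERS:
            rows.append({"label": label, "path": str(path), "format": fmt,
                         "ok": False, "message": f"unknown format {fmt!r}"})
            continue
        try:
            _FORMAT_READERS[fmt](path)
            rows.append({"label": label, "path": str(path), "format": fmt, "ok": True, "message": ""})
        except Exception as exc:  # noqa: BLE001
            rows.append({"label": label, "path": str(path), "format": fmt,
                         "ok": False, "message": str(exc)})
    return pd.DataFrame(rows)
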