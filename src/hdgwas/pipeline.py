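"""End-to-end orchestration: simulate → qc → derive → gwas → characterize →
scan → report, with a reproducibility manifest.

Each stage reads its inputs from the previous stage's on-disk outputs and
writes plain-text outputs (TSV tables, BED intervals, JSON manifests), so a
run is resumable: a stage whose outputs already exist is skipped, and
deleting an intermediate directory recomputes exactly the same files (all
randomness is drawn from per-stage children of the master seed; no
timestamps are written).  One environment per run: cross-environment
comparison is a report-level join, not a model.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import (
    GenotypeMatrix, CrossDesign, filter_markers, polymorphic_filter, maf_filter,
    knn_impute, combine_f1, heterozygosity, kinship, pca, read_vcf,
)
from .simulate import SimulationConfig, QtlSpec, simulate_parents, simulate_f1_phenotypes
from .phenotypes import derive_heterosis, normalize_phenotype
from .gwas import resample_rmip, significant_snps, merge_signals
from .hapblocks import hapblock_interval
from .qtl import (
    genotype_class, da_effects, superiority_class, variance_explained,
    superior_allele_accounting, favorable_direction,
)
from .selection import tajimas_d, low_d_regions, qtl_overlap

__all__ = ["load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "qc", "derive", "gwas", "characterize", "scan", "report")

FLOAT_FMT = "%.10g"


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    qtls = [QtlSpec(**q) for q in sim.pop("qtls", [])]
    return SimulationConfig(seed=int(cfg.get("seed", 0)), qtl_specs=qtls, **sim)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_done(out: Path, files: list[str]) -> bool:
    return all((out / f).exists() for f in files)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: dict, out: Path) -> list[str]:
    files = ["parents.vcf", "design.tsv", "phenotypes.tsv", "truth.json"]
    if _stage_done(out, files):
        return files
    sim = _sim_config(cfg)
    parents, design = simulate_parents(sim)
    table, truth, _f1 = simulate_f1_phenotypes(parents, design, sim)
    out.mkdir(parents=True, exist_ok=True)
    parents.to_vcf(out / "parents.vcf")
    design.to_tsv(out / "design.tsv")
    _write_tsv(table, out / "phenotypes.tsv")
    truth.to_json(out / "truth.json")
    return files


def _stage_qc(cfg: dict, out: Path, sim_dir: Path) -> list[str]:
    files = ["parents_qc.vcf", "f1_qc.vcf", "qc_report.json"]
    if _stage_done(out, files):
        return files
    qc = cfg.get("qc", {})
    parents = read_vcf(sim_dir / "parents.vcf")
    design = CrossDesign.from_tsv(sim_dir / "design.tsv")
    filtered, report = filter_markers(
        parents, qc.get("max_missing", 0.2), qc.get("max_het", 0.15)
    )
    # parents declared inbred: residual het calls treated as missing, then imputed
    het = filtered.calls == 1
    if het.any():
        filtered.calls[het] = -1
    if (filtered.calls == -1).any():
        filtered = knn_impute(filtered, k=qc.get("knn_k", 5))
    filtered = polymorphic_filter(filtered)
    f1 = combine_f1(filtered, design)
    f1 = maf_filter(f1, qc.get("min_maf", 0.05))
    keep = set(f1.markers["id"])
    parents_qc = filtered.subset_markers(filtered.markers["id"].isin(keep).to_numpy())
    per_sample, _ = heterozygosity(f1)
    out.mkdir(parents=True, exist_ok=True)
    parents_qc.to_vcf(out / "parents_qc.vcf")
    f1.to_vcf(out / "f1_qc.vcf")
    payload = {
        "n_input": report.n_input,
        "n_removed_missing": report.n_removed_missing,
        "n_removed_het": report.n_removed_het,
        "n_after_polymorphic": filtered.n_markers,
        "n_after_maf": f1.n_markers,
        "f1_heterozygosity_median": round(float(per_sample.median()), 6),
        "f1_heterozygosity_range": [round(float(per_sample.min()), 6), round(float(per_sample.max()), 6)],
    }
    (out / "qc_report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return files


def _stage_derive(cfg: dict, out: Path, sim_dir: Path) -> list[str]:
    files = ["derived.tsv"]
    if _stage_done(out, files):
        return files
    sim = _sim_config(cfg)
    table = pd.read_csv(sim_dir / "phenotypes.tsv", sep="\t")
    design = CrossDesign.from_tsv(sim_dir / "design.tsv")
    derived = derive_heterosis(table, design, sim.trait, sim.environment)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(derived, out / "derived.tsv")
    return files


def _gwas_categories(cfg: dict) -> list[str]:
    return list(cfg.get("categories", ["F1", "BPaV", "SCA"]))


def _stage_gwas(cfg: dict, out: Path, qc_dir: Path, derive_dir: Path) -> list[str]:
    cats = _gwas_categories(cfg)
    files = [f"rmip_{c}.tsv" for c in cats] + [f"signals_{c}.bed" for c in cats] + ["gwas_manifest.json"]
    if _stage_done(out, files):
        return files
    g = cfg.get("gwas", {})
    f1 = read_vcf(qc_dir / "f1_qc.vcf")
    derived = pd.read_csv(derive_dir / "derived.tsv", sep="\t").set_index("f1")
    kin = kinship(f1)
    seed = int(cfg.get("seed", 0))
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"thresholds": {}, "seed": seed}
    normalize = bool(g.get("normalize", True))
    for ci, cat in enumerate(cats):
        vals = derived[cat]
        if normalize:
            pheno = pd.Series(normalize_phenotype(vals), index=vals.index)
        else:
            pheno = vals.astype(float)
        covariates = None
        if g.get("f1_covariate_rerun") and cat in ("BPaV", "SCA", "MPV"):
            covariates = derived[["F1"]]
        result = resample_rmip(
            pheno,
            f1,
            kin,
            n_resamples=int(g.get("n_resamples", 50)),
            subsample_frac=float(g.get("subsample_frac", 0.8)),
            n_permutations=int(g.get("n_permutations", 100)),
            fdr=float(g.get("fdr", 0.05)),
            covariates=covariates,
            seed=int(np.random.SeedSequence([seed, 300 + ci]).generate_state(1)[0] % (2**31)),
        )
        rmip_tab = result.rmip.copy()
        rmip_tab.insert(0, "id", rmip_tab.index)
        rmip_tab["rmip_max"] = result.rmip_max
        _write_tsv(rmip_tab[rmip_tab["rmip_max"] > 0].reset_index(drop=True), out / f"rmip_{cat}.tsv")
        sig = significant_snps(result, f1, float(g.get("rmip_threshold", 5)))
        signals = merge_signals(
            sig, f1, int(g.get("merge_distance", 800_000)), float(g.get("min_r2", 0.2))
        )
        with open(out / f"signals_{cat}.bed", "w") as fh:
            for s in signals:
                fh.write(
                    f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.lead}\t{FLOAT_FMT % s.rmip}\t"
                    f"{s.best_model}\t{','.join(s.members)}\n"
                )
        manifest["thresholds"][cat] = result.threshold
    (out / "gwas_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return files


def _read_signals(path: Path) -> pd.DataFrame:
    rows = []
    for line in path.read_text().splitlines():
        chrom, start, end, lead, rmip, model, members = line.split("\t")
        rows.append(
            {
                "chrom": int(chrom), "start": int(start) + 1, "end": int(end),
                "lead": lead, "rmip": float(rmip), "best_model": model,
                "members": members,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "lead", "rmip", "best_model", "members"])


def _stage_characterize(cfg: dict, out: Path, sim_dir: Path, qc_dir: Path, derive_dir: Path, gwas_dir: Path) -> list[str]:
    files = ["qtl_report.tsv", "qtl_intervals.bed"]
    if _stage_done(out, files):
        return files
    ch = cfg.get("characterize", {})
    min_class_n = int(ch.get("min_class_n", 15))
    n_pcs = int(ch.get("n_pcs", 10))
    sim = _sim_config(cfg)
    direction = favorable_direction(sim.trait)
    parents = read_vcf(qc_dir / "parents_qc.vcf")
    f1 = read_vcf(qc_dir / "f1_qc.vcf")
    design = CrossDesign.from_tsv(sim_dir / "design.tsv")
    derived = pd.read_csv(derive_dir / "derived.tsv", sep="\t").set_index("f1")
    pcs = pca(f1, n_components=min(n_pcs, f1.n_samples - 1))

    rows = []
    bed_rows = []
    for cat in _gwas_categories(cfg):
        signals = _read_signals(gwas_dir / f"signals_{cat}.bed")
        pheno = derived[cat]
        f1_ids = [s for s in f1.samples if s in pheno.index]
        y = pheno.reindex(f1_ids).to_numpy(dtype=float)
        sidx = f1.sample_index(f1_ids)
        P = pcs.loc[f1_ids].to_numpy()
        for _, s in signals.iterrows():
            lead = s["lead"]
            j = int(f1.markers.index[f1.markers["id"] == lead][0])
            calls = f1.calls[sidx, j]
            cls, counts = genotype_class(calls, min_class_n)
            block = hapblock_interval(lead, parents)
            row = {
                "category": cat, "trait": sim.trait, "lead": lead,
                "chrom": s["chrom"], "qtl_start": block.start, "qtl_end": block.end,
                "rmip": s["rmip"], "best_model": s["best_model"],
                "n_AA": counts[0], "n_Aa": counts[1], "n_aa": counts[2],
                "class": cls,
            }
            if cls == "three_genotype":
                eff = da_effects(y, calls, P)
                row.update(
                    a=eff.a, d=eff.d, d_over_a=eff.d_over_a, stuber=eff.stuber,
                    superiority="NA",
                )
            else:
                sup, tied = superiority_class(y, calls, direction)
                row.update(a=np.nan, d=np.nan, d_over_a=np.nan, stuber="NA", superiority=sup)
            row["variance_explained"] = variance_explained(y, calls)
            rep = superior_allele_accounting(lead, pheno, parents, f1, design, direction)
            row.update(
                superior_allele=rep.superior_allele,
                superior_ratio_maternal=rep.ratio_maternal,
                superior_ratio_paternal=rep.ratio_paternal,
                superior_ratio_f1=rep.ratio_f1,
                contribution=rep.contribution,
                maternal_derived_fraction=rep.maternal_derived_fraction,
            )
            rows.append(row)
            bed_rows.append((s["chrom"], block.start - 1, block.end, f"{cat}:{lead}"))
    report_cols = [
        "category", "trait", "lead", "chrom", "qtl_start", "qtl_end", "rmip",
        "best_model", "n_AA", "n_Aa", "n_aa", "class", "a", "d", "d_over_a",
        "stuber", "superiority", "variance_explained", "superior_allele",
        "superior_ratio_maternal", "superior_ratio_paternal", "superior_ratio_f1",
        "contribution", "maternal_derived_fraction",
    ]
    report = pd.DataFrame(rows, columns=report_cols)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(report, out / "qtl_report.tsv")
    with open(out / "qtl_intervals.bed", "w") as fh:
        for chrom, start, end, name in bed_rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    return files


def _stage_scan(cfg: dict, out: Path, sim_dir: Path, qc_dir: Path) -> list[str]:
    files = ["tajimas_d.tsv", "low_d_regions.bed"]
    if _stage_done(out, files):
        return files
    sc = cfg.get("scan", {})
    parents = read_vcf(qc_dir / "parents_qc.vcf")
    design = CrossDesign.from_tsv(sim_dir / "design.tsv")
    scans = []
    for group, ids in (("maternal", design.maternal_lines), ("paternal", design.paternal_lines)):
        scans.append(
            tajimas_d(parents, ids, group, int(sc.get("window", 240_000)), int(sc.get("step", 20_000)))
        )
    scan = pd.concat(scans, ignore_index=True)
    regions = low_d_regions(scan, float(sc.get("percentile", 10.0)))
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(scan, out / "tajimas_d.tsv")
    with open(out / "low_d_regions.bed", "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{r['start'] - 1}\t{r['end']}\t{r['group']}\n")
    return files


def _stage_report(cfg: dict, out: Path, char_dir: Path, scan_dir: Path) -> list[str]:
    files = ["summary.json", "summary.tsv"]
    if _stage_done(out, files):
        return files
    qtls = pd.read_csv(char_dir / "qtl_report.tsv", sep="\t")
    regions_path = scan_dir / "low_d_regions.bed"
    regions_rows = []
    for line in regions_path.read_text().splitlines():
        chrom, start, end, group = line.split("\t")
        regions_rows.append({"chrom": int(chrom), "start": int(start) + 1, "end": int(end), "group": group})
    regions = pd.DataFrame(regions_rows, columns=["chrom", "start", "end", "group"])

    summary_rows = []
    overlap_counts: dict[str, int] = {}
    if not qtls.empty:
        intervals = qtls.rename(columns={"qtl_start": "start", "qtl_end": "end"})[
            ["category", "lead", "chrom", "start", "end"]
        ]
        flagged = qtl_overlap(intervals, regions)
        for g in ("maternal", "paternal"):
            col = f"overlap_{g}"
            overlap_counts[g] = int(flagged[col].sum()) if col in flagged else 0
    for cat, sub in qtls.groupby("category"):
        ve = sub["variance_explained"]
        summary_rows.append(
            {
                "category": cat,
                "n_qtls": len(sub),
                "n_three_genotype": int((sub["class"] == "three_genotype").sum()),
                "n_two_genotype": int((sub["class"] == "two_genotype").sum()),
                "n_hetero_superior": int((sub["superiority"] == "hetero_superior").sum()),
                "n_homo_superior": int((sub["superiority"] == "homo_superior").sum()),
                "mean_variance_explained": float(ve.mean()),
                "n_large_effect": int((ve > 0.10).sum()),
            }
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=[
            "category", "n_qtls", "n_three_genotype", "n_two_genotype",
            "n_hetero_superior", "n_homo_superior", "mean_variance_explained",
            "n_large_effect",
        ],
    )
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(summary, out / "summary.tsv")
    payload = {
        "per_category": summary.to_dict(orient="records"),
        "selection_overlap_counts": overlap_counts,
        "n_qtls_total": int(len(qtls)),
    }
    (out / "summary.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return files


# ---------------------------------------------------------------------------


def run_pipeline(cfg: dict, out_dir, resume: bool = True) -> dict:
    """Run all stages in dependency order and write ``manifest.json``.

    With ``resume=True`` (default) a stage whose output files all exist is
    skipped; because every stage's randomness is derived from the master
    seed, recomputing a deleted intermediate reproduces it bit-identically.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not resume:
        for stage in STAGES:
            d = out / stage
            if d.exists():
                for f in d.iterdir():
                    f.unlink()

    stage_files: dict[str, list[str]] = {}
    try:
        stage_files["simulate"] = _stage_simulate(cfg, out / "simulate")
        stage_files["qc"] = _stage_qc(cfg, out / "qc", out / "simulate")
        stage_files["derive"] = _stage_derive(cfg, out / "derive", out / "simulate")
        stage_files["gwas"] = _stage_gwas(cfg, out / "gwas", out / "qc", out / "derive")
        stage_files["characterize"] = _stage_characterize(
            cfg, out / "characterize", out / "simulate", out / "qc", out / "derive", out / "gwas"
        )
        stage_files["scan"] = _stage_scan(cfg, out / "scan", out / "simulate", out / "qc")
        stage_files["report"] = _stage_report(cfg, out / "report", out / "characterize", out / "scan")
    except Exception as exc:
        done = list(stage_files)
        failed = STAGES[len(done)] if len(done) < len(STAGES) else "?"
        raise RuntimeError(f"pipeline halted at stage {failed!r}: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": int(cfg.get("seed", 0)),
        "config": cfg,
        "stages": {
            stage: {f: _sha256(out / stage / f) for f in files}
            for stage, files in stage_files.items()
        },
    }
    gwas_manifest = out / "gwas" / "gwas_manifest.json"
    if gwas_manifest.exists():
        manifest["thresholds"] = json.loads(gwas_manifest.read_text()).get("thresholds", {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
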