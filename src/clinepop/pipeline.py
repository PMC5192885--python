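"""File-based orchestration of the analysis stages.

Stages (simulate -> qc -> stats -> outliers -> clines -> dispersal ->
report) communicate through plain-text files in a run directory so every
intermediate artifact is inspectable and the pipeline is restartable.
Every stochastic stage draws its seed deterministically from the master
seed, TSV outputs carry the config hash in a comment header, and a
manifest records the configuration of the run; rerunning with the same
config reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clines as cl
from . import dispersal as dsp
from .genotypes import GenotypeMatrix, PopulationMap, QCThresholds, allele_statistics, apply_qc_filters
from .io import (read_popmap, read_vcf, write_distance_matrix, write_popmap, write_vcf)
from .outliers import NullConfig, OutlierScan
from .simulate import SimulationConfig, simulate_dataset, transect_distance_matrix
from .stats import amova, ld_r2, nj_tree, pairwise_fst, pca_kmeans_bic, wc_fst


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and seeds of one pipeline run."""

    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "qc", "stats", "outliers", "clines", "dispersal", "report"])
    # simulate (or external inputs)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    input_vcf: str | None = None
    input_popmap: str | None = None
    input_positions: str | None = None
    # qc
    qc: QCThresholds = field(default_factory=QCThresholds)
    # stats
    run_amova: bool = True
    amova_permutations: int = 99
    run_pca: bool = True
    pca_max_k: int = 6
    run_nj: bool = True
    nj_bootstrap: int = 100
    group_split_km: float | None = None  # transect position splitting the two groups
    # outliers
    null_model: NullConfig = field(default_factory=lambda: NullConfig(n_sims=20_000))
    outlier_alpha: float = 0.05
    # clines
    cline_iterations: int = 100_000
    cline_burn_in: int = 10_000
    neutral_subset: int = 500
    lnl_cutoff: float = -10.0
    cutoff_mode: str = "saturated"
    # dispersal
    density_per_km: float = 1000.0
    recomb_rate: float = 0.5
    ld_mode: str = "sqrt"
    # stratified runs: name -> list of population codes ('all' added implicitly)
    population_subsets: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)

        def norm(x):
            if isinstance(x, tuple):
                return [norm(v) for v in x]
            if isinstance(x, list):
                return [norm(v) for v in x]
            if isinstance(x, dict):
                return {k: norm(v) for k, v in x.items()}
            return x
        return norm(d)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            sim = dict(d["simulation"])
            for tup_key in ("clinal_center_range_km", "clinal_width_range_km", "ancestral_law"):
                if tup_key in sim and sim[tup_key] is not None:
                    sim[tup_key] = tuple(sim[tup_key])
            if sim.get("ld_pairs"):
                sim["ld_pairs"] = [tuple(p) for p in sim["ld_pairs"]]
            if sim.get("clinal_truths"):
                from .simulate import ClineTruth
                sim["clinal_truths"] = [ClineTruth(**t) for t in sim["clinal_truths"]]
            d["simulation"] = SimulationConfig(**sim)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QCThresholds(**d["qc"])
        if "null_model" in d and isinstance(d["null_model"], dict):
            d["null_model"] = NullConfig(**d["null_model"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _log(msg: str) -> None:
    print(f"[clinepop] {msg}", file=sys.stderr)


def _write_tsv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# clinepop config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kw)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage {stage!r} needs missing upstream artifact {path.name!r}")
    return path


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute the enabled stages in dependency order; returns the run dir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config
    cfg.to_yaml(out / "config.yaml")
    (out / "MANIFEST.json").write_text(json.dumps(
        {"config_hash": cfg.config_hash(), "seed": cfg.seed,
         "stages": cfg.stages}, indent=2) + "\n")

    if "simulate" in cfg.stages:
        _stage_simulate(cfg, out)
    elif cfg.input_vcf:
        _stage_import(cfg, out)
    if "qc" in cfg.stages:
        _stage_qc(cfg, out)
    if "stats" in cfg.stages:
        _stage_stats(cfg, out)
    if "outliers" in cfg.stages:
        _stage_outliers(cfg, out)
    if "clines" in cfg.stages:
        _stage_clines(cfg, out)
    if "dispersal" in cfg.stages:
        _stage_dispersal(cfg, out)
    if "report" in cfg.stages:
        _stage_report(cfg, out)
    return out


def _load_genotypes(out: Path, stage: str, filtered: bool = True):
    name = "qc_genotypes.vcf" if filtered else "genotypes.vcf"
    path = _require(out / name, stage)
    popmap = read_popmap(_require(out / "popmap.tsv", stage),
                         positions_path=out / "positions.tsv")
    return read_vcf(path, popmap), popmap


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    _log("simulate: generating synthetic dataset")
    sim = dataclasses.replace(cfg.simulation, seed=cfg.stage_seed("simulate"))
    G, popmap, truth = simulate_dataset(sim)
    write_vcf(G, out / "genotypes.vcf")
    write_popmap(popmap, out / "popmap.tsv", positions_path=out / "positions.tsv")
    _write_tsv(truth, out / "truth.tsv", cfg)
    write_distance_matrix(transect_distance_matrix(popmap), out / "distance_km.tsv")


def _stage_import(cfg: PipelineConfig, out: Path) -> None:
    _log("import: copying external inputs into the run directory")
    popmap = read_popmap(cfg.input_popmap, positions_path=cfg.input_positions)
    G = read_vcf(cfg.input_vcf, popmap)
    write_vcf(G, out / "genotypes.vcf")
    write_popmap(popmap, out / "popmap.tsv", positions_path=out / "positions.tsv")
    if popmap.positions_km is not None:
        write_distance_matrix(transect_distance_matrix(popmap), out / "distance_km.tsv")


def _stage_qc(cfg: PipelineConfig, out: Path) -> None:
    _log("qc: applying filter chain")
    popmap = read_popmap(_require(out / "popmap.tsv", "qc"),
                         positions_path=out / "positions.tsv")
    G = read_vcf(_require(out / "genotypes.vcf", "qc"), popmap)
    G2, report = apply_qc_filters(G, popmap, cfg.qc)
    write_vcf(G2, out / "qc_genotypes.vcf")
    _write_tsv(report.to_frame(), out / "filter_report.tsv", cfg)
    _log(f"qc: {G.n_loci} -> {G2.n_loci} loci, {G.n_samples} -> {G2.n_samples} individuals")


def _groups_from_positions(popmap: PopulationMap, split_km: float | None,
                           pops: list[str]) -> dict[str, str]:
    x = popmap.positions_for(pops)
    split = split_km if split_km is not None else float(np.median(x))
    return {p: ("north" if xi < split else "south") for p, xi in zip(pops, x)}


def _stage_stats(cfg: PipelineConfig, out: Path) -> None:
    _log("stats: summary statistics")
    G, popmap = _load_genotypes(out, "stats")
    seed = cfg.stage_seed("stats")
    stats = allele_statistics(G, popmap)
    ft = stats.freqs
    _write_tsv(pd.DataFrame({
        "locus": G.loci, "maf": stats.maf, "he": stats.expected_het,
        "missingness": stats.locus_missingness,
    }), out / "locus_stats.tsv", cfg)
    fst = wc_fst(G, popmap)
    _write_tsv(pd.DataFrame({"locus": fst.loci, "theta": fst.theta}),
               out / "locus_fst.tsv", cfg)
    pw = pairwise_fst(G, popmap)
    _write_tsv(pw, out / "pairwise_fst_all.tsv", cfg, index=True)
    summary = {"multilocus_fst": fst.multilocus,
               "mean_locus_fst": float(np.nanmean(fst.theta)),
               "mean_maf": float(np.nanmean(stats.maf)),
               "mean_he": float(np.nanmean(stats.expected_het))}

    pops = [p for p in popmap.pops if p in set(G.populations)]
    if cfg.run_amova and len(pops) >= 3:
        grouping = _groups_from_positions(popmap, cfg.group_split_km, pops)
        if len(set(grouping.values())) >= 2:
            res = amova(G, popmap, grouping, n_perm=cfg.amova_permutations, seed=seed)
            _write_tsv(res.table, out / "amova.tsv", cfg)
    if cfg.run_pca:
        pca = pca_kmeans_bic(G, max_k=min(cfg.pca_max_k, G.n_samples - 1), seed=seed)
        _write_tsv(pd.DataFrame({
            "k": list(pca.bic), "bic": list(pca.bic.values()),
        }), out / "pca_bic.tsv", cfg)
        summary["pca_selected_k"] = pca.selected_k
        summary["pc1_variance_fraction"] = float(pca.explained_variance_ratio[0])
    if cfg.run_nj and len(pops) >= 3:
        from .stats import chord_distance_matrix
        dc = chord_distance_matrix(ft)
        tree = nj_tree(dc, bootstrap=(G, popmap, cfg.nj_bootstrap, seed))
        (out / "nj_tree.nwk").write_text(tree.newick + "\n")
        if tree.supports:
            _write_tsv(pd.DataFrame([
                {"bipartition": ",".join(sorted(s)), "support_pct": v}
                for s, v in tree.supports.items()
            ]), out / "nj_supports.tsv", cfg)
    _write_tsv(pd.DataFrame([summary]), out / "stats_summary.tsv", cfg)


def _stage_outliers(cfg: PipelineConfig, out: Path) -> None:
    _log("outliers: island-model scan")
    G, popmap = _load_genotypes(out, "outliers")
    scan = OutlierScan(G, popmap, cfg.null_model).fit(
        alpha=cfg.outlier_alpha, seed=cfg.stage_seed("outliers"))
    _write_tsv(scan.table, out / "outliers.tsv", cfg)
    _log(scan.summary())
    # per-class pairwise F_ST and LD summaries
    rows = []
    for label, loci in (("outlier", scan.outlier_loci), ("neutral", scan.neutral_loci)):
        if len(loci) >= 2:
            pw = pairwise_fst(G, popmap, loci=loci)
            _write_tsv(pw, out / f"pairwise_fst_{label}.tsv", cfg, index=True)
            sub = loci if len(loci) <= 400 else list(
                np.array(loci)[np.random.default_rng(
                    cfg.stage_seed("ld")).choice(len(loci), 400, replace=False)])
            ld = ld_r2(G, loci=sub)
            rows.append({"class": label, "n_loci": len(loci),
                         "mean_r2": ld.mean_r2, "n_pairs": len(ld.pairs),
                         "n_undefined": ld.n_undefined})
    _write_tsv(pd.DataFrame(rows), out / "ld_summary.tsv", cfg)


def _stage_clines(cfg: PipelineConfig, out: Path) -> None:
    _log("clines: MCMC cline fitting and model selection")
    G, popmap = _load_genotypes(out, "clines")
    otab = _read_tsv(_require(out / "outliers.tsv", "clines"))
    stats = allele_statistics(G, popmap)
    ft = stats.freqs
    pops = ft.pops
    x = popmap.positions_for(pops)
    seed = cfg.stage_seed("clines")
    rng = np.random.default_rng(seed)

    outlier_loci = list(otab.loc[otab["label"] == "outlier", "locus"])
    neutral_loci = list(otab.loc[otab["label"] == "neutral", "locus"])
    k = min(cfg.neutral_subset, len(neutral_loci))
    neutral_sub = [neutral_loci[i] for i in
                   sorted(rng.choice(len(neutral_loci), size=k, replace=False))]

    rows = []
    for cls_label, loci in (("outlier", outlier_loci), ("neutral", neutral_sub)):
        for locus in loci:
            j = ft.loci.index(locus)
            try:
                sel, _ = cl.fit_locus(
                    ft.p[:, j], ft.n[:, j], x, locus=locus,
                    iterations=cfg.cline_iterations, burn_in=cfg.cline_burn_in,
                    seed=seed + j, lnl_cutoff=cfg.lnl_cutoff,
                    cutoff_mode=cfg.cutoff_mode)
            except ValueError:
                continue
            rows.append({
                "locus": locus, "class": cls_label, "best_model": sel.best_model,
                "loglik": sel.loglik, "aicc": sel.aicc,
                "significant": sel.significant,
                "width_km": sel.width_km if sel.width_km is not None else np.nan,
                "center_km": sel.center_km if sel.center_km is not None else np.nan,
            })
    _write_tsv(pd.DataFrame(rows), out / "clines.tsv", cfg)


def _stage_dispersal(cfg: PipelineConfig, out: Path) -> None:
    _log("dispersal: IBD and cline x LD estimators")
    seed = cfg.stage_seed("dispersal")
    dist = pd.read_csv(_require(out / "distance_km.tsv", "dispersal"),
                       sep="\t", index_col=0)
    ctab = _read_tsv(_require(out / "clines.tsv", "dispersal"))
    ld = _read_tsv(_require(out / "ld_summary.tsv", "dispersal"))
    mean_dist = float(dist.to_numpy()[np.triu_indices(len(dist), k=1)].mean())

    ibd_rows = []
    classes = {"all": out / "pairwise_fst_all.tsv",
               "outlier": out / "pairwise_fst_outlier.tsv",
               "neutral": out / "pairwise_fst_neutral.tsv"}
    subsets = {"all": list(dist.index), **cfg.population_subsets}
    for cls_label, path in classes.items():
        if not path.exists():
            continue
        fst = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        for sub_name, pops in subsets.items():
            pops = [p for p in pops if p in fst.index]
            if len(pops) < 4:
                continue
            try:
                res = dsp.ibd_regression(fst.loc[pops, pops], dist.loc[pops, pops],
                                         n_perm=999, seed=seed,
                                         locus_class=cls_label,
                                         distance_label="transect")
            except ValueError:
                continue
            row = {"class": cls_label, "subset": sub_name, "slope_per_km": res.slope,
                   "intercept": res.intercept, "r_squared": res.r_squared,
                   "mantel_r": res.mantel.r, "mantel_p": res.mantel.p,
                   "n_pairs": res.n_pairs}
            if res.slope > 0:
                rss = dsp.rousset_sigma(res.slope, cfg.density_per_km)
                row["rousset_sigma_km"] = rss.mean
            else:
                row["rousset_sigma_km"] = np.nan
            ibd_rows.append(row)
    _write_tsv(pd.DataFrame(ibd_rows), out / "ibd.tsv", cfg)

    est = {}
    disp_rows = []
    for cls_label in ("outlier", "neutral"):
        widths = ctab.loc[(ctab["class"] == cls_label) & ctab["significant"],
                          "width_km"].dropna().to_numpy()
        r2_row = ld.loc[ld["class"] == cls_label, "mean_r2"]
        if widths.size == 0 or r2_row.empty or not np.isfinite(r2_row.iloc[0]):
            continue
        e = dsp.cline_ld_sigma(widths, float(np.clip(r2_row.iloc[0], 0, 1)),
                               recomb=cfg.recomb_rate, ld_mode=cfg.ld_mode)
        est[cls_label] = e
        disp_rows.append({"class": cls_label, "n_clines": widths.size,
                          "mean_width_km": float(widths.mean()),
                          "sd_width_km": float(widths.std(ddof=1)) if widths.size > 1 else 0.0,
                          "sigma_mean_km": e.mean, "sigma_sd_km": e.sd})
    _write_tsv(pd.DataFrame(disp_rows), out / "dispersal.tsv", cfg)
    if "outlier" in est and "neutral" in est and \
            est["outlier"].sigmas.size >= 2 and est["neutral"].sigmas.size >= 2:
        comp = dsp.compare_dispersal(est["outlier"], est["neutral"],
                                     labels=("outlier", "neutral"),
                                     mean_pairwise_distance_km=mean_dist)
        _write_tsv(comp.table, out / "dispersal_comparison.tsv", cfg)


def _stage_report(cfg: PipelineConfig, out: Path) -> None:
    _log("report: run summary")
    lines = [f"clinepop run summary (config {cfg.config_hash()}, seed {cfg.seed})", ""]
    fr = out / "filter_report.tsv"
    if fr.exists():
        rep = _read_tsv(fr)
        first, last = rep.iloc[0], rep.iloc[-1]
        lines.append(f"QC: {first['loci_before']} -> {last['loci_after']} loci, "
                     f"{first['samples_before']} -> {last['samples_after']} individuals")
        for _, r in rep.iterrows():
            lines.append(f"  {r['stage']}: -{r['n_loci_removed']} loci, "
                         f"-{r['n_samples_removed']} individuals")
    ot = out / "outliers.tsv"
    if ot.exists():
        tab = _read_tsv(ot)
        k, n = int((tab["label"] == "outlier").sum()), len(tab)
        lines.append(f"Outliers: {k} of {n} loci ({100.0 * k / max(n, 1):.1f}%) "
                     f"at q <= {cfg.outlier_alpha}")
    ct = out / "clines.tsv"
    if ct.exists():
        tab = _read_tsv(ct)
        for cls_label, sub in tab.groupby("class"):
            ns = int(sub["significant"].sum())
            lines.append(f"Clines ({cls_label}): {ns} of {len(sub)} significant "
                         f"({100.0 * ns / max(len(sub), 1):.1f}%)")
            w = sub.loc[sub["significant"], "width_km"].dropna()
            if len(w):
                lines.append(f"  width {w.mean():.1f} ± {w.std(ddof=1) if len(w) > 1 else 0:.1f} km")
    dt = out / "dispersal.tsv"
    if dt.exists():
        tab = _read_tsv(dt)
        for _, r in tab.iterrows():
            lines.append(f"Dispersal ({r['class']}): sigma = {r['sigma_mean_km']:.1f} "
                         f"± {r['sigma_sd_km']:.1f} km/generation")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
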