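"""End-to-end orchestration: simulate -> phantom -> QC -> GWAS -> deviation
maps -> rankings -> LD -> clustering -> diagnostics, from a single config.

Every stage writes its outputs under the run directory and registers them,
with SHA-256 hashes, in ``manifest.json``; the manifest is rewritten after
each stage so an interrupted run keeps completed stages.  Re-running with
``resume=True`` reuses a completed stage only when every recorded hash still
matches (a corrupted intermediate refuses to resume).  All randomness is
derived from the single config seed, so two complete runs from the same
config produce identical result tables; figure files are registered as
volatile and excluded from the reproducibility contract.

Array intermediates are stored as raw ``.npy`` (deterministic bytes);
summary tables as TSV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import AssociationTensor, coverage as coverage_table, qc_filter, run_gwas
from .diagnostics_viz import (
    ari_heatmap,
    karyotype_plot,
    ld_heatmap,
    manhattan_plot,
    site_variance,
    site_variance_hist,
)
from .empirical_deviation import empirical_p, standardize_betas
from .gene_ranking import gene_tally, map_all_snps, rank_snps
from .io_formats import read_covariates, write_covariates
from .ld import ld_matrix
from .map_clustering import UMAPParams, cluster_maps, select_snps, stability
from .surface_phenotypes import extract_phenotypes
from .synthetic_data import (
    PhantomConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_phantom,
)
from .types import GenotypeMatrix


@dataclass
class PipelineConfig:
    """All named constants of the analysis with their default values:
    0.99 quasi-monomorphic fraction, 1% coverage selection, top 1% /
    top 0.1% rankings, 50 stability runs, 15 UMAP neighbors, 0.1 min_dist,
    alpha = 0.05."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    phenotypes: tuple = ("CT", "GWC")
    target_wm_mean: float = 110.0
    alpha: float = 0.05
    bh_scope: str = "global"
    mono_frac: float = 0.99
    min_n: int | None = None
    min_coverage: float = 0.01
    top_fraction: float = 0.01
    karyotype_fraction: float = 0.001
    n_highest: int = 10
    umap: UMAPParams = field(default_factory=UMAPParams)
    n_stability_runs: int = 50
    radius_percentile: float = 10.0
    radius: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimulationConfig(**self.sim)
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        if isinstance(self.umap, dict):
            self.umap = UMAPParams(**self.umap)
        if isinstance(self.phenotypes, list):
            self.phenotypes = tuple(self.phenotypes)
        # the config seed drives every stage
        self.sim.seed = self.seed
        self.phantom.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["phenotypes"] = list(self.phenotypes)
        return data


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


class Manifest:
    """Incrementally written record of config, seeds and per-stage hashes."""

    def __init__(self, outdir: Path, config: PipelineConfig):
        self.outdir = outdir
        self.data = {
            "package": "cortmapgen",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "stages": {},
        }

    @property
    def path(self) -> Path:
        return self.outdir / "manifest.json"

    def load_existing(self) -> dict | None:
        if self.path.exists():
            with open(self.path) as fh:
                return json.load(fh)
        return None

    def record_stage(self, name: str, outputs: list, volatile: list = (),
                     started: float = 0.0) -> None:
        self.data["stages"][name] = {
            "outputs": {str(Path(p).relative_to(self.outdir)): _sha256(Path(p))
                        for p in outputs},
            "volatile": [str(Path(p).relative_to(self.outdir)) for p in volatile],
            "duration_s": round(time.time() - started, 3),
        }
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)

    def stage_reusable(self, name: str, previous: dict | None) -> bool:
        """A completed stage can be reused iff every recorded hash matches."""
        if previous is None or name not in previous.get("stages", {}):
            return False
        rec = previous["stages"][name]
        for rel, digest in rec["outputs"].items():
            path = self.outdir / rel
            if not path.exists():
                return False
            if _sha256(path) != digest:
                raise PipelineError(
                    f"stage {name!r}: intermediate {rel} does not match its "
                    "recorded hash; refusing to resume from a corrupt run"
                )
        self.data["stages"][name] = rec
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return True


def _save_tensor(tensor: AssociationTensor, stem: Path) -> list:
    paths = []
    for attr in ("beta", "se", "t_stat", "p", "q", "significant", "df", "n_used"):
        path = Path(f"{stem}_{attr}.npy")
        np.save(path, getattr(tensor, attr))
        paths.append(path)
    ids_path = Path(f"{stem}_snp_ids.txt")
    ids_path.write_text("\n".join(str(s) for s in tensor.snp_ids) + "\n")
    paths.append(ids_path)
    return paths


def _load_tensor(stem: Path, alpha: float, bh_scope: str, phenotype: str) -> AssociationTensor:
    arrays = {attr: np.load(f"{stem}_{attr}.npy")
              for attr in ("beta", "se", "t_stat", "p", "q", "significant", "df", "n_used")}
    snp_ids = np.array(Path(f"{stem}_snp_ids.txt").read_text().split())
    return AssociationTensor(snp_ids=snp_ids, alpha=alpha, bh_scope=bh_scope,
                             phenotype=phenotype, **arrays)


def _synthetic_annotation(snp_meta: pd.DataFrame, width: int = 1500,
                          spacing: int = 4) -> pd.DataFrame:
    """Gene intervals tiled over every ``spacing``-th SNP position so the
    assignment step exercises both overlap and nearest-gene paths."""
    rows = []
    k = 0
    for chrom, group in snp_meta.groupby("chrom", sort=True):
        pos = np.sort(group["pos"].unique())
        for p in pos[::spacing]:
            rows.append({"gene_name": f"gene{k:05d}", "chrom": str(chrom),
                         "start": max(int(p) - width // 2, 0),
                         "end": int(p) + width // 2 + 1})
            k += 1
    from .types import validate_gene_annotation

    return validate_gene_annotation(pd.DataFrame(rows))


def run_all(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute every stage in dependency order; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir, config)
    previous = manifest.load_existing() if resume else None

    # ---- stage: simulate ------------------------------------------------
    t0 = time.time()
    sim_files = {
        "calls": outdir / "genotype_calls.npy",
        "meta": outdir / "genotype_meta.tsv",
        "covars": outdir / "covariates.tsv",
    }
    pheno_files = {name: outdir / f"phenotype_{name}.npy" for name in config.phenotypes}
    truth_files = {name: outdir / f"truth_{name}.json" for name in config.phenotypes}
    outputs = list(sim_files.values()) + list(pheno_files.values()) + list(truth_files.values())
    if manifest.stage_reusable("simulate", previous):
        calls = np.load(sim_files["calls"])
        meta = pd.read_csv(sim_files["meta"], sep="\t", dtype={"chrom": str})
        genotypes = GenotypeMatrix(calls=calls, snp_meta=meta)
        covariates = read_covariates(sim_files["covars"])
        phenotypes = {name: np.load(path) for name, path in pheno_files.items()}
        truth = {name: json.loads(truth_files[name].read_text())
                 for name in config.phenotypes}
    else:
        cohort = simulate_cohort(config.sim, phenotype_names=config.phenotypes)
        genotypes, covariates = cohort.genotypes, cohort.covariates
        phenotypes = cohort.phenotypes
        np.save(sim_files["calls"], genotypes.calls)
        genotypes.snp_meta.to_csv(sim_files["meta"], sep="\t", index=False)
        write_covariates(covariates, sim_files["covars"])
        truth = {}
        for name in config.phenotypes:
            np.save(pheno_files[name], phenotypes[name])
            ptruth = cohort.truth["phenotypes"][name]
            truth[name] = {
                "causal_ids": [str(s) for s in ptruth["causal_ids"]],
                "archetype_of": ptruth["archetype_of"].tolist(),
                "effect_sizes": ptruth["effect_sizes"].tolist(),
            }
            truth_files[name].write_text(json.dumps(truth[name], indent=1))
        manifest.record_stage("simulate", outputs, started=t0)

    # ---- stage: phantom geometry ---------------------------------------
    t0 = time.time()
    phantom_out = outdir / "phantom_recovery.tsv"
    if not manifest.stage_reusable("phantom", previous):
        vol, wm_mesh, pial_mesh, ph_truth = simulate_phantom(
            config.phantom, target_wm_mean=config.target_wm_mean
        )
        extracted = extract_phenotypes(vol, wm_mesh, pial_mesh,
                                       target_wm_mean=config.target_wm_mean)
        pd.DataFrame(
            {
                "vertex": np.arange(len(extracted["ct"])),
                "ct_mm": extracted["ct"],
                "ct_truth_mm": ph_truth["ct_mm"],
                "gwc": extracted["gwc"],
                "gwc_truth": ph_truth["gwc"],
            }
        ).to_csv(phantom_out, sep="\t", index=False, float_format="%.8g")
        manifest.record_stage("phantom", [phantom_out], started=t0)

    # ---- stage: QC -------------------------------------------------------
    t0 = time.time()
    qc_out = outdir / "qc_report.json"
    filtered, report = qc_filter(genotypes, min_n=config.min_n,
                                 mono_frac=config.mono_frac)
    qc_out.write_text(json.dumps(report.to_dict(), indent=1))
    manifest.record_stage("qc", [qc_out], started=t0)

    # ---- per-phenotype analysis -----------------------------------------
    for name in config.phenotypes:
        pheno = phenotypes[name]
        stem = outdir / f"assoc_{name}"

        t0 = time.time()
        if manifest.stage_reusable(f"gwas_{name}", previous):
            tensor = _load_tensor(stem, config.alpha, config.bh_scope, name)
        else:
            tensor = run_gwas(filtered, pheno, covariates, alpha=config.alpha,
                              bh_scope=config.bh_scope, phenotype=name)
            paths = _save_tensor(tensor, stem)
            cov_path = outdir / f"coverage_{name}.tsv"
            coverage_table(tensor).to_csv(cov_path, sep="\t", index=False,
                                          float_format="%.8g")
            manifest.record_stage(f"gwas_{name}", paths + [cov_path], started=t0)

        t0 = time.time()
        zmap = standardize_betas(tensor, mode="include-self")
        zmap = empirical_p(zmap, alpha=config.alpha)
        z_path = outdir / f"zmap_{name}.npy"
        np.save(z_path, zmap.z)
        manifest.record_stage(f"zmap_{name}", [z_path], started=t0)

        # rankings, genes, LD, clustering, diagnostics
        t0 = time.time()
        stage_outputs = []
        volatile = []

        rank_peak = rank_snps(tensor, zmap, scheme="peak_q",
                              top_fraction=config.top_fraction,
                              n_highest=config.n_highest)
        rank_cov = rank_snps(tensor, zmap, scheme="coverage",
                             top_fraction=config.top_fraction,
                             n_highest=config.n_highest)
        for scheme, rep in (("peak_q", rank_peak), ("coverage", rank_cov)):
            path = outdir / f"ranking_{name}_{scheme}.tsv"
            rep.order.to_csv(path, sep="\t", float_format="%.8g")
            stage_outputs.append(path)

        annotation = _synthetic_annotation(filtered.snp_meta)
        assignments = map_all_snps(
            filtered.snp_meta[filtered.snp_meta["id"].isin(rank_peak.top_ids)],
            annotation,
        )
        tally = gene_tally(rank_peak.top_ids, assignments)
        tally_path = outdir / f"gene_tally_{name}.tsv"
        tally.to_csv(tally_path, sep="\t", index=False)
        stage_outputs.append(tally_path)

        ld_res = ld_matrix(filtered, rank_peak.highest_ranked_ids)
        ld_path = outdir / f"ld_{name}.tsv"
        ld_res.to_frame().to_csv(ld_path, sep="\t", index=False, float_format="%.8g")
        stage_outputs.append(ld_path)
        fig = ld_heatmap(ld_res.dprime, ld_res.r_squared, ld_res.snp_ids)
        ld_png = outdir / f"ld_{name}.png"
        fig.savefig(ld_png, dpi=120)
        volatile.append(ld_png)

        selected_ids, features = select_snps(tensor, min_coverage=config.min_coverage)
        cluster_report = stability(
            features, config.umap, n_runs=config.n_stability_runs,
            seed0=config.seed, radius=config.radius,
            radius_percentile=config.radius_percentile,
        )
        cluster_report.snp_ids = selected_ids
        labels_path = outdir / f"cluster_labels_{name}.tsv"
        pd.DataFrame({"snp": selected_ids, "cluster": cluster_report.labels}).to_csv(
            labels_path, sep="\t", index=False
        )
        ari_path = outdir / f"ari_{name}.tsv"
        np.savetxt(ari_path, cluster_report.ari_matrix, delimiter="\t", fmt="%.6f")
        stage_outputs += [labels_path, ari_path]
        maps = cluster_maps(cluster_report.labels, selected_ids, zmap, tensor)
        maps_path = outdir / f"cluster_maps_{name}.tsv"
        pd.DataFrame(maps).to_csv(maps_path, sep="\t", index=False, float_format="%.8g")
        stage_outputs.append(maps_path)
        fig = ari_heatmap(cluster_report.ari_matrix, phenotype=name)
        ari_png = outdir / f"ari_{name}.png"
        fig.savefig(ari_png, dpi=120)
        volatile.append(ari_png)

        sv = site_variance(pheno, covariates["site_id"].to_numpy())
        sv_path = outdir / f"site_variance_{name}.tsv"
        pd.DataFrame({"location": np.arange(len(sv.r2_pct)), "r2_pct": sv.r2_pct}).to_csv(
            sv_path, sep="\t", index=False, float_format="%.8g"
        )
        stage_outputs.append(sv_path)
        fig = site_variance_hist(sv, phenotype=name)
        sv_png = outdir / f"site_variance_{name}.png"
        fig.savefig(sv_png, dpi=120)
        volatile.append(sv_png)

        fig = manhattan_plot(tensor, filtered.snp_meta)
        man_png = outdir / f"manhattan_{name}.png"
        fig.savefig(man_png, dpi=120)
        volatile.append(man_png)

        n_karyo = max(1, int(np.ceil(config.karyotype_fraction * tensor.n_snps)))
        karyo_ids = rank_peak.order["snp"].iloc[:n_karyo]
        meta_idx = filtered.snp_meta.set_index("id")
        karyo = pd.DataFrame(
            {
                "snp": karyo_ids,
                "chrom": meta_idx.loc[karyo_ids, "chrom"].to_numpy(),
                "pos": meta_idx.loc[karyo_ids, "pos"].to_numpy(),
                "peak_q": rank_peak.order.set_index("snp").loc[karyo_ids, "peak_q"].to_numpy(),
            }
        )
        fig = karyotype_plot(karyo)
        karyo_png = outdir / f"karyotype_{name}.png"
        fig.savefig(karyo_png, dpi=120)
        volatile.append(karyo_png)

        import matplotlib.pyplot as plt

        plt.close("all")
        manifest.record_stage(f"downstream_{name}", stage_outputs,
                              volatile=volatile, started=t0)

    return manifest.data


def compare_manifests(a: dict, b: dict) -> list:
    """Relative paths whose hashes differ between two runs (volatile files
    excluded).  Empty list = bit-identical result tables."""
    diffs = []
    for stage, rec in a.get("stages", {}).items():
        other = b.get("stages", {}).get(stage, {})
        for rel, digest in rec.get("outputs", {}).items():
            if other.get("outputs", {}).get(rel) != digest:
                diffs.append(f"{stage}:{rel}")
    return diffs
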