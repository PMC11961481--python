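"""Scanner-site variance diagnostic and the standard plot families.

The site diagnostic is a per-location one-way ANOVA of the phenotype on
imaging site: the fraction of variance explained is R^2 = SS_between /
SS_total, reported in percent.  Site is excluded from the association model
itself, so this diagnostic is how site effects are monitored.

Plot functions are pure (same inputs -> same rendered buffer) and return
matplotlib Figure objects; callers decide where to save them.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import matplotlib

matplotlib.use("Agg")  # headless; must precede pyplot
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .association import AssociationTensor
from .types import SurfaceMesh, ValidationError


# ---------------------------------------------------------------------------
# site variance
# ---------------------------------------------------------------------------

@dataclass
class SiteVarianceReport:
    r2_pct: np.ndarray           # per location, percent
    mean_pct: float
    min_pct: float
    max_pct: float
    sd_pct: float

    def summary(self) -> dict:
        return {
            "mean_pct": self.mean_pct,
            "min_pct": self.min_pct,
            "max_pct": self.max_pct,
            "sd_pct": self.sd_pct,
        }


def site_variance(pheno: np.ndarray, sites: np.ndarray) -> SiteVarianceReport:
    """One-way ANOVA variance fraction per location, vectorized over sites."""
    pheno = np.asarray(pheno, dtype=np.float64)
    sites = np.asarray(sites)
    uniq, inverse = np.unique(sites, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("need at least 2 sites for a variance diagnostic")
    counts = np.bincount(inverse)
    if counts.min() < 2:
        raise ValidationError("every site needs at least 2 participants")
    grand = pheno.mean(axis=0)
    ss_total = ((pheno - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for k in range(len(uniq)):
        grp = pheno[inverse == k]
        ss_between += len(grp) * (grp.mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_total > 0, ss_between / ss_total, 0.0)
    r2_pct = 100.0 * r2
    return SiteVarianceReport(
        r2_pct=r2_pct,
        mean_pct=float(r2_pct.mean()),
        min_pct=float(r2_pct.min()),
        max_pct=float(r2_pct.max()),
        sd_pct=float(r2_pct.std(ddof=1)) if r2_pct.size > 1 else 0.0,
    )


def site_variance_hist(report: SiteVarianceReport, phenotype: str = "") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(report.r2_pct, bins=40, color="steelblue", edgecolor="white")
    ax.set_xlabel("variance explained by site (%)")
    ax.set_ylabel("number of locations")
    title = "Site variance"
    if phenotype:
        title += f" ({phenotype})"
    ax.set_title(f"{title}: mean {report.mean_pct:.2f}%")
    fig.tight_layout()
    return fig


# ---------------------------------------------------------------------------
# chromosome lengths
# ---------------------------------------------------------------------------

def chromosome_lengths() -> pd.DataFrame:
    """Bundled GRCh37 chromosome lengths (chrom, length)."""
    with resources.files("cortmapgen.data").joinpath("grch37_chrom_lengths.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def manhattan_plot(tensor: AssociationTensor, snp_meta: pd.DataFrame,
                   use_corrected: bool = True) -> plt.Figure:
    """-log10 of each SNP's peak (corrected by default) p against cumulative
    genomic position, colored by chromosome, with the significance line."""
    if tensor.n_snps == 0:
        raise ValidationError("empty association tensor")
    values = tensor.q if use_corrected else tensor.p
    peak = np.nanmin(values, axis=1)
    neglog = -np.log10(np.maximum(peak, 1e-300))

    lengths = chromosome_lengths().set_index("chrom")["length"]
    meta = snp_meta.set_index("id").loc[list(tensor.snp_ids)]
    chroms = meta["chrom"].astype(str).to_numpy()
    pos = meta["pos"].to_numpy(dtype=np.float64)
    order = sorted(set(chroms), key=lambda c: (not c.isdigit(), int(c) if c.isdigit() else 0, c))
    offsets = {}
    running = 0.0
    for c in order:
        offsets[c] = running
        running += float(lengths.get(c, pos[chroms == c].max() + 1))
    x = np.array([offsets[c] for c in chroms]) + pos

    fig, ax = plt.subplots(figsize=(9, 4))
    for i, c in enumerate(order):
        sel = chroms == c
        ax.scatter(x[sel], neglog[sel], s=6,
                   color=["#30507a", "#7aa0c8"][i % 2], rasterized=True)
    ax.axhline(-np.log10(tensor.alpha), color="firebrick", linewidth=1, linestyle="--")
    ax.set_xlabel("cumulative genomic position (bp)")
    label = "q" if use_corrected else "p"
    ax.set_ylabel(f"-log10 peak {label}")
    ax.set_xticks([offsets[c] + float(lengths.get(c, 1)) / 2 for c in order])
    ax.set_xticklabels(order, fontsize=7)
    fig.tight_layout()
    return fig


def karyotype_plot(top_snps: pd.DataFrame, genes: pd.DataFrame | None = None,
                   lengths: pd.DataFrame | None = None) -> plt.Figure:
    """One band per SNP positioned along its chromosome; band color encodes
    the corrected p of its most significant coefficient.

    ``top_snps`` columns: snp, chrom, pos, peak_q.  ``genes`` (optional)
    columns: gene_name, chrom, start, end for midpoint labels.
    """
    if lengths is None:
        lengths = chromosome_lengths()
    lens = lengths.set_index("chrom")["length"]
    for _, row in top_snps.iterrows():
        c = str(row["chrom"])
        if c in lens.index and row["pos"] >= lens[c]:
            raise ValidationError(
                f"SNP {row['snp']} at {row['pos']} beyond chromosome {c} length {lens[c]}"
            )
    order = [c for c in lens.index if c in set(top_snps["chrom"].astype(str))]
    cmap = plt.get_cmap("viridis")
    neglog = -np.log10(np.maximum(top_snps["peak_q"].to_numpy(dtype=float), 1e-300))
    vmax = max(neglog.max(), 1.0)

    fig, ax = plt.subplots(figsize=(7, 0.5 * max(len(order), 4) + 1.5))
    for y, c in enumerate(order):
        ax.plot([0, lens[c]], [y, y], color="0.8", linewidth=6, solid_capstyle="round")
        sel = top_snps[top_snps["chrom"].astype(str) == c]
        for _, row in sel.iterrows():
            nl = -np.log10(max(float(row["peak_q"]), 1e-300))
            ax.plot([row["pos"], row["pos"]], [y - 0.18, y + 0.18],
                    color=cmap(nl / vmax), linewidth=1.5)
        if genes is not None:
            for _, grow in genes[genes["chrom"].astype(str) == c].iterrows():
                mid = (grow["start"] + grow["end"]) / 2
                ax.annotate(grow["gene_name"], (mid, y + 0.25), fontsize=6,
                            ha="center", rotation=45)
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([f"chr{c}" for c in order], fontsize=8)
    ax.set_xlabel("position (bp)")
    ax.invert_yaxis()
    sm = plt.cm.ScalarMappable(cmap=cmap, norm=plt.Normalize(0, vmax))
    fig.colorbar(sm, ax=ax, label="-log10 q")
    fig.tight_layout()
    return fig


def surface_map_plot(values: np.ndarray, mesh: SurfaceMesh, title: str = "") -> plt.Figure:
    """Diverging (red = positive, blue = negative) vertex map, symmetric
    color limits at the maximum |value|, rendered as a 2D vertex scatter."""
    values = np.asarray(values, dtype=np.float64)
    if len(values) != len(mesh.vertices):
        raise ValidationError("value count != vertex count")
    lim = np.nanmax(np.abs(values)) if np.isfinite(values).any() else 1.0
    lim = lim if lim > 0 else 1.0
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    views = (("lateral", 0, 2), ("dorsal", 0, 1))
    for ax, (name, i, j) in zip(axes, views):
        sc = ax.scatter(mesh.vertices[:, i], mesh.vertices[:, j], c=values,
                        cmap="RdBu_r", vmin=-lim, vmax=lim, s=12)
        ax.set_aspect("equal")
        ax.set_title(name, fontsize=9)
        ax.axis("off")
    fig.colorbar(sc, ax=axes, label="z", shrink=0.8)
    if title:
        fig.suptitle(title)
    return fig


def ari_heatmap(ari_matrix: np.ndarray, phenotype: str = "") -> plt.Figure:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(ari_matrix, vmin=0, vmax=1, cmap="magma")
    ax.set_xlabel("run")
    ax.set_ylabel("run")
    off = ari_matrix[~np.eye(len(ari_matrix), dtype=bool)]
    title = f"ARI across runs (mean {off.mean():.2f})"
    if phenotype:
        title = f"{phenotype}: {title}"
    ax.set_title(title, fontsize=10)
    fig.colorbar(im, ax=ax, label="ARI")
    fig.tight_layout()
    return fig


def ld_heatmap(dprime: np.ndarray, r2: np.ndarray, snp_ids: list) -> plt.Figure:
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.5))
    for ax, mat, name in ((axes[0], r2, "$R^2$"), (axes[1], dprime, "D'")):
        im = ax.imshow(mat, vmin=0, vmax=1, cmap="Reds")
        ax.set_xticks(range(len(snp_ids)))
        ax.set_yticks(range(len(snp_ids)))
        ax.set_xticklabels(snp_ids, rotation=90, fontsize=6)
        ax.set_yticklabels(snp_ids, fontsize=6)
        ax.set_title(name)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    return fig
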