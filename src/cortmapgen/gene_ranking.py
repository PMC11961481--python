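"""SNP-to-gene assignment, SNP rankings and averaged gene maps.

Assignment follows the closest-boundary rule: a SNP inside one or more gene
intervals is assigned to the overlapping gene whose nearer boundary is
closest (ties keep all tied genes); a SNP outside every interval goes to the
gene(s) minimizing the distance to the interval.  Distances are measured in
bp to the stored half-open boundary coordinates and strand is ignored.
An optional user-supplied override table (snp_id -> gene) can stand in for
curated external mappings.

Rankings:

* ``peak_q`` — by each SNP's most significant corrected p-value over
  locations (ascending), ties broken by larger peak |beta|, then SNP id;
* ``coverage`` — by the count of significantly associated locations
  (descending), with the same tie-break chain.

The tie-break chain is a deterministic convention of this package.  "Top"
SNPs are the top 1% (ceil) of the post-QC ranking; "highest-ranked" the top
10; "broadest-reaching" the top 10 by coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from .association import AssociationTensor, coverage as coverage_table
from .empirical_deviation import ZScoreMap, standardize_with_moments
from .types import ValidationError, validate_gene_annotation


@dataclass
class SNPGeneAssignment:
    snp_id: str
    genes: list                  # one or more gene names (ties keep all)
    assignment_type: str         # "overlap" | "nearest" | "unassigned" | "override"
    distance_bp: int             # 0 for overlap


def map_snp_to_gene(pos: int, chrom: str, ann: pd.DataFrame,
                    snp_id: str = "") -> SNPGeneAssignment:
    """Assign one SNP position to gene(s) under the closest-boundary rule."""
    ann = validate_gene_annotation(ann)
    sub = ann[ann["chrom"] == chrom]
    if len(sub) == 0:
        return SNPGeneAssignment(snp_id=snp_id, genes=[], assignment_type="unassigned",
                                 distance_bp=-1)
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    names = sub["gene_name"].to_numpy()
    inside = (start <= pos) & (pos < end)
    if inside.any():
        # among overlapping genes, the one whose nearer boundary is closest
        b_dist = np.minimum(pos - start[inside], end[inside] - pos)
        best = b_dist.min()
        genes = sorted(set(names[inside][b_dist == best]))
        return SNPGeneAssignment(snp_id=snp_id, genes=genes,
                                 assignment_type="overlap", distance_bp=0)
    dist = np.where(pos < start, start - pos, pos - end)
    best = dist.min()
    genes = sorted(set(names[dist == best]))
    return SNPGeneAssignment(snp_id=snp_id, genes=genes, assignment_type="nearest",
                             distance_bp=int(best))


def map_all_snps(snp_meta: pd.DataFrame, ann: pd.DataFrame,
                 override: pd.DataFrame | None = None) -> dict:
    """SNP id -> SNPGeneAssignment for a whole metadata table.

    ``override`` (columns snp_id, gene) wins over interval assignment.
    """
    ann = validate_gene_annotation(ann)
    over: dict[str, list] = {}
    if override is not None:
        for sid, group in override.groupby("snp_id"):
            over[str(sid)] = sorted(set(group["gene"].astype(str)))
    out = {}
    for _, row in snp_meta.iterrows():
        sid = str(row["id"])
        if sid in over:
            out[sid] = SNPGeneAssignment(snp_id=sid, genes=over[sid],
                                         assignment_type="override", distance_bp=0)
        else:
            out[sid] = map_snp_to_gene(int(row["pos"]), str(row["chrom"]), ann, snp_id=sid)
    return out


# ---------------------------------------------------------------------------
# rankings
# ---------------------------------------------------------------------------

@dataclass
class RankingReport:
    scheme: str
    order: pd.DataFrame          # full ranking with sort keys
    top_fraction: float = 0.01
    top_ids: list = field(default_factory=list)        # top 1% (ceil)
    highest_ranked_ids: list = field(default_factory=list)  # top 10


def _sort_frame(tensor: AssociationTensor) -> pd.DataFrame:
    peak_q = np.nanmin(tensor.q, axis=1)
    peak_beta_idx = np.nanargmax(np.abs(np.nan_to_num(tensor.beta)), axis=1)
    rows = np.arange(tensor.n_snps)
    peak_abs_beta = np.abs(tensor.beta[rows, peak_beta_idx])
    peak_beta = tensor.beta[rows, peak_beta_idx]
    cov = coverage_table(tensor)["coverage_pct"].to_numpy()
    return pd.DataFrame(
        {
            "snp": tensor.snp_ids,
            "peak_q": peak_q,
            "peak_abs_beta": peak_abs_beta,
            "peak_beta": peak_beta,
            "coverage_pct": cov,
            "n_significant": tensor.significant.sum(axis=1),
        }
    )


def rank_snps(tensor: AssociationTensor, zmap: ZScoreMap | None = None,
              scheme: str = "peak_q", top_fraction: float = 0.01,
              n_highest: int = 10) -> RankingReport:
    """Rank SNPs by peak corrected significance or by coverage."""
    frame = _sort_frame(tensor)
    if scheme == "peak_q":
        keys = ["peak_q", "peak_abs_beta", "snp"]
        ascending = [True, False, True]
    elif scheme == "coverage":
        keys = ["coverage_pct", "peak_q", "peak_abs_beta", "snp"]
        ascending = [False, True, False, True]
    else:
        raise ValueError(f"unknown ranking scheme {scheme!r}")
    order = frame.sort_values(keys, ascending=ascending, kind="mergesort").reset_index(drop=True)
    order.index.name = "rank"
    n_top = ceil(top_fraction * len(order))
    return RankingReport(
        scheme=scheme,
        order=order,
        top_fraction=top_fraction,
        top_ids=list(order["snp"].iloc[:n_top]),
        highest_ranked_ids=list(order["snp"].iloc[:n_highest]),
    )


def gene_tally(top_snp_ids: list, assignments: dict) -> pd.DataFrame:
    """Per-gene counts of associated top SNPs, ranked.

    A SNP assigned to k genes contributes one count to each.  Descending by
    count, ties broken lexicographically by gene name.
    """
    counts: dict[str, int] = {}
    for sid in top_snp_ids:
        assignment = assignments.get(str(sid))
        if assignment is None:
            continue
        for gene in assignment.genes:
            counts[gene] = counts.get(gene, 0) + 1
    frame = pd.DataFrame(
        {"gene": list(counts.keys()), "n_top_snps": list(counts.values())}
    )
    return frame.sort_values(["n_top_snps", "gene"], ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)


def average_map(zmap: ZScoreMap, snp_set: list, tensor: AssociationTensor) -> np.ndarray:
    """Location-wise mean of the member SNPs' raw betas, re-standardized
    against the ensemble moments (same z-scoring as a single SNP)."""
    snp_set = [str(s) for s in snp_set]
    if not snp_set:
        raise ValidationError("empty SNP set")
    id_to_row = {str(s): i for i, s in enumerate(tensor.snp_ids)}
    try:
        rows = [id_to_row[s] for s in snp_set]
    except KeyError as exc:
        raise ValidationError(f"SNP {exc.args[0]!r} not in tensor") from exc
    mean_beta = tensor.beta[rows].mean(axis=0)
    return standardize_with_moments(mean_beta, zmap)


def gene_average_maps(tally: pd.DataFrame, assignments: dict, top_snp_ids: list,
                      zmap: ZScoreMap, tensor: AssociationTensor,
                      n_genes: int = 10) -> dict:
    """Averaged standardized map for each of the most frequently hit genes."""
    top = set(str(s) for s in top_snp_ids)
    maps = {}
    for gene in tally["gene"].iloc[:n_genes]:
        members = [sid for sid, a in assignments.items()
                   if sid in top and gene in a.genes]
        if members:
            maps[gene] = average_map(zmap, members, tensor)
    return maps
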