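"""Core in-memory containers shared across the pipeline.

Conventions fixed here and relied on everywhere else:

* Genomic coordinates are stored 0-based half-open internally; positions read
  from VCF (1-based) are converted on input and converted back for any printed
  output.
* Genotypes are coded as the number of REFERENCE alleles (0, 1 or 2) carried
  by a participant at a SNP.  This is deliberate and documented prominently:
  most GWAS software counts ALT/effect alleles instead, so betas from this
  package have the opposite sign convention to such tools.
* Missing genotype calls are stored as :data:`MISSING` (-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING: int = -1

#: required covariate columns, in model order (after intercept and genotype)
COVARIATE_COLUMNS = ("age_years", "sex", "pc1", "pc2", "pc3", "pc4", "pc5")


class ValidationError(ValueError):
    """Raised when an input object or file violates a structural invariant."""


class FormatError(ValueError):
    """Raised when a file cannot be parsed in its declared format."""


@dataclass
class SurfaceMesh:
    """Triangle mesh for a cortical boundary (vertices in mm)."""

    vertices: np.ndarray  # (V, 3) float64, mm
    faces: np.ndarray     # (F, 3) int, 0-based vertex indices
    name: str = "wm"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError("faces must be an (F, 3) array of triangles")
        if len(self.vertices) < 4:
            raise ValidationError("a closed surface needs at least 4 vertices")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise ValidationError("face index exceeds vertex count")
        if self.faces.size and self.faces.min() < 0:
            raise ValidationError("negative face index")
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise ValidationError("degenerate face with repeated vertex index")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)


@dataclass
class VolumeImage:
    """3D scalar intensity grid with a voxel-index -> mm affine.

    ``labels`` is an optional integer grid of the same shape with
    0 = background, 1 = gray matter, 2 = white matter.
    """

    intensities: np.ndarray           # (X, Y, Z) float
    affine: np.ndarray                # (4, 4) voxel index -> mm
    labels: np.ndarray | None = None  # (X, Y, Z) int, or None

    LABEL_BG = 0
    LABEL_GM = 1
    LABEL_WM = 2

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int16)
        self.validate()

    def validate(self) -> None:
        if self.intensities.ndim != 3:
            raise ValidationError("intensities must be a 3D grid")
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine is not invertible")
        if self.labels is not None and self.labels.shape != self.intensities.shape:
            raise ValidationError("labels and intensities must share a shape")

    def voxel_size(self) -> np.ndarray:
        """Edge lengths of a voxel in mm along each grid axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class GenotypeMatrix:
    """Participants x SNPs reference-allele counts with per-SNP metadata.

    ``snp_meta`` columns: ``id``, ``chrom``, ``pos`` (0-based), ``ref_allele``,
    ``has_ref_id`` (False when the variant identifier was missing, "."), and
    ``ref_allele_valid`` (False when REF is not a single A/C/G/T base).
    """

    calls: np.ndarray            # (N, M) int8, MISSING = -1
    snp_meta: pd.DataFrame
    participant_ids: list[str] = field(default_factory=list)

    META_COLUMNS = ("id", "chrom", "pos", "ref_allele", "has_ref_id", "ref_allele_valid")

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if not self.participant_ids:
            self.participant_ids = [f"P{i:06d}" for i in range(self.calls.shape[0])]
        self.validate()

    def validate(self) -> None:
        if self.calls.ndim != 2:
            raise ValidationError("calls must be 2D (participants x SNPs)")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("genotype calls must be 0, 1, 2 or missing (-1)")
        for col in self.META_COLUMNS:
            if col not in self.snp_meta.columns:
                raise ValidationError(f"snp_meta missing column {col!r}")
        if len(self.snp_meta) != self.calls.shape[1]:
            raise ValidationError("snp_meta row count != number of SNP columns")
        ids = self.snp_meta["id"]
        real = ids[self.snp_meta["has_ref_id"].astype(bool)]
        if real.duplicated().any():
            raise ValidationError("duplicate SNP ids")
        if (self.snp_meta["pos"].to_numpy() < 0).any():
            raise ValidationError("negative SNP position")
        if len(self.participant_ids) != self.calls.shape[0]:
            raise ValidationError("participant_ids length != row count")

    @property
    def n_participants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_meta["id"].to_numpy() == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not found")
        return int(idx[0])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to SNP columns selected by ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            calls=self.calls[:, keep].copy(),
            snp_meta=self.snp_meta.iloc[keep].reset_index(drop=True),
            participant_ids=list(self.participant_ids),
        )


def validate_covariates(covars: pd.DataFrame, participant_ids: list[str] | None = None) -> pd.DataFrame:
    """Check a covariate table and return it indexed by participant id.

    Required columns: age_years, sex (0/1), pc1..pc5, site_id.  Missing values
    are rejected: the association model assumes complete covariates for every
    analyzed participant.
    """
    required = list(COVARIATE_COLUMNS) + ["site_id"]
    for col in required:
        if col not in covars.columns:
            raise ValidationError(f"covariate table missing column {col!r}")
    if covars[required].isna().any().any():
        raise ValidationError("covariate table contains missing values")
    if not np.isin(covars["sex"].to_numpy(), (0, 1)).all():
        raise ValidationError("sex must be coded 0/1")
    if participant_ids is not None:
        if list(covars.index.astype(str)) != [str(p) for p in participant_ids]:
            raise ValidationError("covariate rows do not match participant ids")
    return covars


def validate_gene_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalize a gene annotation table.

    Columns: gene_name, chrom, start, end with 0-based half-open intervals,
    sorted by (chrom, start).
    """
    for col in ("gene_name", "chrom", "start", "end"):
        if col not in ann.columns:
            raise ValidationError(f"gene annotation missing column {col!r}")
    if (ann["start"] >= ann["end"]).any():
        bad = ann[ann["start"] >= ann["end"]].iloc[0]
        raise ValidationError(
            f"gene {bad['gene_name']!r}: start {bad['start']} >= end {bad['end']}"
        )
    if (ann["start"] < 0).any():
        raise ValidationError("negative interval start")
    if (ann["gene_name"].astype(str).str.len() == 0).any():
        raise ValidationError("empty gene name")
    out = ann.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return out
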