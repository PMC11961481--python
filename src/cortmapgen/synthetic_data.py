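"""Synthetic cohort generator.

Everything downstream of data acquisition is testable against this module:
it produces genotype matrices with known haplotype structure, covariate
tables, phenotype matrices with planted spatial effect maps, and a two-shell
cortical phantom with analytically known thickness and contrast.

The generative model
--------------------

* Genotypes: each SNP's two haplotype alleles are drawn independently
  (Hardy-Weinberg).  Within an LD block, adjacent loci are chained through a
  two-locus haplotype distribution whose coupling is set to reach a target
  D' given the drawn allele frequencies.  Missing calls are injected
  completely at random.  A configurable number of SNPs are made
  quasi-monomorphic or given invalid metadata so the QC rules have real work.
* Effect maps ("archetypes"): smooth unit-norm spatial patterns on the
  location mesh, built from low-order polynomial harmonics of the vertex
  coordinates and orthonormalized, so distinct archetypes are mutually
  orthogonal (pairwise |cosine| = 0 <= the 0.3 bound).
* Phenotypes: baseline + sum over causal SNPs of beta_k * archetype_k(loc) *
  genotype + linear age/sex/PC terms + a per-site offset + Gaussian noise.
  Missing genotypes contribute their per-SNP mean so phenotypes are defined
  for every participant (the analysis side still drops those participants
  per SNP).
* Phantom: two concentric spherical shells rasterized on a 1 mm grid: WM
  interior, GM shell, background outside; thickness truth is the radial
  separation and contrast truth follows from the configured intensities.

Cortical locations are the vertices of an icosphere (default 642), a uniform
mesh-compatible stand-in for a downsampled cortical surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import trimesh

from .types import MISSING, GenotypeMatrix, SurfaceMesh, ValidationError, VolumeImage


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LDBlockSpec:
    """Blocks of consecutive SNPs with a target pairwise D' between neighbours."""

    n_blocks: int = 10
    block_size: int = 5
    target_dprime: float = 0.9


@dataclass
class CovariateEffects:
    """Linear covariate effects on the phenotype (phenotype units)."""

    age_slope: float = -0.01     # per year: slow age-related decline
    sex_offset: float = 0.1
    pc_slopes: tuple = (0.05, 0.05, 0.05, 0.05, 0.05)


@dataclass
class SimulationConfig:
    """Desk-scale cohort defaults: n=2,000 participants, M=5,000 SNPs, L=642.

    ``effect_size_per_archetype`` is the phenotype change per reference
    allele per unit archetype loading.  Unit-norm archetypes on 642
    locations peak near 0.07, so the default 8.0 gives a peak per-allele
    effect of ~0.55 noise SDs.  That value comes from a worst-case power
    calculation: at the lowest default MAF (0.05), genotype SD is
    sqrt(2*0.05*0.95) = 0.31, so the peak-location t-statistic is about
    8 * 0.068 * 0.31 * sqrt(2000) = 7.5 — enough that every planted SNP is
    detectable over >1% of locations at desk scale, mirroring how the real
    study's reported variants sit well above its detection floor at n~43k.
    """

    n_participants: int = 2000
    n_snps: int = 5000
    n_locations: int = 642
    maf_range: tuple = (0.05, 0.5)
    missing_rate: float = 0.02
    n_monomorphic: int = 150
    n_bad_refid: int = 50
    n_bad_allele: int = 50
    ld_block_spec: LDBlockSpec = field(default_factory=LDBlockSpec)
    archetype_count: int = 4
    n_causal_per_archetype: int = 40
    effect_size_per_archetype: float = 8.0
    baseline: float = 2.5
    noise_sd: float = 1.0
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    site_count: int = 3
    site_effect_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.ld_block_spec, dict):
            self.ld_block_spec = LDBlockSpec(**self.ld_block_spec)
        if isinstance(self.covariate_effects, dict):
            self.covariate_effects = CovariateEffects(**self.covariate_effects)
        self.validate()

    def validate(self) -> None:
        if min(self.n_participants, self.n_snps, self.n_locations) <= 0:
            raise ValidationError("all counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValidationError("maf_range must lie in (0, 0.5]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    phenotypes: dict            # name -> (N, L) ndarray
    truth: dict                 # generative ground truth per phenotype + genotypes


# ---------------------------------------------------------------------------
# locations
# ---------------------------------------------------------------------------

def location_mesh(n_locations: int = 642) -> SurfaceMesh:
    """Unit icosphere whose first ``n_locations`` vertices are the analysis
    locations.  Icosphere vertex counts are 12, 42, 162, 642, 2562, ..."""
    subdiv = 0
    while 10 * 4 ** subdiv + 2 < n_locations:
        subdiv += 1
        if subdiv > 7:
            raise ValidationError(f"n_locations={n_locations} too large")
    ico = trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)
    return SurfaceMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces),
                       name="atlas")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _coupled_haplotype_conditionals(p1: float, p2: float, dprime: float):
    """P(ref at locus 2 | allele at locus 1) for positive coupling D = D'*Dmax."""
    q1, q2 = 1 - p1, 1 - p2
    dmax = min(p1 * q2, q1 * p2)  # maximum D for D > 0
    d = dprime * dmax
    p_ab = p1 * p2 + d       # ref-ref haplotype
    p_a_b = q1 * p2 - d      # alt-ref
    if p_ab < -1e-12 or p_a_b < -1e-12:
        return None  # infeasible for these frequencies (cannot happen for d>=0)
    return p_ab / p1, p_a_b / q1


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None):
    """Draw the genotype matrix plus haplotype-level ground truth.

    Returns ``(GenotypeMatrix, truth)`` where truth records, per LD-block
    pair of adjacent SNPs, the exact haplotype frequencies used, and the
    simulated haplotypes themselves (before collapsing to genotypes) so LD
    estimators can be validated against phase-known data.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_participants, cfg.n_snps
    block = cfg.ld_block_spec
    n_block_snps = block.n_blocks * block.block_size
    if n_block_snps + cfg.n_monomorphic + cfg.n_bad_refid + cfg.n_bad_allele > m:
        raise ValidationError("n_snps too small for the requested block/flag counts")

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    ref_freq = 1.0 - mafs  # reference allele is the major allele

    # two haplotypes per participant; fill per SNP
    hap = np.zeros((2, n, m), dtype=np.int8)
    truth_pairs = []
    col = 0
    for b in range(block.n_blocks):
        for k in range(block.block_size):
            p = ref_freq[col]
            if k == 0:
                hap[:, :, col] = rng.random((2, n)) < p
            else:
                cond = _coupled_haplotype_conditionals(ref_freq[col - 1], p, block.target_dprime)
                while cond is None:  # re-draw an infeasible frequency (defensive)
                    mafs[col] = rng.uniform(*cfg.maf_range)
                    ref_freq[col] = 1.0 - mafs[col]
                    p = ref_freq[col]
                    cond = _coupled_haplotype_conditionals(ref_freq[col - 1], p, block.target_dprime)
                p_given_ref, p_given_alt = cond
                prob = np.where(hap[:, :, col - 1] == 1, p_given_ref, p_given_alt)
                hap[:, :, col] = rng.random((2, n)) < prob
                p1, p2 = ref_freq[col - 1], p
                d = block.target_dprime * min(p1 * (1 - p2), (1 - p1) * p2)
                truth_pairs.append(
                    {
                        "snp_i": col - 1,
                        "snp_j": col,
                        "block": b,
                        "p_AB": p1 * p2 + d,
                        "p_Ab": p1 * (1 - p2) - d,
                        "p_aB": (1 - p1) * p2 - d,
                        "p_ab": (1 - p1) * (1 - p2) + d,
                        "dprime": block.target_dprime,
                    }
                )
            col += 1
    # remaining SNPs: independent loci
    rest = np.s_[col:m]
    hap[:, :, rest] = rng.random((2, n, m - col)) < ref_freq[rest]

    calls = (hap[0] + hap[1]).astype(np.int8)

    # quasi-monomorphic SNPs: modal genotype frequency > 0.99
    special = np.arange(col, m)
    rng.shuffle(special)
    mono_idx = special[: cfg.n_monomorphic]
    bad_refid_idx = special[cfg.n_monomorphic : cfg.n_monomorphic + cfg.n_bad_refid]
    bad_allele_idx = special[
        cfg.n_monomorphic + cfg.n_bad_refid :
        cfg.n_monomorphic + cfg.n_bad_refid + cfg.n_bad_allele
    ]
    n_minor = max(1, int(np.floor(0.004 * n)))  # < 1% of participants
    for j in mono_idx:
        calls[:, j] = 2
        minority = rng.choice(n, size=n_minor, replace=False)
        calls[minority, j] = 1

    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        calls[miss] = MISSING

    # metadata: SNPs laid out across 22 chromosomes in order
    chrom = (np.arange(m) % 22 + 1).astype(str)
    pos = 10_000 + (np.arange(m) // 22) * 1_000
    # block members stay adjacent on one chromosome
    chrom[:col] = "1"
    pos = pos.astype(np.int64)
    pos[:col] = 10_000 + np.arange(col) * 1_000
    bases = np.array(list("ACGT"))
    ref_allele = bases[rng.integers(0, 4, size=m)].astype(object)
    has_ref_id = np.ones(m, dtype=bool)
    ref_valid = np.ones(m, dtype=bool)
    has_ref_id[bad_refid_idx] = False
    ref_valid[bad_allele_idx] = False
    ref_allele[bad_allele_idx] = "N"
    ids = np.array([f"snp{j:05d}" for j in range(m)], dtype=object)
    ids[bad_refid_idx] = [f"__noid_{j}" for j in bad_refid_idx]
    meta = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": pos,
            "ref_allele": ref_allele,
            "has_ref_id": has_ref_id,
            "ref_allele_valid": ref_valid,
        }
    )
    g = GenotypeMatrix(calls=calls, snp_meta=meta,
                       participant_ids=[f"P{i:06d}" for i in range(n)])
    truth = {
        "ld_pairs": truth_pairs,
        "haplotypes": hap,
        "maf": mafs,
        "ref_freq": ref_freq,
        "monomorphic": np.sort(mono_idx),
        "bad_refid": np.sort(bad_refid_idx),
        "bad_allele": np.sort(bad_allele_idx),
        "n_block_snps": col,
    }
    return g, truth


# ---------------------------------------------------------------------------
# effect maps
# ---------------------------------------------------------------------------

def simulate_effect_maps(cfg: SimulationConfig,
                         locations: SurfaceMesh | None = None) -> np.ndarray:
    """Unit-norm orthogonal archetype maps, shape (archetype_count, L).

    Archetypes are Gram-Schmidt orthonormalized low-order polynomial
    harmonics of the location coordinates, hence smooth on the mesh and
    mutually orthogonal (pairwise |cos| = 0, within the <= 0.3 bound).
    """
    if cfg.archetype_count < 2:
        raise ValidationError("archetype_count must be >= 2")
    if locations is None:
        locations = location_mesh(cfg.n_locations)
    xyz = locations.vertices[: cfg.n_locations]
    x, y, z = (xyz / np.linalg.norm(xyz, axis=1, keepdims=True)).T
    basis = [x, y, z, x * y, x * z, y * z, x * x - y * y, 3 * z * z - 1,
             x * (x * x - 3 * y * y), z * (x * x - y * y)]
    if cfg.archetype_count > len(basis):
        raise ValidationError(
            f"cannot build {cfg.archetype_count} archetypes with |cos| <= 0.3; "
            f"use at most {len(basis)}"
        )
    maps = []
    for vec in basis:
        v = vec.astype(np.float64).copy()
        for u in maps:
            v -= (v @ u) * u
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            continue
        maps.append(v / norm)
        if len(maps) == cfg.archetype_count:
            break
    if len(maps) < cfg.archetype_count:
        raise ValidationError("could not build enough independent archetypes; "
                              "reduce archetype_count")
    return np.stack(maps)


# ---------------------------------------------------------------------------
# covariates and phenotypes
# ---------------------------------------------------------------------------

def simulate_covariates(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ages ~ N(64.4, 7.7) clipped to [45, 83], sex ~ Bernoulli(0.527),
    five standard-normal genetic PCs, and a uniform site assignment."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_participants
    table = pd.DataFrame(
        {
            "age_years": np.clip(rng.normal(64.4, 7.7, size=n), 45, 83),
            "sex": (rng.random(n) < 0.527).astype(int),
            **{f"pc{k}": rng.normal(0, 1, size=n) for k in range(1, 6)},
            "site_id": rng.integers(0, cfg.site_count, size=n),
        },
        index=pd.Index([f"P{i:06d}" for i in range(n)], name="participant_id"),
    )
    return table


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame,
    effect_maps: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    causal_snps: np.ndarray | None = None,
):
    """Phenotype matrix (N, L) plus the planted ground truth.

    ``causal_snps`` may pin the causal columns; by default
    ``archetype_count * n_causal_per_archetype`` clean (valid, polymorphic)
    SNPs are drawn at random and assigned archetypes round-robin.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n, m = genotypes.calls.shape
    n_arch, n_loc = effect_maps.shape
    if len(covariates) != n:
        raise ValidationError("covariate rows != participants")

    meta = genotypes.snp_meta
    if causal_snps is None:
        n_causal = cfg.archetype_count * cfg.n_causal_per_archetype
        clean = np.flatnonzero(
            meta["has_ref_id"].to_numpy()
            & meta["ref_allele_valid"].to_numpy()
        )
        # exclude quasi-monomorphic columns: no variance, no recoverable effect
        nonmiss = genotypes.calls != MISSING
        with np.errstate(invalid="ignore"):
            modal = np.array([
                np.bincount(genotypes.calls[nonmiss[:, j], j], minlength=3).max()
                / max(nonmiss[:, j].sum(), 1)
                for j in clean
            ])
        clean = clean[modal <= 0.99]
        if n_causal > clean.size:
            raise ValidationError("not enough clean SNPs for the causal set")
        causal_snps = np.sort(rng.choice(clean, size=n_causal, replace=False))
    causal_snps = np.asarray(causal_snps)
    archetype_of = np.arange(len(causal_snps)) % n_arch
    effects = np.full(len(causal_snps), float(cfg.effect_size_per_archetype))

    true_maps = effects[:, None] * effect_maps[archetype_of]
    pheno = np.full((n, n_loc), float(cfg.baseline))
    if len(causal_snps):
        calls = genotypes.calls[:, causal_snps].astype(np.float64)
        calls[calls == MISSING] = np.nan
        col_mean = np.nanmean(calls, axis=0)
        inds = np.where(np.isnan(calls))
        calls[inds] = np.take(col_mean, inds[1])
        pheno += calls @ true_maps  # (n_causal, L) true per-SNP effect maps

    ce = cfg.covariate_effects
    covar_term = (
        ce.age_slope * (covariates["age_years"].to_numpy() - 64.4)
        + ce.sex_offset * covariates["sex"].to_numpy()
        + covariates[[f"pc{k}" for k in range(1, 6)]].to_numpy() @ np.asarray(ce.pc_slopes)
    )
    site_offsets = rng.normal(0, cfg.site_effect_sd, size=cfg.site_count)
    site_term = site_offsets[covariates["site_id"].to_numpy()]
    pheno += (covar_term + site_term)[:, None]
    if cfg.noise_sd > 0:
        pheno += rng.normal(0, cfg.noise_sd, size=(n, n_loc))

    truth = {
        "causal_snps": causal_snps,
        "causal_ids": meta["id"].to_numpy()[causal_snps],
        "archetype_of": archetype_of,
        "effect_sizes": effects,
        "true_maps": true_maps,
        "site_offsets": site_offsets,
    }
    return pheno, truth


def simulate_cohort(cfg: SimulationConfig,
                    phenotype_names: tuple = ("CT", "GWC")) -> SyntheticCohort:
    """Full cohort: genotypes, covariates and one phenotype matrix per name.

    Each phenotype gets its own causal-SNP draw and noise but the phenotypes
    share the genotype matrix and covariates, mirroring a multi-trait study.
    """
    rng = np.random.default_rng(cfg.seed)
    genotypes, geno_truth = simulate_genotypes(cfg, rng)
    covariates = simulate_covariates(cfg, rng)
    maps = simulate_effect_maps(cfg)
    phenotypes = {}
    truth = {"genotypes": geno_truth, "effect_maps": maps, "phenotypes": {}}
    for name in phenotype_names:
        pheno, ptruth = simulate_phenotypes(genotypes, covariates, maps, cfg, rng)
        phenotypes[name] = pheno
        truth["phenotypes"][name] = ptruth
    return SyntheticCohort(genotypes=genotypes, covariates=covariates,
                           phenotypes=phenotypes, truth=truth)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 1.0
    wm_radius_mm: float = 20.0
    pial_radius_mm: float = 23.0
    wm_intensity: float = 55.0
    gm_intensity: float = 35.0
    noise_sd: float = 0.0
    n_vertices: int = 642
    seed: int = 0


def simulate_phantom(cfg: PhantomConfig | None = None,
                     target_wm_mean: float = 110.0):
    """Two-shell spherical phantom plus WM/pial meshes and analytic truth.

    Returns ``(VolumeImage, wm_mesh, pial_mesh, truth)`` where truth holds
    the per-vertex thickness (radial separation, mm) and the contrast
    expected after scaling intensities so the WM mean equals
    ``target_wm_mean``.
    """
    if cfg is None:
        cfg = PhantomConfig()
    shape = np.asarray(cfg.grid_shape)
    half_extent = (shape.min() * cfg.voxel_size_mm) / 2.0
    if cfg.pial_radius_mm + 2 * cfg.voxel_size_mm >= half_extent:
        raise ValidationError("pial shell intersects the grid boundary; enlarge the grid")
    center = (shape - 1) / 2.0 * cfg.voxel_size_mm
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = cfg.voxel_size_mm

    idx = np.indices(tuple(shape)).astype(np.float64)
    coords = idx * cfg.voxel_size_mm  # voxel centers in mm
    r = np.sqrt(((coords - center[:, None, None, None]) ** 2).sum(axis=0))
    labels = np.zeros(tuple(shape), dtype=np.int16)
    labels[r < cfg.wm_radius_mm] = VolumeImage.LABEL_WM
    labels[(r >= cfg.wm_radius_mm) & (r < cfg.pial_radius_mm)] = VolumeImage.LABEL_GM
    intensities = np.zeros(tuple(shape))
    intensities[labels == VolumeImage.LABEL_WM] = cfg.wm_intensity
    intensities[labels == VolumeImage.LABEL_GM] = cfg.gm_intensity
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        intensities = np.abs(intensities + rng.normal(0, cfg.noise_sd, size=intensities.shape))
    vol = VolumeImage(intensities=intensities, affine=affine, labels=labels)

    base = location_mesh(cfg.n_vertices)
    unit = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    wm_mesh = SurfaceMesh(vertices=unit * cfg.wm_radius_mm + center, faces=base.faces, name="wm")
    pial_mesh = SurfaceMesh(vertices=unit * cfg.pial_radius_mm + center, faces=base.faces, name="pial")

    scale = target_wm_mean / cfg.wm_intensity
    gm_scaled = cfg.gm_intensity * scale
    truth = {
        "ct_mm": np.full(len(base.vertices), cfg.pial_radius_mm - cfg.wm_radius_mm),
        "gwc": np.full(
            len(base.vertices),
            (target_wm_mean - gm_scaled) / (target_wm_mean + gm_scaled),
        ),
        "scale": scale,
    }
    return vol, wm_mesh, pial_mesh, truth
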