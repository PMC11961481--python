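"""SNP-vs-ensemble deviation test on standardized beta maps.

At each cortical location the mean and standard deviation of the regression
betas are taken across the SNP ensemble; each SNP's beta is standardized to
a z-score against these ensemble moments.  The empirical significance of a
SNP at a location is then the two-tailed tail probability of its z-score —
a test of whether the SNP's association pattern deviates from the typical
(mean) pattern across SNPs, using the ensemble itself as the null, not the
regression standard error.

Two ambiguities of the procedure are exposed as options rather than guessed:
the focal SNP can be included in the ensemble moments (``include-self``,
default) or left out (``loo``), and the tail probability can be normal
(default; at genome scale the two are numerically identical) or Student-t
with df = n_SNPs - 1.  The standard deviation is the sample (n-1) form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import AssociationTensor, bh_adjust
from .types import ValidationError


@dataclass
class ZScoreMap:
    snp_ids: np.ndarray
    z: np.ndarray                  # (M, L)
    mu_beta: np.ndarray            # (L,) ensemble mean (include-self moments)
    sd_beta: np.ndarray            # (L,) ensemble sd
    mode: str = "include-self"
    p_emp: np.ndarray | None = None
    q_emp: np.ndarray | None = None

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]


def standardize_betas(tensor: AssociationTensor, mode: str = "include-self",
                      ddof: int = 1) -> ZScoreMap:
    """Standardize betas across SNPs at each location.

    ``loo`` excludes the focal SNP from the moments, matching the null
    hypothesis phrasing "did not differ from the mean across all other
    SNPs"; at ensemble scale the difference is negligible and bounded by
    the tests.
    """
    if mode not in ("include-self", "loo"):
        raise ValueError(f"unknown standardization mode {mode!r}")
    beta = np.asarray(tensor.beta, dtype=np.float64)
    m = beta.shape[0]
    if m < 3:
        raise ValidationError("need at least 3 SNPs per location to standardize")
    mu = beta.mean(axis=0)
    sd = beta.std(axis=0, ddof=ddof)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        raise ValidationError(
            f"zero beta dispersion at location(s) {degenerate[:5].tolist()}; "
            "cannot standardize"
        )
    if mode == "include-self":
        z = (beta - mu) / sd
    else:
        total = beta.sum(axis=0)
        sumsq = (beta * beta).sum(axis=0)
        mu_loo = (total - beta) / (m - 1)
        # sum of squared deviations about the leave-one-out mean
        ss = sumsq - beta * beta - (m - 1) * mu_loo * mu_loo
        var_loo = np.maximum(ss, 0.0) / (m - 1 - ddof)
        sd_loo = np.sqrt(var_loo)
        if np.any(sd_loo == 0):
            loc = np.flatnonzero((sd_loo == 0).any(axis=0))
            raise ValidationError(f"zero leave-one-out dispersion at location(s) {loc[:5].tolist()}")
        z = (beta - mu_loo) / sd_loo
    return ZScoreMap(snp_ids=tensor.snp_ids.copy(), z=z, mu_beta=mu, sd_beta=sd, mode=mode)


def empirical_p(zmap: ZScoreMap, alpha: float = 0.05, dist: str = "normal",
                bh_scope: str = "global") -> ZScoreMap:
    """Attach two-tailed empirical p-values and their BH adjustment.

    ``dist``: "normal" (default) or "t" with df = n_SNPs - 1.
    """
    z = np.abs(zmap.z)
    if dist == "normal":
        p = 2.0 * stats.norm.sf(z)
    elif dist == "t":
        p = 2.0 * stats.t.sf(z, df=zmap.n_snps - 1)
    else:
        raise ValueError(f"unknown dist {dist!r}")
    if bh_scope == "global":
        q, _ = bh_adjust(p, alpha)
    elif bh_scope == "per-snp":
        q = np.empty_like(p)
        for j in range(p.shape[0]):
            q[j], _ = bh_adjust(p[j], alpha)
    else:
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    zmap.p_emp = p
    zmap.q_emp = q
    return zmap


def standardize_with_moments(beta_map: np.ndarray, zmap: ZScoreMap) -> np.ndarray:
    """Standardize an arbitrary beta map against the ensemble moments.

    Used for gene- and cluster-averaged maps: averaging happens on the raw
    beta scale, then the average is put through the same z-scoring as any
    single SNP.
    """
    beta_map = np.asarray(beta_map, dtype=np.float64)
    if beta_map.shape[-1] != zmap.mu_beta.shape[0]:
        raise ValidationError("beta map length != number of locations")
    return (beta_map - zmap.mu_beta) / zmap.sd_beta
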