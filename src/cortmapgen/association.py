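"""Genotype QC, vertex-wise linear-model association and FDR control.

The association model at every (SNP, location) pair is ordinary least
squares of the phenotype on [intercept, genotype, age, sex, pc1..pc5]
(9 regressors including the intercept), where genotype is the
reference-allele count.  Participants with a missing call at a SNP are
dropped for that SNP only (complete-case per SNP, no dosage imputation), so
the effective sample size varies across SNPs.  The genotype coefficient's
two-tailed Student-t p-value uses the standard OLS degrees of freedom,
df = n_used - 9.  Imaging site is deliberately NOT a covariate; it enters
only the variance-explained diagnostic.

Benjamini-Hochberg correction is applied, by default, over the full
SNP x location p-value universe of one phenotype ("global" scope, the most
conservative reading of genome-wide FDR control); per-SNP and per-location
scopes are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import (
    COVARIATE_COLUMNS,
    MISSING,
    GenotypeMatrix,
    ValidationError,
    validate_covariates,
)

logger = logging.getLogger(__name__)

N_REGRESSORS = 2 + len(COVARIATE_COLUMNS)  # intercept + genotype + covariates


class CollinearityError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; the message names the column."""


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Exclusion counts by rule, applied in order (first rule that fires):

    A insufficient non-missing calls, B quasi-monomorphic (modal genotype
    frequency among non-missing > mono_frac), C missing reference
    identifier, D invalid reference allele.
    """

    n_input: int
    excluded_a: int
    excluded_b: int
    excluded_c: int
    excluded_d: int
    surviving_ids: list = field(default_factory=list)

    @property
    def n_surviving(self) -> int:
        return self.n_input - (self.excluded_a + self.excluded_b
                               + self.excluded_c + self.excluded_d)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded_a_low_n": self.excluded_a,
            "excluded_b_monomorphic": self.excluded_b,
            "excluded_c_missing_id": self.excluded_c,
            "excluded_d_bad_allele": self.excluded_d,
            "n_surviving": self.n_surviving,
        }


def default_min_n(n_participants: int) -> int:
    """Minimum per-SNP sample size, scaled from the 35,000-of-43,030 rule."""
    return int(round(n_participants * 35000 / 43030))


def qc_filter(g: GenotypeMatrix, min_n: int | None = None,
              mono_frac: float = 0.99):
    """Apply exclusion rules A-D; returns (filtered GenotypeMatrix, QCReport)."""
    if min_n is None:
        min_n = default_min_n(g.n_participants)
    calls = g.calls
    nonmissing = calls != MISSING
    n_obs = nonmissing.sum(axis=0)

    rule_a = n_obs < min_n
    modal = np.zeros(g.n_snps)
    for j in range(g.n_snps):
        if n_obs[j] == 0:
            modal[j] = 1.0
            continue
        counts = np.bincount(calls[nonmissing[:, j], j], minlength=3)
        modal[j] = counts.max() / n_obs[j]
    rule_b = modal > mono_frac
    rule_c = ~g.snp_meta["has_ref_id"].to_numpy(dtype=bool)
    rule_d = ~g.snp_meta["ref_allele_valid"].to_numpy(dtype=bool)

    first = np.full(g.n_snps, -1)
    for code, rule in enumerate((rule_a, rule_b, rule_c, rule_d)):
        first[(first == -1) & rule] = code
    keep = first == -1
    report = QCReport(
        n_input=g.n_snps,
        excluded_a=int((first == 0).sum()),
        excluded_b=int((first == 1).sum()),
        excluded_c=int((first == 2).sum()),
        excluded_d=int((first == 3).sum()),
        surviving_ids=list(g.snp_meta["id"].to_numpy()[keep]),
    )
    return g.subset_snps(keep), report


# ---------------------------------------------------------------------------
# regression core
# ---------------------------------------------------------------------------

def _design_base(covars: pd.DataFrame) -> np.ndarray:
    """(N, 8) design with a zeroed genotype column at index 1."""
    n = len(covars)
    X = np.empty((n, N_REGRESSORS))
    X[:, 0] = 1.0
    X[:, 1] = 0.0
    for k, col in enumerate(COVARIATE_COLUMNS):
        X[:, 2 + k] = covars[col].to_numpy(dtype=np.float64)
    return X

_COLUMN_NAMES = ("intercept", "genotype") + COVARIATE_COLUMNS


def _check_rank(XtX: np.ndarray) -> None:
    """Raise CollinearityError naming the offending column via pivoted QR."""
    from scipy.linalg import qr

    _, r, piv = qr(XtX, pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(XtX.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < XtX.shape[1]:
        bad = piv[rank]
        raise CollinearityError(
            f"design matrix is rank deficient: column {_COLUMN_NAMES[bad]!r} "
            "is collinear with the others"
        )


def _fit_masked(X: np.ndarray, Y: np.ndarray, Ysq_cols: np.ndarray | None,
                mask: np.ndarray):
    """OLS of each Y column on X restricted to masked rows.

    Returns (beta, se, t, p, df) for the genotype coefficient, each of
    shape (L,).  ``Ysq_cols`` may carry precomputed column-wise squares.
    """
    n_used = int(mask.sum())
    df = n_used - N_REGRESSORS
    Xm = X * mask[:, None]
    XtX = Xm.T @ X
    _check_rank(XtX)
    XtY = Xm.T @ Y
    if Ysq_cols is None:
        yty = mask @ (Y * Y)
    else:
        yty = mask @ Ysq_cols
    beta_all = np.linalg.solve(XtX, XtY)            # (8, L)
    rss = yty - (beta_all * XtY).sum(axis=0)
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    var_g = np.linalg.inv(XtX)[1, 1]
    se = np.sqrt(sigma2 * var_g)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta_all[1] / np.where(se > 0, se, 1.0), np.inf * np.sign(beta_all[1]))
        t = np.where((se == 0) & (beta_all[1] == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta_all[1], se, t, p, df


def fit_association(geno_column: np.ndarray, pheno_column: np.ndarray,
                    covars: pd.DataFrame):
    """Single SNP x single location fit.

    Returns ``(beta, se, t, df, p, n_used)`` for the genotype coefficient.
    """
    validate_covariates(covars)
    geno = np.array(geno_column, dtype=np.float64, copy=True)
    geno[geno == MISSING] = np.nan
    pheno = np.asarray(pheno_column, dtype=np.float64)
    mask = ~np.isnan(geno) & ~np.isnan(pheno)
    if mask.sum() < N_REGRESSORS + 2:
        raise ValidationError(
            f"too few complete cases ({int(mask.sum())}) for {N_REGRESSORS} regressors"
        )
    X = _design_base(covars)
    X[:, 1] = np.where(mask, np.nan_to_num(geno), 0.0)
    beta, se, t, p, df = _fit_masked(X, pheno[:, None], None, mask)
    return float(beta[0]), float(se[0]), float(t[0]), int(df), float(p[0]), int(mask.sum())


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------

def bh_adjust(p_values: np.ndarray, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: returns (q_values, significance flags).

    q_i = min_{j >= rank(i)} m * p_(j) / j capped at 1; significant iff
    q <= alpha, which reproduces the classic step-up decision set.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    shape = p.shape
    reject, q, _, _ = multipletests(p.ravel(), alpha=alpha, method="fdr_bh")
    return q.reshape(shape), reject.reshape(shape)


# ---------------------------------------------------------------------------
# tensor
# ---------------------------------------------------------------------------

@dataclass
class AssociationTensor:
    """Per SNP x location regression results for one phenotype."""

    snp_ids: np.ndarray          # (M,)
    beta: np.ndarray             # (M, L) phenotype units per reference allele
    se: np.ndarray               # (M, L)
    t_stat: np.ndarray           # (M, L)
    p: np.ndarray                # (M, L) two-tailed
    q: np.ndarray                # (M, L) BH-adjusted
    significant: np.ndarray      # (M, L) bool, q <= alpha
    df: np.ndarray               # (M,)
    n_used: np.ndarray           # (M,)
    alpha: float = 0.05
    bh_scope: str = "global"
    phenotype: str = ""

    @property
    def n_snps(self) -> int:
        return self.beta.shape[0]

    @property
    def n_locations(self) -> int:
        return self.beta.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (snp, location, beta, se, t, df, p, q, sig, n_used)."""
        m, loc = self.beta.shape
        return pd.DataFrame(
            {
                "snp": np.repeat(self.snp_ids, loc),
                "location": np.tile(np.arange(loc), m),
                "beta": self.beta.ravel(),
                "se": self.se.ravel(),
                "t": self.t_stat.ravel(),
                "df": np.repeat(self.df, loc),
                "p": self.p.ravel(),
                "q": self.q.ravel(),
                "significant": self.significant.ravel(),
                "n_used": np.repeat(self.n_used, loc),
            }
        )


def run_gwas(g: GenotypeMatrix, pheno: np.ndarray, covars: pd.DataFrame,
             alpha: float = 0.05, bh_scope: str = "global",
             phenotype: str = "") -> AssociationTensor:
    """Fit every SNP against every location and BH-correct the p-values.

    ``pheno`` is (participants, locations); QC is assumed already applied.
    """
    validate_covariates(covars)
    pheno = np.asarray(pheno, dtype=np.float64)
    n, n_loc = pheno.shape
    if n != g.n_participants:
        raise ValidationError("phenotype rows != participants")
    if bh_scope not in ("global", "per-snp", "per-location"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")

    pheno_ok = ~np.isnan(pheno).any(axis=1)
    X = _design_base(covars)
    Ysq = pheno * pheno
    m = g.n_snps
    beta = np.empty((m, n_loc))
    se = np.empty((m, n_loc))
    t = np.empty((m, n_loc))
    p = np.empty((m, n_loc))
    df = np.empty(m, dtype=np.int64)
    n_used = np.empty(m, dtype=np.int64)
    for j in range(m):
        geno = g.calls[:, j]
        mask = (geno != MISSING) & pheno_ok
        n_used[j] = int(mask.sum())
        if n_used[j] < N_REGRESSORS + 2:
            logger.warning("SNP %s: only %d complete cases; marked missing",
                           g.snp_meta['id'].iloc[j], n_used[j])
            beta[j] = se[j] = t[j] = p[j] = np.nan
            df[j] = 0
            continue
        X[:, 1] = np.where(mask, geno, 0).astype(np.float64)
        try:
            beta[j], se[j], t[j], p[j], df_j = _fit_masked(X, pheno, Ysq, mask)
        except CollinearityError as exc:
            raise CollinearityError(f"SNP {g.snp_meta['id'].iloc[j]}: {exc}") from exc
        df[j] = df_j

    q = np.full_like(p, np.nan)
    sig = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    if bh_scope == "global":
        if valid.any():
            q[valid], sig[valid] = bh_adjust(p[valid], alpha)
    elif bh_scope == "per-snp":
        for j in range(m):
            if valid[j].any():
                q[j, valid[j]], sig[j, valid[j]] = bh_adjust(p[j, valid[j]], alpha)
    else:  # per-location
        for loc in range(n_loc):
            v = valid[:, loc]
            if v.any():
                q[v, loc], sig[v, loc] = bh_adjust(p[v, loc], alpha)
    return AssociationTensor(
        snp_ids=g.snp_meta["id"].to_numpy(), beta=beta, se=se, t_stat=t, p=p,
        q=q, significant=sig, df=df, n_used=n_used, alpha=alpha,
        bh_scope=bh_scope, phenotype=phenotype,
    )


def coverage(tensor: AssociationTensor) -> pd.DataFrame:
    """Per-SNP percentage of locations with a significant association."""
    pct = 100.0 * tensor.significant.sum(axis=1) / tensor.n_locations
    return pd.DataFrame({"snp": tensor.snp_ids, "coverage_pct": pct})
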