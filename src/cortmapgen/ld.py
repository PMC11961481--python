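"""Two-locus linkage disequilibrium from unphased genotypes.

Haplotype frequencies are estimated by expectation-maximization over the
two-locus multinomial likelihood: all genotype cells determine their two
haplotypes except the double heterozygote, whose mass is split between the
coupling (AB/ab) and repulsion (Ab/aB) phases in proportion to the current
haplotype-frequency products.  "A" denotes the REFERENCE allele at each
locus, consistent with the genotype coding; D' and R^2 are invariant to
allele labeling but the haplotype table itself is not.

From the frequencies: D = p_AB - p_A p_B; Dmax = min(p_A p_b, p_a p_B) for
D > 0, else min(p_A p_B, p_a p_b); D' = |D| / Dmax (defined as 0 when
D = 0); R^2 = D^2 / (p_A p_a p_B p_b).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, GenotypeMatrix, ValidationError

_TOL = 1e-8
_MAX_ITER = 1000


@dataclass
class HaplotypeEstimate:
    """EM output: frequencies ordered (p_AB, p_Ab, p_aB, p_ab)."""

    freqs: np.ndarray
    n_pairs: int
    iterations: int
    loglik_trace: list = field(default_factory=list)

    @property
    def p_AB(self) -> float:
        return float(self.freqs[0])

    @property
    def p_Ab(self) -> float:
        return float(self.freqs[1])

    @property
    def p_aB(self) -> float:
        return float(self.freqs[2])

    @property
    def p_ab(self) -> float:
        return float(self.freqs[3])


def _genotype_cell_counts(geno1: np.ndarray, geno2: np.ndarray):
    g1 = np.asarray(geno1)
    g2 = np.asarray(geno2)
    ok = (g1 != MISSING) & (g2 != MISSING)
    n = int(ok.sum())
    if n < 2:
        raise ValidationError(f"need at least 2 complete genotype pairs, got {n}")
    cells = np.zeros((3, 3), dtype=np.int64)
    np.add.at(cells, (g1[ok], g2[ok]), 1)
    return cells, n


def _loglik(cells: np.ndarray, f: np.ndarray) -> float:
    pAB, pAb, paB, pab = f
    probs = np.array(
        [
            [pab ** 2, 2 * pab * paB, paB ** 2],
            [2 * pab * pAb, 2 * pAB * pab + 2 * pAb * paB, 2 * pAB * paB],
            [pAb ** 2, 2 * pAB * pAb, pAB ** 2],
        ]
    )
    with np.errstate(divide="ignore"):
        logp = np.where(cells > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((cells * logp).sum())


def em_haplotypes(geno1: np.ndarray, geno2: np.ndarray) -> HaplotypeEstimate:
    """EM haplotype-frequency estimate for a pair of SNPs.

    Initialization splits double heterozygotes equally between the two
    phases; convergence when the largest frequency change is below 1e-8 or
    after 1,000 iterations.  The log-likelihood trace is recorded so the
    monotone-EM property can be asserted.
    """
    cells, n = _genotype_cell_counts(geno1, geno2)
    n_hap = 2.0 * n
    n_dh = cells[1, 1]  # double heterozygotes: phase-ambiguous

    # haplotype counts fully determined by every cell except (1,1)
    base_AB = 2 * cells[2, 2] + cells[2, 1] + cells[1, 2]
    base_Ab = 2 * cells[2, 0] + cells[2, 1] + cells[1, 0]
    base_aB = 2 * cells[0, 2] + cells[0, 1] + cells[1, 2]
    base_ab = 2 * cells[0, 0] + cells[0, 1] + cells[1, 0]

    def m_step(alpha: float) -> np.ndarray:
        c = np.array(
            [
                base_AB + alpha * n_dh,
                base_Ab + (1 - alpha) * n_dh,
                base_aB + (1 - alpha) * n_dh,
                base_ab + alpha * n_dh,
            ],
            dtype=np.float64,
        )
        return c / n_hap

    freqs = m_step(0.5)
    trace = [_loglik(cells, freqs)]
    iterations = 0
    for iterations in range(1, _MAX_ITER + 1):
        pAB, pAb, paB, pab = freqs
        coupling = pAB * pab
        repulsion = pAb * paB
        alpha = 0.5 if (coupling + repulsion) == 0 else coupling / (coupling + repulsion)
        new = m_step(alpha)
        trace.append(_loglik(cells, new))
        delta = np.abs(new - freqs).max()
        freqs = new
        if delta < _TOL:
            break
    return HaplotypeEstimate(freqs=freqs, n_pairs=n, iterations=iterations,
                             loglik_trace=trace)


def ld_stats(haps: HaplotypeEstimate | np.ndarray):
    """(D, D', R^2) from haplotype frequencies; errors on a monomorphic locus."""
    f = haps.freqs if isinstance(haps, HaplotypeEstimate) else np.asarray(haps, dtype=float)
    if f.shape != (4,):
        raise ValidationError("expected 4 haplotype frequencies (AB, Ab, aB, ab)")
    if np.any(f < -1e-9) or abs(f.sum() - 1.0) > 1e-6:
        raise ValidationError("haplotype frequencies must be non-negative and sum to 1")
    pAB, pAb, paB, pab = f
    pA = pAB + pAb
    pB = pAB + paB
    pa, pb = 1 - pA, 1 - pB
    if min(pA, pa) <= 0 or min(pB, pb) <= 0:
        raise ValidationError("monomorphic locus: LD undefined")
    d = pAB - pA * pB
    if d > 0:
        dmax = min(pA * pb, pa * pB)
    else:
        dmax = min(pA * pB, pa * pb)
    dprime = 0.0 if d == 0 else abs(d) / dmax
    r2 = d * d / (pA * pa * pB * pb)
    return float(d), float(dprime), float(r2)


@dataclass
class LDMatrixResult:
    snp_ids: list
    d: np.ndarray
    dprime: np.ndarray
    r_squared: np.ndarray
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        m = len(self.snp_ids)
        for i in range(m):
            for j in range(i + 1, m):
                rows.append(
                    {
                        "snp_i": self.snp_ids[i],
                        "snp_j": self.snp_ids[j],
                        "D": self.d[i, j],
                        "Dprime": self.dprime[i, j],
                        "R2": self.r_squared[i, j],
                        "n": int(self.n_pairs[i, j]),
                    }
                )
        return pd.DataFrame(rows)


def ld_matrix(g: GenotypeMatrix, snp_ids: list) -> LDMatrixResult:
    """Pairwise D'/R^2 among the named SNPs.

    Pairs on different chromosomes are reported as NaN (undefined), the
    diagonal as 1.
    """
    idx = [g.snp_index(str(s)) for s in snp_ids]
    chroms = [str(g.snp_meta["chrom"].iloc[j]) for j in idx]
    m = len(idx)
    d = np.full((m, m), np.nan)
    dprime = np.full((m, m), np.nan)
    r2 = np.full((m, m), np.nan)
    n_pairs = np.zeros((m, m), dtype=np.int64)
    np.fill_diagonal(dprime, 1.0)
    np.fill_diagonal(r2, 1.0)
    np.fill_diagonal(d, 0.0)
    for a in range(m):
        for b in range(a + 1, m):
            if chroms[a] != chroms[b]:
                continue
            est = em_haplotypes(g.calls[:, idx[a]], g.calls[:, idx[b]])
            try:
                dv, dp, r2v = ld_stats(est)
            except ValidationError:
                continue  # monomorphic in this sample: leave undefined
            d[a, b] = d[b, a] = dv
            dprime[a, b] = dprime[b, a] = dp
            r2[a, b] = r2[b, a] = r2v
            n_pairs[a, b] = n_pairs[b, a] = est.n_pairs
    return LDMatrixResult(snp_ids=[str(s) for s in snp_ids], d=d, dprime=dprime,
                          r_squared=r2, n_pairs=n_pairs)
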