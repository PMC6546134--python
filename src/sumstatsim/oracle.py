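"""Individual-level forward simulator and single-SNP analyzers.

This is the slow validation path the direct simulator replaces: sample N0
control and N1 case genotypes from the panel (cases by exact rejection from
the exponentially tilted haplotype-pair law), then compute the trend-test Z
and a per-SNP logistic Wald fit. Cost scales linearly in N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .causal import CausalModel, EnrichmentModel
from .panel import HaplotypePanel

__all__ = [
    "IndividualStudy",
    "OracleResult",
    "sample_study",
    "cochran_armitage_z",
    "logistic_wald",
]


@dataclass
class IndividualStudy:
    """Genotype dosage matrix with case/control labels."""

    genotypes: np.ndarray  # (N, n) in {0,1,2}
    phenotypes: np.ndarray  # (N,) in {0,1}
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.shape[0] != self.phenotypes.shape[0]:
            raise ValueError("genotype/phenotype length mismatch")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be in {0,1,2}")
        if not np.isin(self.phenotypes, (0, 1)).all():
            raise ValueError("phenotypes must be binary")

    @property
    def n1(self) -> int:
        return int(self.phenotypes.sum())

    @property
    def n0(self) -> int:
        return len(self.phenotypes) - self.n1


@dataclass
class OracleResult:
    """Per-SNP score Z and logistic Wald (beta, se); NaN where flagged."""

    snp_ids: np.ndarray
    z: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    flagged: np.ndarray  # monomorphic / separated / non-converged


def sample_study(panel: HaplotypePanel, model: CausalModel,
                 enr: EnrichmentModel, seed: int,
                 snp_subset=None, min_acceptance: float = 1e-8,
                 ) -> IndividualStudy:
    """Sample a case-control study conditional on the design (N0, N1).

    Controls are random unions of two panel haplotypes. Cases are drawn by
    rejection: propose a haplotype pair, accept with probability
    ``exp(gamma . w - max_w' gamma . w')`` where w is the proposed causal
    genotype vector, which targets exactly the tilted case distribution
    P1(w) = P0(w) exp(gamma.w) / C.

    ``snp_subset`` restricts the genotype matrix to the named SNPs (the
    sampling itself always uses the causal SNPs).
    """
    rng = np.random.default_rng(seed)
    H = panel.n_haplotypes
    cidx = np.array([panel.index_of(s) for s in model.causal_ids])
    out_idx = (np.arange(panel.n_snps) if snp_subset is None
               else np.array([panel.index_of(s) for s in snp_subset]))
    A = panel.alleles

    # max of gamma . w over achievable causal genotype vectors (pairs drawn
    # with replacement, so the max is twice the best single haplotype)
    hap_eta = A[:, cidx].astype(float) @ model.gamma
    eta_max = 2.0 * float(hap_eta.max())
    accept_rate = float(np.mean(np.exp(hap_eta - hap_eta.max()))) ** 2
    if accept_rate < min_acceptance:
        raise OverflowError(
            f"rejection acceptance rate {accept_rate:.2e} underflows; "
            "reduce |gamma|")

    h0 = rng.integers(0, H, size=(model.n0, 2))
    controls = A[h0[:, 0]][:, out_idx] + A[h0[:, 1]][:, out_idx]

    cases = np.empty((model.n1, len(out_idx)), dtype=np.int8)
    filled = 0
    while filled < model.n1:
        batch = max(1024, 2 * (model.n1 - filled))
        h = rng.integers(0, H, size=(batch, 2))
        eta = hap_eta[h[:, 0]] + hap_eta[h[:, 1]]
        accept = rng.random(batch) < np.exp(eta - eta_max)
        take = np.flatnonzero(accept)[: model.n1 - filled]
        if take.size:
            cases[filled: filled + take.size] = (
                A[h[take, 0]][:, out_idx] + A[h[take, 1]][:, out_idx])
            filled += take.size

    genotypes = np.vstack([controls, cases]).astype(np.int8)
    phenotypes = np.concatenate([np.zeros(model.n0, dtype=np.int8),
                                 np.ones(model.n1, dtype=np.int8)])
    return IndividualStudy(genotypes, phenotypes, panel.snp_ids[out_idx])


def _dosage_tables(study: IndividualStudy) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP 3-vector genotype counts among controls and cases."""
    y = study.phenotypes.astype(bool)
    g = study.genotypes
    n_snps = g.shape[1]
    c0 = np.stack([np.bincount(g[~y, j], minlength=3) for j in range(n_snps)])
    c1 = np.stack([np.bincount(g[y, j], minlength=3) for j in range(n_snps)])
    return c0, c1


def cochran_armitage_z(study: IndividualStudy) -> OracleResult:
    """Additive trend-test Z per SNP: U / sqrt((N-1) V_X V_Y).

    V_X and V_Y are (N-1)-divisor sample variances. Monomorphic SNPs are
    flagged (Z undefined) rather than raised.
    """
    y = study.phenotypes.astype(float)
    n = len(y)
    n1 = y.sum()
    if n1 == 0 or n1 == n:
        raise ValueError("phenotype is constant")
    c0, c1 = _dosage_tables(study)
    tot = c0 + c1
    gvals = np.arange(3.0)
    sum_g = tot @ gvals
    sum_g2 = tot @ gvals ** 2
    sum_gy = c1 @ gvals
    u = sum_gy - sum_g * n1 / n
    vx = (sum_g2 - sum_g ** 2 / n) / (n - 1)
    vy = n1 * (n - n1) / (n * (n - 1))
    flagged = vx <= 0
    z = np.full(len(vx), np.nan)
    okv = ~flagged
    z[okv] = u[okv] / np.sqrt((n - 1) * vx[okv] * vy)
    return OracleResult(study.snp_ids, z, np.full_like(z, np.nan),
                        np.full_like(z, np.nan), flagged)


def _logistic_fit_counts(c0: np.ndarray, c1: np.ndarray,
                         tol: float = 1e-8, max_iter: int = 50):
    """Newton fit of logit P(Y=1) = a + b*g from a 2x3 genotype table.

    Returns (beta, se, converged). Aggregation over the 6 cells makes each
    iteration O(1) regardless of N.
    """
    g = np.arange(3.0)
    tot = c0 + c1
    a, b = float(np.log((c1.sum() + 0.5) / (c0.sum() + 0.5))), 0.0
    for _ in range(max_iter):
        eta = a + b * g
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = tot * mu * (1 - mu)
        grad = np.array([np.sum(c1 - tot * mu), np.sum((c1 - tot * mu) * g)])
        hess = np.array([[w.sum(), (w * g).sum()],
                         [(w * g).sum(), (w * g * g).sum()]])
        if np.linalg.norm(grad) < tol:
            if np.abs(eta).max() > 15:  # (quasi-)separation: MLE diverging
                return b, np.nan, False
            cov = np.linalg.inv(hess)
            return b, float(np.sqrt(cov[1, 1])), True
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return b, np.nan, False
        if not np.isfinite(step).all() or np.abs(step).max() > 1e6:
            return b, np.nan, False
        a += step[0]
        b += step[1]
    return b, np.nan, False


def logistic_wald(study: IndividualStudy) -> OracleResult:
    """Per-SNP single-predictor logistic regression Wald (beta, se).

    Iterates Newton/IRLS to gradient norm < 1e-8; separation or
    non-convergence within 50 iterations flags the SNP.
    """
    c0, c1 = _dosage_tables(study)
    n_snps = c0.shape[0]
    beta = np.full(n_snps, np.nan)
    se = np.full(n_snps, np.nan)
    flagged = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        if (c0[j] + c1[j] > 0).sum() < 2:
            flagged[j] = True  # monomorphic
            continue
        b, s, ok = _logistic_fit_counts(c0[j], c1[j])
        if not ok or not np.isfinite(s):
            flagged[j] = True
            continue
        beta[j], se[j] = b, s
    return OracleResult(study.snp_ids, np.full(n_snps, np.nan), beta, se,
                        flagged)
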