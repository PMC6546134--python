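"""Deterministic math core: expected score statistics for a region.

For each SNP X the expected score numerator E(U_X) is an exact enumeration
over causal genotype classes; the sample variance V_X of genotype dosage is
modelled as inverse gamma with parameters fitted by method of moments from
its exact first two moments; and the expected Z score is the first-order
product

    Z_E = E(U_X) * E(V_X^{-1/2}) / sqrt((N-1) * V_Y)

with V_Y = N0*N1 / (N*(N-1)) the (N-1)-divisor sample variance of the
phenotype. None of these quantities requires individual-level data and their
cost is independent of N0 and N1.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.special import gammaln

from .causal import (CausalModel, EnrichmentModel, CaseControlGenotypeDist,
                     group_genotype_dist, solve_enrichment)
from .panel import (HaplotypePanel, JointGenotypeTable, haplotype_freq_table,
                    joint_genotype_probs)

__all__ = [
    "ExpectedSummary",
    "expected_u",
    "variance_moments",
    "fit_inverse_gamma",
    "expected_inv_sqrt_v",
    "expected_z_region",
    "phenotype_variance",
]


class DegenerateVarianceError(ValueError):
    """Signals E(V^2) <= E(V)^2: the dosage variance is (near) constant."""


@dataclass
class ExpectedSummary:
    """Per-SNP expected summary statistics for a region."""

    snp_ids: np.ndarray
    eu: np.ndarray
    ev: np.ndarray
    ev2: np.ndarray
    alpha: np.ndarray  # NaN where degenerate
    beta: np.ndarray
    degenerate: np.ndarray  # bool: V_X treated as the constant ev
    vy: float
    ze: np.ndarray
    n0: int
    n1: int
    n_enum_ops: int = 0  # enumeration work; independent of N0, N1

    def __post_init__(self) -> None:
        n = self.n0 + self.n1
        assert self.vy == self.n0 * self.n1 / (n * (n - 1))
        if np.any((self.eu == 0) & (self.ze != 0)):
            raise ValueError("ze must vanish where eu vanishes")


def phenotype_variance(n0: int, n1: int) -> float:
    """(N-1)-divisor sample variance of the case indicator."""
    n = n0 + n1
    return n0 * n1 / (n * (n - 1))


# ---------------------------------------------------------------------------
# E(U_X)
# ---------------------------------------------------------------------------

def expected_u(snp_id, model: CausalModel, joint: JointGenotypeTable,
               enr: EnrichmentModel) -> float:
    """Expected score-test numerator at one SNP.

    ``(N-1) * N0 * N1 / N**2 * sum_w (factor(w) - 1) *
    [2 P0(G_X=2, G_W=w) + P0(G_X=1, G_W=w)]``
    where factor(w) = (N0/N1) exp(gamma0 + gamma.w) = exp(gamma.w)/C.
    """
    jx = joint.subset.index(snp_id)
    jw = [joint.subset.index(s) for s in model.causal_ids]
    gx = joint.genotypes[:, jx].astype(float)
    eta = joint.genotypes[:, jw].astype(float) @ model.gamma
    fac = np.exp(eta) / enr.normalizer
    n0, n1 = model.n0, model.n1
    n = n0 + n1
    scale = (n - 1) * n0 * n1 / n ** 2
    return float(scale * np.sum(joint.probs * (fac - 1.0) * gx))


# ---------------------------------------------------------------------------
# Exact moments of the dosage sample variance
# ---------------------------------------------------------------------------

_STIRLING2 = {
    (0, 0): 1,
    (1, 1): 1,
    (2, 1): 1, (2, 2): 1,
    (3, 1): 1, (3, 2): 3, (3, 3): 1,
    (4, 1): 1, (4, 2): 7, (4, 3): 6, (4, 4): 1,
}


def _falling(n: float, k: int) -> float:
    out = 1.0
    for i in range(k):
        out *= n - i
    return out


def _poly_mul(a: dict, b: dict) -> dict:
    out: dict = {}
    for ea, ca in a.items():
        for eb, cb in b.items():
            e = tuple(x + y for x, y in zip(ea, eb))
            out[e] = out.get(e, 0.0) + ca * cb
    return out


def _poly_pow(p: dict, k: int) -> dict:
    out = {(0, 0, 0): 1.0}
    for _ in range(k):
        out = _poly_mul(out, p)
    return out


def _multinomial_expect(poly: dict, n: int, probs: np.ndarray) -> float:
    """E of a polynomial in multinomial counts (n over 3 categories).

    Uses E[(n0)_u (n1)_v (n2)_w] = (n)_{u+v+w} p0^u p1^v p2^w after
    converting powers to falling factorials with Stirling numbers.
    """
    total = 0.0
    for (i, j, k), coef in poly.items():
        if coef == 0.0:
            continue
        acc = 0.0
        for u in range(i + 1):
            su = _STIRLING2.get((i, u), 0)
            if not su:
                continue
            for v in range(j + 1):
                sv = _STIRLING2.get((j, v), 0)
                if not sv:
                    continue
                for w in range(k + 1):
                    sw = _STIRLING2.get((k, w), 0)
                    if not sw:
                        continue
                    acc += (su * sv * sw * _falling(n, u + v + w)
                            * probs[0] ** u * probs[1] ** v * probs[2] ** w)
        total += coef * acc
    return total


def _group_sum_moments(p: np.ndarray, n: int, values: np.ndarray) -> dict:
    """Joint moments E[S1^a S2^b] of S1 = sum v(g_i), S2 = sum v(g_i)^2.

    g_i are n i.i.d. draws from ``p`` over {0,1,2}; ``values`` maps genotype
    to the (centred) dosage v(g). Returns all (a, b) with a + 2b <= 4.
    """
    e1 = {(1, 0, 0): values[0], (0, 1, 0): values[1], (0, 0, 1): values[2]}
    e2 = {(1, 0, 0): values[0] ** 2, (0, 1, 0): values[1] ** 2,
          (0, 0, 1): values[2] ** 2}
    out = {}
    for a, b in [(0, 0), (1, 0), (2, 0), (3, 0), (4, 0),
                 (0, 1), (1, 1), (2, 1), (0, 2)]:
        poly = _poly_mul(_poly_pow(e1, a), _poly_pow(e2, b))
        out[(a, b)] = _multinomial_expect(poly, n, p)
    return out


def variance_moments(dist: CaseControlGenotypeDist, n0: int,
                     n1: int) -> tuple[float, float]:
    """Exact E(V_X) and E(V_X^2) of the (N-1)-divisor dosage sample variance.

    N0 dosages are drawn i.i.d. from ``dist.p0`` and N1 from ``dist.p1``.
    Works through joint moments of the centred power sums T1 = sum (g - c),
    T2 = sum (g - c)^2, with c the expected overall mean (centring keeps the
    large-N cancellations benign):

        V = (N*T2 - T1^2) / (N*(N-1))
    """
    n = n0 + n1
    if n < 2:
        raise ValueError("need N >= 2 for a sample variance")
    g = np.array([0.0, 1.0, 2.0])
    mu = (n0 * float(dist.p0 @ g) + n1 * float(dist.p1 @ g)) / n
    v = g - mu
    ma = _group_sum_moments(dist.p0, n0, v)
    mb = _group_sum_moments(dist.p1, n1, v)

    e_t2 = ma[(0, 1)] + mb[(0, 1)]
    e_t1sq = ma[(2, 0)] + 2 * ma[(1, 0)] * mb[(1, 0)] + mb[(2, 0)]
    e_t2sq = ma[(0, 2)] + 2 * ma[(0, 1)] * mb[(0, 1)] + mb[(0, 2)]
    e_t2_t1sq = (ma[(2, 1)]
                 + 2 * ma[(1, 1)] * mb[(1, 0)]
                 + ma[(0, 1)] * mb[(2, 0)]
                 + mb[(0, 1)] * ma[(2, 0)]
                 + 2 * mb[(1, 1)] * ma[(1, 0)]
                 + mb[(2, 1)])
    e_t1_4 = sum(comb(4, r) * ma[(r, 0)] * mb[(4 - r, 0)] for r in range(5))

    denom = n * (n - 1)
    ev = (n * e_t2 - e_t1sq) / denom
    ev2 = (n * n * e_t2sq - 2 * n * e_t2_t1sq + e_t1_4) / denom ** 2
    return float(ev), float(ev2)


# ---------------------------------------------------------------------------
# Inverse-gamma model of V_X
# ---------------------------------------------------------------------------

def fit_inverse_gamma(ev: float, ev2: float) -> tuple[float, float]:
    """Method-of-moments inverse-gamma parameters from (E V, E V^2).

    alpha = (2*ev2 - ev^2) / (ev2 - ev^2); beta = ev*ev2 / (ev2 - ev^2).
    """
    if ev <= 0:
        raise DegenerateVarianceError("E(V) must be positive")
    d = ev2 - ev * ev
    if d <= 0:
        raise DegenerateVarianceError(
            "E(V^2) <= E(V)^2: variance of V_X is degenerate")
    alpha = (2 * ev2 - ev * ev) / d
    beta = ev * ev2 / d
    return float(alpha), float(beta)


def expected_inv_sqrt_v(alpha: float, beta: float) -> float:
    """E(V^{-1/2}) for V ~ InverseGamma(alpha, beta), via log-gamma."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return float(np.exp(gammaln(alpha + 0.5) - gammaln(alpha)
                        - 0.5 * np.log(beta)))


# ---------------------------------------------------------------------------
# Region-level expected Z
# ---------------------------------------------------------------------------

def expected_z_region(model: CausalModel, panel: HaplotypePanel,
                      smoothing: float = 0.0) -> ExpectedSummary:
    """Expected summary statistics for every SNP in the panel.

    The per-SNP work enumerates haplotype patterns and causal genotype
    classes only; N0 and N1 enter as scalar factors, so the operation count
    is independent of sample size.
    """
    for s in model.causal_ids:
        panel.index_of(s)  # raise early on unknown causal SNPs
    n0, n1 = model.n0, model.n1
    n = n0 + n1
    vy = phenotype_variance(n0, n1)
    causal_set = set(model.causal_ids)
    pw = joint_genotype_probs(
        haplotype_freq_table(panel, model.causal_ids, smoothing=smoothing))
    enr = solve_enrichment(model, pw)

    n_snps = panel.n_snps
    eu = np.zeros(n_snps)
    ev = np.zeros(n_snps)
    ev2 = np.zeros(n_snps)
    alpha = np.full(n_snps, np.nan)
    beta = np.full(n_snps, np.nan)
    degen = np.zeros(n_snps, dtype=bool)
    ze = np.zeros(n_snps)
    ops = 0

    zscale = np.sqrt(n / (n0 * n1))  # 1 / sqrt((N-1) * vy)
    for j, sid in enumerate(panel.snp_ids):
        subset = (list(model.causal_ids) if sid in causal_set
                  else [sid] + list(model.causal_ids))
        joint = joint_genotype_probs(
            haplotype_freq_table(panel, subset, smoothing=smoothing))
        ops += len(joint.probs)
        eu[j] = expected_u(sid, model, joint, enr)
        dist = group_genotype_dist(sid, model, joint, enr)
        ev[j], ev2[j] = variance_moments(dist, n0, n1)
        try:
            alpha[j], beta[j] = fit_inverse_gamma(ev[j], ev2[j])
            inv_sqrt = expected_inv_sqrt_v(alpha[j], beta[j])
        except DegenerateVarianceError:
            degen[j] = True
            inv_sqrt = 1.0 / np.sqrt(ev[j]) if ev[j] > 0 else 0.0
        ze[j] = eu[j] * inv_sqrt * zscale if eu[j] != 0.0 else 0.0

    return ExpectedSummary(panel.snp_ids.copy(), eu, ev, ev2, alpha, beta,
                           degen, vy, ze, n0, n1, n_enum_ops=ops)


def write_expected_summary(summary: ExpectedSummary, panel: HaplotypePanel,
                           path: str) -> None:
    """Tab-delimited per-SNP expected statistics (snp, pos, ze, alpha, beta, eu)."""
    with open(path, "w") as fh:
        fh.write("snp\tpos\tze\talpha\tbeta\teu\n")
        for j, sid in enumerate(summary.snp_ids):
            fh.write(f"{sid}\t{panel.positions[j]}\t{summary.ze[j]:.10g}\t"
                     f"{summary.alpha[j]:.10g}\t{summary.beta[j]:.10g}\t"
                     f"{summary.eu[j]:.10g}\n")
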