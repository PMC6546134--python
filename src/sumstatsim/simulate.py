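"""Stochastic layer: replicate Z vectors, standard errors, effect sizes.

Z* ~ MVN(Z_E, Sigma) carries the LD structure; per-SNP dosage variances are
drawn V* ~ InverseGamma(alpha, beta), giving sigma* = 1/sqrt((N-1) V* V_Y)
and gamma* = sigma* Z*. P-values are two-sided standard-normal tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .expected import ExpectedSummary
from .panel import CorrelationMatrix

__all__ = ["SimulatedSummary", "simulate_z", "simulate_se", "assemble"]

# fixed offsets deriving per-component streams from one master seed
SEED_OFFSET_Z = 0
SEED_OFFSET_SE = 104729


@dataclass
class SimulatedSummary:
    """Replicate-by-SNP simulated summary statistics."""

    snp_ids: np.ndarray
    z: np.ndarray
    se: np.ndarray
    beta: np.ndarray
    p: np.ndarray
    seed: int
    n_rep: int

    def __post_init__(self) -> None:
        if self.z.shape != self.se.shape:
            raise ValueError("z and se shapes differ")
        if (self.se <= 0).any():
            raise ValueError("standard errors must be positive")


def simulate_z(ze: np.ndarray, sigma: CorrelationMatrix, n_rep: int,
               seed: int) -> np.ndarray:
    """Draw ``n_rep`` independent Z vectors from MVN(ze, sigma)."""
    ze = np.asarray(ze, dtype=float)
    s = sigma.sigma
    if s.shape[0] != ze.shape[0]:
        raise ValueError("dimension mismatch between ze and sigma")
    w, v = np.linalg.eigh(s)
    if w.min() < -1e-8:
        raise ValueError("sigma is not PSD; repair it upstream")
    root = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed + SEED_OFFSET_Z)
    return ze + rng.standard_normal((n_rep, ze.shape[0])) @ root.T


def simulate_se(summary: ExpectedSummary, n_rep: int, seed: int) -> np.ndarray:
    """Draw per-replicate standard errors sigma* = 1/sqrt((N-1) V* V_Y).

    V* is inverse gamma per SNP, independent across SNPs and replicates;
    degenerate SNPs use the constant V = E(V).
    """
    rng = np.random.default_rng(seed + SEED_OFFSET_SE)
    n = summary.n0 + summary.n1
    n_snps = len(summary.snp_ids)
    vstar = np.empty((n_rep, n_snps))
    ok = ~summary.degenerate
    if ok.any():
        # InverseGamma(alpha, beta) == beta / Gamma(alpha, 1)
        draws = rng.standard_gamma(summary.alpha[ok], size=(n_rep, ok.sum()))
        vstar[:, ok] = summary.beta[ok] / draws
    vstar[:, ~ok] = summary.ev[~ok]
    return 1.0 / np.sqrt((n - 1) * vstar * summary.vy)


def assemble(snp_ids: np.ndarray, z: np.ndarray, se: np.ndarray, seed: int,
             ) -> SimulatedSummary:
    """Combine Z and SE draws into effect sizes and p-values."""
    if z.shape != se.shape:
        raise ValueError("z and se shapes differ")
    beta = se * z
    p = 2.0 * stats.norm.sf(np.abs(z))
    return SimulatedSummary(np.asarray(snp_ids), z, se, beta, p,
                            seed=seed, n_rep=z.shape[0])


def simulate_summary(summary: ExpectedSummary, sigma: CorrelationMatrix,
                     n_rep: int, seed: int) -> SimulatedSummary:
    """Convenience wrapper: Z draws + SE draws + assembly with one seed."""
    z = simulate_z(summary.ze, sigma, n_rep, seed)
    se = simulate_se(summary, n_rep, seed)
    return assemble(summary.snp_ids, z, se, seed)
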