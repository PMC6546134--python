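"""Disease model and retrospective case-control conditioning.

Reference haplotype frequencies are treated as control frequencies. Under a
logistic disease model with causal genotype vector w and log odds ratios
gamma, the case genotype distribution is the exponentially tilted control
distribution

    P1(w) = P0(w) * exp(gamma . w) / C,    C = sum_w' P0(w') exp(gamma . w'),

and the sampling intercept satisfies exp(gamma0) = (N1 / N0) / C, which makes
the per-class case/control enrichment factor (N0/N1) * exp(gamma0 + gamma.w)
equal to exp(gamma.w) / C.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .panel import JointGenotypeTable

__all__ = [
    "CausalModel",
    "EnrichmentModel",
    "CaseControlGenotypeDist",
    "solve_enrichment",
    "group_genotype_dist",
    "load_causal_model",
]

MAX_CAUSAL = 12  # enumeration of 3**m causal genotype classes stays exact


@dataclass
class CausalModel:
    """Causal SNP set with per-SNP log odds ratios and the study design."""

    causal_ids: list
    gamma: np.ndarray
    n0: int
    n1: int

    def __post_init__(self) -> None:
        self.causal_ids = list(self.causal_ids)
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        m = len(self.causal_ids)
        if m < 1:
            raise ValueError("need at least one causal SNP")
        if m > MAX_CAUSAL:
            raise ValueError(f"at most {MAX_CAUSAL} causal SNPs supported")
        if len(set(self.causal_ids)) != m:
            raise ValueError("causal SNP ids must be distinct")
        if self.gamma.shape != (m,):
            raise ValueError("gamma length must match causal_ids")
        if not np.isfinite(self.gamma).all():
            raise ValueError("log odds ratios must be finite")
        if self.n0 < 1 or self.n1 < 1:
            raise ValueError("N0 and N1 must be positive")

    @property
    def m(self) -> int:
        return len(self.causal_ids)

    @property
    def n(self) -> int:
        return self.n0 + self.n1


@dataclass
class EnrichmentModel:
    """Solved intercept and per-class case enrichment factors."""

    causal_ids: list
    gamma: np.ndarray
    gamma0: float
    normalizer: float  # C
    w_patterns: np.ndarray  # (K, m) causal genotype vectors with P0 > 0
    p0_w: np.ndarray  # control probabilities of each pattern
    factors: np.ndarray  # exp(gamma . w) / C per pattern

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("enrichment factors must be positive")
        if abs(float(self.p0_w @ self.factors) - 1.0) > 1e-10:
            raise ValueError("enrichment factors must average to 1 under P0")

    def factor(self, w) -> float:
        """exp(gamma . w) / C for an arbitrary causal genotype vector."""
        return float(np.exp(self.gamma @ np.asarray(w, float))
                     / self.normalizer)


@dataclass
class CaseControlGenotypeDist:
    """Genotype distribution over {0,1,2} in controls (p0) and cases (p1)."""

    snp_id: object
    p0: np.ndarray
    p1: np.ndarray

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1):
            if (np.asarray(p) < -1e-12).any() or abs(p.sum() - 1.0) > 1e-10:
                raise ValueError("group genotype distribution invalid")


def solve_enrichment(model: CausalModel,
                     pw: JointGenotypeTable) -> EnrichmentModel:
    """Solve gamma0 so the expected case fraction equals N1/N.

    ``pw`` must be the joint genotype table over exactly the causal subset,
    in the model's SNP order.
    """
    if list(pw.subset) != list(model.causal_ids):
        raise ValueError("joint table must cover exactly the causal SNPs, "
                         f"got {pw.subset!r} for {model.causal_ids!r}")
    w = pw.genotypes.astype(float)
    p0 = pw.probs
    eta = w @ model.gamma
    if np.abs(eta).max() > 500:
        raise OverflowError("gamma . w too large; rescale the odds ratios")
    expeta = np.exp(eta)
    C = float(p0 @ expeta)
    gamma0 = float(np.log(model.n1 / model.n0) - np.log(C))
    factors = expeta / C
    return EnrichmentModel(list(model.causal_ids), model.gamma, gamma0, C,
                           pw.genotypes.copy(), p0.copy(), factors)


def solve_gamma0_numeric(model: CausalModel, pw: JointGenotypeTable,
                         bracket: float = 50.0) -> float:
    """Root-solve the sample-prevalence constraint for gamma0.

    The sample genotype mixture is (N0 * P0 + N1 * P1) / N with P1 the tilted
    case distribution; the root of
    ``sum_w Psam(w) * logistic(gamma0 + gamma.w) - N1/N`` is the intercept.
    Used as an independent cross-check of :func:`solve_enrichment`.
    """
    enr = solve_enrichment(model, pw)
    p1 = enr.p0_w * enr.factors
    psam = (model.n0 * enr.p0_w + model.n1 * p1) / model.n
    eta = pw.genotypes.astype(float) @ model.gamma
    target = model.n1 / model.n

    def f(g0):
        return float(psam @ expit(g0 + eta)) - target

    return float(brentq(f, -bracket, bracket, xtol=1e-13, rtol=1e-14))


def group_genotype_dist(snp_id, model: CausalModel, joint: JointGenotypeTable,
                        enr: EnrichmentModel) -> CaseControlGenotypeDist:
    """Per-group genotype distribution at one SNP.

    ``joint`` covers {snp_id} union W; cases reweight each causal class by
    its enrichment factor.
    """
    expected = set(model.causal_ids) | {snp_id}
    if set(joint.subset) != expected:
        raise ValueError(f"joint table covers {joint.subset!r}, "
                         f"need {sorted(map(str, expected))!r}")
    jx = joint.subset.index(snp_id)
    jw = [joint.subset.index(s) for s in model.causal_ids]
    gx = joint.genotypes[:, jx]
    eta = joint.genotypes[:, jw].astype(float) @ model.gamma
    fac = np.exp(eta) / enr.normalizer
    p0 = np.zeros(3)
    p1 = np.zeros(3)
    np.add.at(p0, gx, joint.probs)
    np.add.at(p1, gx, joint.probs * fac)
    p0 /= p0.sum()
    p1 /= p1.sum()
    return CaseControlGenotypeDist(snp_id, p0, p1)


def load_causal_model(path: str) -> CausalModel:
    """Read a causal-model config (JSON: snp ids, odds ratios, N0, N1).

    Odds ratios are given on the natural scale and converted to logs;
    alternatively ``log_odds_ratios`` may be given directly.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    ids = cfg["causal_snps"]
    if "log_odds_ratios" in cfg:
        gamma = np.asarray(cfg["log_odds_ratios"], dtype=float)
    else:
        gamma = np.log(np.asarray(cfg["odds_ratios"], dtype=float))
    return CausalModel(ids, gamma, int(cfg["n0"]), int(cfg["n1"]))
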