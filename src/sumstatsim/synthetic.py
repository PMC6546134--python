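"""Synthetic reference panels with controlled MAFs and pairwise LD.

Haplotypes are generated by a Gaussian copula: a latent MVN vector with a
Markov (per-link autoregressive) correlation structure is binarized at
per-SNP empirical quantiles, which pins realized allele frequencies while
named-pair latent correlations are calibrated against the bivariate-normal
orthant probability so the binary correlation hits its target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

from .causal import CausalModel
from .panel import HaplotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "PanelSpec",
    "FeasibilityError",
    "binary_r_bounds",
    "calibrate_latent_rho",
    "generate_panel",
    "scenario_panel",
    "SCENARIOS",
]


class FeasibilityError(ValueError):
    """Target binary correlation outside the Frechet bounds for the MAFs."""


def binary_r_bounds(maf_a: float, maf_b: float) -> tuple[float, float]:
    """Frechet bounds on the Pearson correlation of two Bernoulli alleles."""
    pa, pb = maf_a, maf_b
    denom = np.sqrt(pa * (1 - pa) * pb * (1 - pb))
    hi = (min(pa, pb) - pa * pb) / denom
    lo = (max(0.0, pa + pb - 1.0) - pa * pb) / denom
    return float(lo), float(hi)


def _binary_r_from_latent(rho: float, maf_a: float, maf_b: float) -> float:
    """Binary correlation induced by latent Gaussian correlation ``rho``."""
    ta, tb = norm.isf(maf_a), norm.isf(maf_b)
    if rho >= 1.0 - 1e-12:
        p11 = min(maf_a, maf_b)
    elif rho <= -1.0 + 1e-12:
        p11 = max(0.0, maf_a + maf_b - 1.0)
    else:
        # P(Z1 > ta, Z2 > tb) by symmetry of the bivariate normal
        p11 = float(multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([-ta, -tb]))
    denom = np.sqrt(maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    return (p11 - maf_a * maf_b) / denom


def calibrate_latent_rho(target_r: float, maf_a: float, maf_b: float,
                         tol: float = 1e-3) -> float:
    """Latent Gaussian correlation whose binarized Pearson r hits ``target_r``.

    Solved by root finding against the bivariate-normal orthant probability;
    raises :class:`FeasibilityError` when the target violates the Frechet
    bounds for the given allele frequencies.
    """
    lo, hi = binary_r_bounds(maf_a, maf_b)
    if not lo - 1e-9 <= target_r <= hi + 1e-9:
        raise FeasibilityError(
            f"target r={target_r} outside feasible range [{lo:.4f}, {hi:.4f}] "
            f"for MAFs ({maf_a}, {maf_b})")
    if target_r == 0.0:
        return 0.0
    if target_r >= hi - 1e-9:
        return 1.0
    if target_r <= lo + 1e-9:
        return -1.0

    def f(rho):
        return _binary_r_from_latent(rho, maf_a, maf_b) - target_r

    rho = float(brentq(f, -1.0 + 1e-9, 1.0 - 1e-9, xtol=1e-6))
    achieved = _binary_r_from_latent(rho, maf_a, maf_b)
    if abs(achieved - target_r) > tol:
        raise FeasibilityError(
            f"calibration reached r={achieved:.5f} for target {target_r}")
    return rho


@dataclass
class PanelSpec:
    """Recipe for a synthetic panel.

    ``ar_decay`` is the latent correlation between adjacent SNPs (background
    LD decays as ar_decay**distance); ``named_r`` maps SNP index pairs to
    target binary correlations, realized by calibrating the latent links on
    the path between them.
    """

    mafs: np.ndarray
    n_hap: int
    seed: int = 0
    ar_decay: float = 0.9
    named_r: dict = field(default_factory=dict)
    max_retries: int = 50

    def __post_init__(self) -> None:
        self.mafs = np.asarray(self.mafs, dtype=float)
        if ((self.mafs <= 0) | (self.mafs > 0.5)).any():
            raise ValueError("MAFs must lie in (0, 0.5]")
        if not -1 < self.ar_decay < 1:
            raise ValueError("ar_decay must lie in (-1, 1)")
        if self.n_hap < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.n_hap < 100:
            warnings.warn("n_hap < 100: frequency estimates will be noisy",
                          stacklevel=2)
        if round(self.mafs.min() * self.n_hap) < 1:
            raise ValueError("smallest MAF yields zero minor alleles")
        for (a, b), r in self.named_r.items():
            if not (0 <= a < len(self.mafs) and 0 <= b < len(self.mafs)):
                raise ValueError(f"named pair ({a}, {b}) out of range")
            lo, hi = binary_r_bounds(self.mafs[a], self.mafs[b])
            if not lo - 1e-9 <= r <= hi + 1e-9:
                raise FeasibilityError(
                    f"pair ({a}, {b}): target r={r} outside [{lo:.4f}, {hi:.4f}]")


def _latent_correlation(spec: PanelSpec) -> np.ndarray:
    """Markov latent correlation matrix: R[i, j] = prod of links in (i, j]."""
    n = len(spec.mafs)
    links = np.full(max(n - 1, 0), spec.ar_decay)
    for (a, b), r in sorted(spec.named_r.items()):
        a, b = min(a, b), max(a, b)
        rho = calibrate_latent_rho(r, spec.mafs[a], spec.mafs[b])
        span = b - a
        if span == 0:
            continue
        link = (np.sign(rho) * np.abs(rho) ** (1.0 / span)
                if rho != 0 else 0.0)
        links[a:b] = link
    R = np.eye(n)
    for i in range(n - 1):
        R[i, i + 1:] = np.cumprod(links[i:])
    R = np.triu(R) + np.triu(R, 1).T
    return R


def generate_panel(spec: PanelSpec, snp_prefix: str = "s",
                   chrom: str = "1") -> HaplotypePanel:
    """Draw a haplotype panel realizing the recipe.

    Columns are binarized at per-SNP empirical quantiles so realized minor
    allele counts equal ``round(maf * n_hap)`` exactly; named-pair realized
    correlations are checked within +/- 0.05 with bounded regeneration.
    """
    n = len(spec.mafs)
    R = _latent_correlation(spec)
    w, v = np.linalg.eigh(R)
    root = v * np.sqrt(np.clip(w, 0.0, None))
    counts = np.maximum(np.round(spec.mafs * spec.n_hap).astype(int), 1)

    for attempt in range(spec.max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        z = rng.standard_normal((spec.n_hap, n)) @ root.T
        alleles = np.zeros((spec.n_hap, n), dtype=np.int8)
        # rank-threshold: top-k latent values carry the minor allele
        order = np.argsort(-z, axis=0, kind="stable")
        for j in range(n):
            alleles[order[:counts[j], j], j] = 1
        ok = True
        for (a, b), r in spec.named_r.items():
            realized = float(np.corrcoef(alleles[:, a], alleles[:, b])[0, 1])
            if abs(realized - r) > 0.05:
                ok = False
                logger.info("attempt %d: pair (%d,%d) realized r=%.3f "
                            "vs target %.3f; regenerating", attempt, a, b,
                            realized, r)
                break
        if ok:
            break
    else:
        raise RuntimeError("could not realize named-pair correlations "
                           f"within {spec.max_retries} attempts")

    width = len(str(n))
    ids = np.array([f"{snp_prefix}{j:0{width}d}" for j in range(n)],
                   dtype=object)
    positions = np.arange(1, n + 1) * 1000
    labels = np.array([("A", "G")] * n, dtype=object)
    return HaplotypePanel(alleles, ids, positions, labels, chrom=chrom)


# ---------------------------------------------------------------------------
# Validation scenarios
# ---------------------------------------------------------------------------

# five standard validation scenarios: causal MAFs, odds ratios, pairwise r
SCENARIOS = {
    1: {"mafs": [0.5], "ors": [1.1], "r": None},
    2: {"mafs": [0.02], "ors": [1.5], "r": None},
    3: {"mafs": [0.27, 0.37, 0.26], "ors": [1.1, 1.2, 1.3], "r": None},
    4: {"mafs": [0.39, 0.25], "ors": [1.2, 1 / 1.2], "r": 0.15},
    5: {"mafs": [0.1, 0.15], "ors": [1.2, 1 / 1.2], "r": 0.8},
}


def scenario_panel(scenario_id: int, n_hap: int = 600, seed: int = 0,
                   n0: int = 2000, n1: int = 2000, n_snps: int = 1000,
                   ar_decay: float = 0.9, use_r_squared: bool = False,
                   ) -> tuple[HaplotypePanel, CausalModel]:
    """Panel plus causal model for one of the five validation scenarios.

    Causal SNPs are embedded in a background of ``n_snps`` SNPs with
    autoregressive latent LD; linked causal pairs sit adjacent with their
    target correlation, unlinked causal SNPs are spaced 50 SNPs apart.
    ``use_r_squared`` interprets the quoted pairwise value as r^2 rather
    than r. Targets beyond the Frechet bound for the scenario MAFs are
    clamped to the bound with a warning.
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"scenario_id must be in 1..5, got {scenario_id}")
    sc = SCENARIOS[scenario_id]
    m = len(sc["mafs"])
    linked = sc["r"] is not None
    spacing = 1 if linked else 50  # unlinked causals sit 50 SNPs apart
    if n_snps < spacing * (m - 1) + 10:
        raise ValueError("n_snps too small to embed the causal SNPs")

    rng = np.random.default_rng((seed, 9001))
    mafs = rng.uniform(0.05, 0.5, size=n_snps)
    base = (n_snps - spacing * (m - 1)) // 2
    causal_pos = [base + spacing * k for k in range(m)]
    for pos, maf in zip(causal_pos, sc["mafs"]):
        mafs[pos] = maf

    named_r = {}
    if linked:
        target = float(np.sqrt(sc["r"])) if use_r_squared else float(sc["r"])
        _, hi = binary_r_bounds(sc["mafs"][0], sc["mafs"][1])
        if target > hi:
            warnings.warn(
                f"scenario {scenario_id}: target r={target:.3f} exceeds the "
                f"Frechet bound {hi:.4f} for MAFs {tuple(sc['mafs'])}; "
                "clamping to the bound", stacklevel=2)
            target = hi
        named_r[(causal_pos[0], causal_pos[1])] = target

    spec = PanelSpec(mafs=mafs, n_hap=n_hap, seed=seed, ar_decay=ar_decay,
                     named_r=named_r)
    panel = generate_panel(spec)
    causal_ids = [panel.snp_ids[p] for p in causal_pos]
    model = CausalModel(causal_ids, np.log(sc["ors"]), n0=n0, n1=n1)
    return panel, model
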