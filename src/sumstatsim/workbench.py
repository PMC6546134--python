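"""Orchestration: end-to-end runs, validation reports, long-format output."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats

from . import expected as expected_mod
from .causal import CausalModel, load_causal_model, solve_enrichment
from .oracle import cochran_armitage_z, logistic_wald, sample_study
from .panel import HaplotypePanel, genotype_correlation, load_panel
from .simulate import SimulatedSummary, simulate_summary
from .synthetic import scenario_panel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_simulation", "run_oracle", "run_validation",
           "oracle_replicates", "write_long_table"]


@dataclass
class RunConfig:
    """Configuration for an end-to-end run."""

    panel_path: str | None = None
    panel_format: str = "hap_legend"
    causal_config: str | None = None
    scenario: int | None = None
    n_hap: int = 600
    n_snps: int = 1000
    n0: int = 2000
    n1: int = 2000
    n_rep: int = 100
    seed: int = 0
    out_prefix: str | None = None
    oracle: bool = False
    oracle_reps: int = 100
    smoothing: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rep < 1:
            raise ValueError("n_rep must be >= 1")
        if (self.panel_path is None) == (self.scenario is None):
            raise ValueError("exactly one of panel_path / scenario required")
        if self.panel_path is not None and self.causal_config is None:
            raise ValueError("a causal-model config is required with a panel")


def load_inputs(config: RunConfig) -> tuple[HaplotypePanel, CausalModel]:
    if config.scenario is not None:
        return scenario_panel(config.scenario, n_hap=config.n_hap,
                              seed=config.seed, n0=config.n0, n1=config.n1,
                              n_snps=config.n_snps)
    panel = load_panel(config.panel_path, format=config.panel_format)
    model = load_causal_model(config.causal_config)
    if (model.n0, model.n1) != (config.n0, config.n1):
        model = CausalModel(model.causal_ids, model.gamma,
                            n0=config.n0, n1=config.n1)
    return panel, model


def run_simulation(config: RunConfig):
    """Panel -> expected statistics -> replicate summary statistics.

    Returns ``(sim, expected, metadata)``; writes the long-format table and a
    JSON sidecar when ``config.out_prefix`` is set.
    """
    t0 = time.perf_counter()
    panel, model = load_inputs(config)
    t_load = time.perf_counter()
    expected = expected_mod.expected_z_region(model, panel,
                                              smoothing=config.smoothing)
    sigma = genotype_correlation(panel)
    t_exp = time.perf_counter()
    sim = simulate_summary(expected, sigma, config.n_rep, config.seed)
    t_sim = time.perf_counter()

    metadata = {
        "config": asdict(config),
        "seed": config.seed,
        "n_rep": config.n_rep,
        "causal_snps": [str(s) for s in model.causal_ids],
        "log_odds_ratios": list(map(float, model.gamma)),
        "stage_calls": {"expected_stats": 1, "simulate": 1},
        "n_enum_ops": expected.n_enum_ops,
        "timings_s": {"load": t_load - t0, "expected_stats": t_exp - t_load,
                      "simulate": t_sim - t_exp},
    }
    if config.out_prefix:
        write_long_table(config.out_prefix + ".tsv", panel, sim)
        with open(config.out_prefix + ".json", "w") as fh:
            json.dump(metadata, fh, indent=2)
    return sim, expected, metadata


def write_long_table(path: str, panel: HaplotypePanel,
                     sim: SimulatedSummary) -> None:
    """One row per replicate x SNP: summary-statistic interchange format."""
    n_rep, n_snps = sim.z.shape
    rep = np.repeat(np.arange(n_rep), n_snps)
    snp = np.tile(sim.snp_ids, n_rep)
    df = pd.DataFrame({
        "replicate": rep,
        "snp": snp,
        "chr": panel.chrom,
        "pos": np.tile(panel.positions, n_rep),
        "a0": np.tile(panel.allele_labels[:, 0], n_rep),
        "a1": np.tile(panel.allele_labels[:, 1], n_rep),
        "beta": sim.beta.ravel(),
        "se": sim.se.ravel(),
        "z": sim.z.ravel(),
        "p": sim.p.ravel(),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def oracle_replicates(panel: HaplotypePanel, model: CausalModel, n_rep: int,
                      seed: int, snp_subset=None) -> dict:
    """Forward-simulate ``n_rep`` studies and analyze each.

    Returns replicate-by-SNP arrays of score Z, logistic beta and SE for the
    requested SNPs (default: all panel SNPs).
    """
    from .panel import haplotype_freq_table, joint_genotype_probs

    pw = joint_genotype_probs(haplotype_freq_table(panel, model.causal_ids))
    enr = solve_enrichment(model, pw)
    ids = panel.snp_ids if snp_subset is None else np.asarray(snp_subset,
                                                             dtype=object)
    k = len(ids)
    z = np.full((n_rep, k), np.nan)
    beta = np.full((n_rep, k), np.nan)
    se = np.full((n_rep, k), np.nan)
    ss = np.random.SeedSequence((seed, 27182))
    child_seeds = ss.generate_state(n_rep)
    for r in range(n_rep):
        study = sample_study(panel, model, enr, int(child_seeds[r]),
                             snp_subset=ids)
        sc = cochran_armitage_z(study)
        wald = logistic_wald(study)
        z[r] = sc.z
        beta[r] = wald.beta
        se[r] = wald.se
    return {"snp_ids": ids, "z": z, "beta": beta, "se": se}


def run_oracle(config: RunConfig):
    """Forward-simulation path emitting the same long-table schema."""
    panel, model = load_inputs(config)
    res = oracle_replicates(panel, model, config.n_rep, config.seed)
    n_rep, n_snps = res["z"].shape
    p = 2.0 * stats.norm.sf(np.abs(res["z"]))
    df = pd.DataFrame({
        "replicate": np.repeat(np.arange(n_rep), n_snps),
        "snp": np.tile(res["snp_ids"], n_rep),
        "chr": panel.chrom,
        "pos": np.tile(panel.positions, n_rep),
        "a0": np.tile(panel.allele_labels[:, 0], n_rep),
        "a1": np.tile(panel.allele_labels[:, 1], n_rep),
        "beta": res["beta"].ravel(),
        "se": res["se"].ravel(),
        "z": res["z"].ravel(),
        "p": p.ravel(),
    })
    if config.out_prefix:
        df.to_csv(config.out_prefix + ".oracle.tsv", sep="\t", index=False,
                  float_format="%.10g")
    return df, res


def run_validation(config: RunConfig, make_plots: bool = False) -> dict:
    """Side-by-side comparison of the direct simulator and the oracle.

    Per causal SNP: means/SDs of Z and beta for both paths, two-sample KS
    statistics, and QQ data; plus regional median / IQR of -log10 p from the
    direct path.
    """
    if not config.oracle:
        raise ValueError("run_validation requires oracle=True")
    if config.oracle_reps < 100:
        logger.warning("oracle_reps < 100: comparison will be noisy")
    panel, model = load_inputs(config)
    expected = expected_mod.expected_z_region(model, panel,
                                              smoothing=config.smoothing)
    sigma = genotype_correlation(panel)
    sim = simulate_summary(expected, sigma, config.n_rep, config.seed)
    orc = oracle_replicates(panel, model, config.oracle_reps, config.seed,
                            snp_subset=model.causal_ids)

    mlog10p = -np.log10(np.clip(sim.p, 1e-300, None))
    regional = pd.DataFrame({
        "snp": sim.snp_ids,
        "pos": panel.positions,
        "median_mlog10p": np.median(mlog10p, axis=0),
        "q25_mlog10p": np.percentile(mlog10p, 25, axis=0),
        "q75_mlog10p": np.percentile(mlog10p, 75, axis=0),
    })

    per_snp = []
    sim_idx = {s: j for j, s in enumerate(sim.snp_ids)}
    for k, sid in enumerate(orc["snp_ids"]):
        j = sim_idx[sid]
        zs, zo = sim.z[:, j], orc["z"][:, k]
        bs, bo = sim.beta[:, j], orc["beta"][:, k]
        zo, bo = zo[np.isfinite(zo)], bo[np.isfinite(bo)]
        ks_z = stats.ks_2samp(zs, zo)
        ks_b = stats.ks_2samp(bs, bo)
        per_snp.append({
            "snp": str(sid),
            "ze": float(expected.ze[j]),
            "sim_mean_z": float(zs.mean()), "sim_sd_z": float(zs.std(ddof=1)),
            "oracle_mean_z": float(zo.mean()),
            "oracle_sd_z": float(zo.std(ddof=1)),
            "sim_mean_beta": float(bs.mean()),
            "sim_sd_beta": float(bs.std(ddof=1)),
            "oracle_mean_beta": float(bo.mean()),
            "oracle_sd_beta": float(bo.std(ddof=1)),
            "ks_z_stat": float(ks_z.statistic), "ks_z_p": float(ks_z.pvalue),
            "ks_beta_stat": float(ks_b.statistic),
            "ks_beta_p": float(ks_b.pvalue),
            "qq_sim_beta": np.sort(bs).tolist(),
            "qq_oracle_beta": np.sort(bo).tolist(),
        })

    report = {
        "config": asdict(config),
        "seed": config.seed,
        "causal": per_snp,
        "regional": regional.to_dict(orient="list"),
    }
    if config.out_prefix:
        slim = {**report,
                "causal": [{k: v for k, v in d.items()
                            if not k.startswith("qq_")} for d in per_snp]}
        with open(config.out_prefix + ".validation.json", "w") as fh:
            json.dump(slim, fh, indent=2)
        regional.to_csv(config.out_prefix + ".regional.tsv", sep="\t",
                        index=False)
        if make_plots:
            _plot_validation(report, config.out_prefix)
    return report


def _plot_validation(report: dict, prefix: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    reg = report["regional"]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.errorbar(reg["pos"], reg["median_mlog10p"],
                yerr=[np.array(reg["median_mlog10p"]) - np.array(reg["q25_mlog10p"]),
                      np.array(reg["q75_mlog10p"]) - np.array(reg["median_mlog10p"])],
                fmt=".", ms=3, lw=0.5)
    ax.set_xlabel("position")
    ax.set_ylabel("median -log10 p (IQR)")
    fig.tight_layout()
    fig.savefig(prefix + ".regional.png", dpi=120)
    plt.close(fig)

    ncaus = len(report["causal"])
    fig, axes = plt.subplots(1, ncaus, figsize=(3 * ncaus, 3), squeeze=False)
    for ax, d in zip(axes[0], report["causal"]):
        qs, qo = d["qq_sim_beta"], d["qq_oracle_beta"]
        qgrid = np.linspace(0.01, 0.99, 99)
        ax.plot(np.quantile(qs, qgrid), np.quantile(qo, qgrid), ".")
        lim = [min(min(qs), min(qo)), max(max(qs), max(qo))]
        ax.plot(lim, lim, "k--", lw=0.5)
        ax.set_title(f"{d['snp']} KS p={d['ks_beta_p']:.2g}")
        ax.set_xlabel("sim beta")
        ax.set_ylabel("oracle beta")
    fig.tight_layout()
    fig.savefig(prefix + ".qq.png", dpi=120)
    plt.close(fig)
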