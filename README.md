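# sumstatsim

Direct simulation of case–control GWAS summary statistics (Z scores, log
odds ratios, standard errors, p-values) for a genomic region, computed
straight from reference haplotype frequencies and a specified multi-SNP
causal model — no individual-level genotype data is ever generated on the
fast path.

Given phased reference haplotypes (treated as control frequencies) and a
causal model (causal SNPs, odds ratios, N0 controls, N1 cases), the package:

1. enumerates the exact expected score-test numerator E(U_X) per SNP from
   the joint genotype probabilities of {X} ∪ causal set under random union
   of gametes;
2. computes the exact first two moments of the dosage sample variance V_X
   under the tilted case / control genotype distributions and fits an
   inverse-gamma model by method of moments;
3. forms the expected Z score Z_E = E(U_X)·E(V_X^{-1/2})/√((N−1)·V_Y);
4. draws replicate Z* ~ MVN(Z_E, Σ) with Σ the panel genotype correlation
   matrix, draws V* per SNP, and back-calculates σ* = 1/√((N−1)·V*·V_Y)
   and γ* = σ*·Z*.

The cost of steps 1–3 is independent of sample size. An individual-level
forward simulator (rejection sampling of cases from the exponentially
tilted haplotype-pair law, Cochran–Armitage trend test, per-SNP logistic
Wald fits) is included as the gold-standard validation path, together with
a synthetic-panel generator (Gaussian-copula haplotypes with controlled
MAFs and pairwise LD) so everything runs without external reference data.

## Package layout

| module | contents |
| --- | --- |
| `sumstatsim.panel` | `.hap`/`.legend` + phased-VCF I/O, haplotype frequency tables, joint genotype probabilities, genotype correlation with PSD repair |
| `sumstatsim.causal` | causal model, γ0 solve, case/control genotype distributions |
| `sumstatsim.expected` | E(U_X), exact V_X moments, inverse-gamma fit, expected Z per region |
| `sumstatsim.simulate` | MVN Z draws, SE draws, assembly into β/SE/Z/p replicates |
| `sumstatsim.oracle` | forward study sampler, trend-test Z, logistic Wald |
| `sumstatsim.synthetic` | copula panel generator, latent-correlation calibration, the five built-in validation scenarios |
| `sumstatsim.workbench` | end-to-end runs, validation reports, CLI plumbing |

## CLI

```sh
# simulate from a built-in validation scenario (synthetic panel)
sumstatsim simulate --scenario 4 --n0 5000 --n1 5000 --nrep 1000 \
    --seed 1 --out scenario4

# or from your own reference panel + causal model config
sumstatsim simulate --hap region --causals model.json \
    --n0 2000 --n1 2000 --nrep 100 --seed 1 --out run

# gold-standard forward simulation with the same output schema
sumstatsim oracle --scenario 4 --nrep 100 --seed 1 --out run

# side-by-side comparison report (means/SDs, KS tests, QQ + regional data)
sumstatsim validate --scenario 4 --nrep 1000 --oracle-reps 500 \
    --seed 1 --out val --plots

# write a synthetic .hap/.legend panel
sumstatsim make-panel --scenario 5 --out panel5
```

`model.json` looks like:

```json
{"causal_snps": ["rs123", "rs456"], "odds_ratios": [1.2, 0.8333],
 "n0": 2000, "n1": 2000}
```

Outputs are long-format TSV (`replicate, snp, chr, pos, a0, a1, beta, se,
z, p`) plus a JSON sidecar carrying the full config and seed, so any run is
reproducible bit-for-bit.

## Notes

- Scenario 5 quotes r = 0.8 between causal SNPs with MAFs 0.1 and 0.15;
  the Fréchet upper bound for binary variables with those margins is
  ≈ 0.7935, so the generator clamps to the bound (with a warning) and the
  realized correlation is ~0.79.
- Monomorphic SNPs are dropped at load time (their trend-test variance is
  zero); multi-allelic and missing-genotype records are dropped with a
  logged warning; unphased VCF genotypes are an error.
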