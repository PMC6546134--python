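"""Reference haplotype panels: I/O, frequency tables, genotype probabilities, LD.

A panel is a binary matrix of phased haplotypes (rows) by SNPs (columns).
All downstream quantities -- control genotype distributions, joint genotype
probabilities under random union of gametes, and the Z-score correlation
matrix -- are derived from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HaplotypePanel",
    "HaplotypeFreqTable",
    "JointGenotypeTable",
    "CorrelationMatrix",
    "load_panel",
    "write_hap_legend",
    "haplotype_freq_table",
    "joint_genotype_probs",
    "genotype_correlation",
    "nearest_psd_correlation",
]


class PanelFormatError(ValueError):
    """Raised for malformed or unphased input records."""


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with per-SNP metadata.

    Attributes
    ----------
    alleles : ndarray of shape (H, n), dtype int8
        0 = first (.legend a0 / VCF REF) allele, 1 = second (a1 / ALT) allele.
    snp_ids : ndarray of str
    positions : ndarray of int
        1-based base-pair positions, nondecreasing.
    allele_labels : ndarray of shape (n, 2), dtype str
        (a0, a1) per SNP; allele dosage counts the a1 allele.
    chrom : str
    """

    alleles: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    allele_labels: np.ndarray
    chrom: str = "1"

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.allele_labels = np.asarray(self.allele_labels, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        H, n = self.alleles.shape
        if H < 2:
            raise ValueError("panel needs at least 2 haplotypes")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype matrix must be strictly binary")
        if len(self.snp_ids) != n or len(self.positions) != n:
            raise ValueError("metadata length does not match SNP count")
        if len(set(self.snp_ids)) != n:
            raise ValueError("snp_ids must be unique")
        if n > 1 and np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be nondecreasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    def index_of(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if idx.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(idx[0])

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the counted (a1) allele per SNP."""
        return self.alleles.mean(axis=0)

    def drop_monomorphic(self) -> "HaplotypePanel":
        f = self.allele_freqs()
        keep = (f > 0) & (f < 1)
        if not keep.all():
            dropped = [str(s) for s in self.snp_ids[~keep]]
            logger.warning("dropping %d monomorphic SNP(s): %s",
                           len(dropped), ", ".join(dropped[:10]))
        return HaplotypePanel(self.alleles[:, keep], self.snp_ids[keep],
                              self.positions[keep], self.allele_labels[keep],
                              chrom=self.chrom)


@dataclass
class HaplotypeFreqTable:
    """Relative frequencies of distinct haplotype patterns over a SNP subset."""

    subset: list
    patterns: np.ndarray  # (K, len(subset)) binary
    freqs: np.ndarray  # (K,) nonnegative, sums to 1

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=np.int8)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if (self.freqs < 0).any():
            raise ValueError("negative frequency")
        if abs(self.freqs.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")
        if len(np.unique(self.patterns, axis=0)) != len(self.patterns):
            raise ValueError("patterns must be distinct")

    def as_dict(self) -> dict:
        return {tuple(int(a) for a in p): float(f)
                for p, f in zip(self.patterns, self.freqs)}


@dataclass
class JointGenotypeTable:
    """Joint genotype probabilities over a SNP subset under random pairing."""

    subset: list
    genotypes: np.ndarray  # (K, len(subset)) entries in {0,1,2}
    probs: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.probs = np.asarray(self.probs, dtype=float)
        if abs(self.probs.sum() - 1.0) > 1e-10:
            raise ValueError("joint genotype probabilities must sum to 1")

    def marginal(self, snp_id) -> np.ndarray:
        """Genotype distribution over {0,1,2} for one SNP of the subset."""
        j = self.subset.index(snp_id)
        out = np.zeros(3)
        np.add.at(out, self.genotypes[:, j], self.probs)
        return out


@dataclass
class CorrelationMatrix:
    """SNP-by-SNP genotype correlation matrix, PSD after repair."""

    sigma: np.ndarray
    snp_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        s = self.sigma
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError("sigma must be square")
        if not np.allclose(s, s.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(s), 1.0, atol=1e-10):
            raise ValueError("sigma must have unit diagonal")
        if np.abs(s).max() > 1 + 1e-10:
            raise ValueError("correlations must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_panel(path: str, format: str = "hap_legend",
               chrom: str | None = None) -> HaplotypePanel:
    """Load a phased reference panel.

    Parameters
    ----------
    path : str
        For ``hap_legend``: common prefix of ``<path>.hap`` / ``<path>.legend``
        (or the path of either file). For ``vcf``: a VCF file path.
    format : {"hap_legend", "vcf"}

    Multi-allelic and missing-genotype records are dropped with a logged
    warning; monomorphic SNPs are dropped because their score statistic is
    undefined. Unphased VCF genotypes raise :class:`PanelFormatError`.
    """
    if format == "hap_legend":
        panel = _load_hap_legend(path, chrom=chrom or "1")
    elif format == "vcf":
        panel = _load_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    return panel.drop_monomorphic()


def _strip_suffix(path: str) -> str:
    for suf in (".hap", ".legend"):
        if path.endswith(suf):
            return path[: -len(suf)]
    return path


def _load_hap_legend(prefix: str, chrom: str = "1") -> HaplotypePanel:
    prefix = _strip_suffix(prefix)
    hap_path, leg_path = prefix + ".hap", prefix + ".legend"
    ids, pos, labels = [], [], []
    with open(leg_path) as fh:
        header = fh.readline().split()
        if header[:4] != ["id", "position", "a0", "a1"]:
            raise PanelFormatError(
                f"{leg_path}: expected header 'id position a0 a1', got {header!r}")
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            ids.append(tok[0])
            pos.append(int(tok[1]))
            labels.append((tok[2], tok[3]))
    try:
        mat = np.loadtxt(hap_path, dtype=np.int8, ndmin=2)
    except ValueError as exc:
        raise PanelFormatError(f"{hap_path}: non-binary entry ({exc})") from exc
    if mat.shape[0] != len(ids):
        raise PanelFormatError(
            f"{hap_path}: {mat.shape[0]} rows but {len(ids)} legend records")
    # .hap stores SNPs as rows, haplotypes as columns
    return HaplotypePanel(mat.T, np.array(ids, dtype=object),
                          np.array(pos), np.array(labels, dtype=object),
                          chrom=chrom)


def _load_vcf(path: str) -> HaplotypePanel:
    from cyvcf2 import VCF

    vcf = VCF(path)
    cols, ids, pos, labels = [], [], [], []
    chrom = "1"
    for rec in vcf:
        chrom = rec.CHROM
        if len(rec.ALT) != 1:
            logger.warning("dropping multi-allelic record %s at %s:%d",
                           rec.ID, rec.CHROM, rec.POS)
            continue
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        hap = []
        bad = False
        for g in gts:
            *alleles, phased = g
            if any(a < 0 for a in alleles):
                logger.warning("dropping record %s with missing genotype", rec.ID)
                bad = True
                break
            if len(alleles) > 1 and not phased:
                raise PanelFormatError(
                    f"unphased genotype at {rec.CHROM}:{rec.POS} ({rec.ID})")
            hap.extend(alleles)
        if bad:
            continue
        cols.append(hap)
        ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        pos.append(rec.POS)
        labels.append((rec.REF, rec.ALT[0]))
    if not cols:
        raise PanelFormatError(f"{path}: no usable biallelic phased records")
    mat = np.array(cols, dtype=np.int8).T
    return HaplotypePanel(mat, np.array(ids, dtype=object), np.array(pos),
                          np.array(labels, dtype=object), chrom=chrom)


def write_hap_legend(panel: HaplotypePanel, prefix: str) -> None:
    """Write IMPUTE2-style ``<prefix>.hap`` / ``<prefix>.legend`` files."""
    with open(prefix + ".legend", "w") as fh:
        fh.write("id position a0 a1\n")
        for sid, p, (a0, a1) in zip(panel.snp_ids, panel.positions,
                                    panel.allele_labels):
            fh.write(f"{sid} {p} {a0} {a1}\n")
    np.savetxt(prefix + ".hap", panel.alleles.T, fmt="%d", delimiter=" ")


# ---------------------------------------------------------------------------
# Frequencies and probabilities
# ---------------------------------------------------------------------------

def haplotype_freq_table(panel: HaplotypePanel, subset,
                         smoothing: float = 0.0) -> HaplotypeFreqTable:
    """Empirical haplotype-pattern frequencies over a subset of SNPs.

    With ``smoothing`` lambda > 0, Laplace smoothing assigns
    ``(count + lambda) / (H + lambda * 2**k)`` over all ``2**k`` patterns.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    idx = [panel.index_of(s) for s in subset]
    sub = panel.alleles[:, idx]
    H = sub.shape[0]
    if smoothing > 0:
        k = len(subset)
        if k > 20:
            raise ValueError("smoothing enumerates 2**k patterns; k too large")
        codes = sub @ (1 << np.arange(k - 1, -1, -1)).astype(np.int64)
        counts = np.bincount(codes, minlength=1 << k).astype(float)
        patterns = ((np.arange(1 << k)[:, None] >> np.arange(k - 1, -1, -1)) & 1)
        freqs = (counts + smoothing) / (H + smoothing * (1 << k))
    else:
        patterns, counts = np.unique(sub, axis=0, return_counts=True)
        freqs = counts / H
    return HaplotypeFreqTable(subset, patterns.astype(np.int8), freqs)


def joint_genotype_probs(freqs: HaplotypeFreqTable) -> JointGenotypeTable:
    """Genotype probabilities under Hardy-Weinberg random union of gametes.

    ``P(G = g) = sum over ordered haplotype pairs (h1, h2), h1 + h2 = g,
    of f(h1) * f(h2)``.
    """
    pat = freqs.patterns.astype(np.int64)
    f = freqs.freqs
    K, k = pat.shape
    if k > 14:
        raise ValueError("joint genotype enumeration limited to 14 SNPs")
    # encode genotype vectors base-3 and accumulate over all ordered pairs
    weights = np.power(3, np.arange(k - 1, -1, -1), dtype=np.int64)
    codes = (pat[:, None, :] + pat[None, :, :]) @ weights
    probs = np.bincount(codes.ravel(), weights=np.outer(f, f).ravel(),
                        minlength=3 ** k)
    nz = np.flatnonzero(probs)
    genos = (nz[:, None] // weights) % 3
    return JointGenotypeTable(list(freqs.subset), genos.astype(np.int8),
                              probs[nz] / probs.sum())


def genotype_correlation(panel: HaplotypePanel,
                         clip: float = 1e-8) -> CorrelationMatrix:
    """Genotype correlation matrix estimated from haplotype allele indicators.

    Under random union of gametes the genotype correlation equals the
    haplotype-allele correlation, so Sigma is the Pearson correlation of
    panel columns, followed by PSD repair (eigenvalue clipping at ``clip``
    and rescaling to unit diagonal).
    """
    A = panel.alleles.astype(float)
    f = A.mean(axis=0)
    if np.any((f <= 0) | (f >= 1)):
        bad = panel.snp_ids[(f <= 0) | (f >= 1)]
        raise ValueError(f"monomorphic SNP(s) in correlation input: {list(bad)}")
    sigma = np.corrcoef(A, rowvar=False)
    sigma = np.atleast_2d(sigma)
    sigma = nearest_psd_correlation(sigma, clip=clip)
    return CorrelationMatrix(sigma, panel.snp_ids)


def nearest_psd_correlation(sigma: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Clip eigenvalues at ``clip`` and rescale to a unit-diagonal matrix."""
    sigma = (sigma + sigma.T) / 2
    w, v = np.linalg.eigh(sigma)
    if w.min() >= clip:
        out = sigma.copy()
    else:
        w = np.clip(w, clip, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
    np.fill_diagonal(out, 1.0)
    return np.clip(out, -1.0, 1.0)
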