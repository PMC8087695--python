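"""Allele-level expression: TPM, imbalance testing, and tissue clustering.

Quantification uses transcripts-per-million within each tissue library over
the combined allelic transcript set. Allelic imbalance is an exact two-sided
binomial test of the A-allele count against a length-corrected null
p0 = len_A / (len_A + len_B), with Benjamini-Hochberg correction across
pairs within each tissue. Sample relationships are summarized by Pearson
correlation of log2(TPM+1) profiles over allele-pair rows and average-linkage
hierarchical clustering at distance 1 - r.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import binomtest


@dataclass
class ASEResult:
    pair_id: str
    tissue: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    p_value: float
    fdr: float = float("nan")
    direction: str = "balanced"  # "A" | "B" | "balanced"


def tpm(counts: pd.DataFrame, eff_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million per sample column.

    rate_g = count_g / eff_length_g; TPM_g = rate_g / sum(rates) * 1e6.
    Raises if a sample has no mapped reads (TPM undefined).
    """
    lens = eff_lengths.reindex(counts.index)
    if lens.isna().any():
        missing = list(lens.index[lens.isna()])[:3]
        raise ValueError(f"missing effective length for genes {missing}")
    if (lens <= 0).any():
        raise ValueError("effective lengths must be positive")
    rates = counts.div(lens, axis=0)
    sums = rates.sum(axis=0)
    dead = sums[sums == 0]
    if len(dead):
        raise ValueError(f"all-zero sample(s) {list(dead.index)}: TPM undefined")
    return rates.div(sums, axis=1) * 1e6


def highly_expressed(tpm_matrix: pd.DataFrame, threshold: float = 10.0) -> set[str]:
    """Genes with TPM strictly above threshold in at least one sample."""
    if tpm_matrix.empty:
        return set()
    mask = (tpm_matrix > threshold).any(axis=1)
    return set(tpm_matrix.index[mask])


def ase_test(count_a: int, count_b: int, len_a: float, len_b: float) -> Optional[float]:
    """Exact two-sided binomial p-value for allelic imbalance.

    Null: count_a ~ Binomial(count_a + count_b, len_a / (len_a + len_b)).
    Returns None when both counts are zero (no information).
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    n = count_a + count_b
    if n == 0:
        return None
    p0 = len_a / (len_a + len_b)
    return float(binomtest(count_a, n, p0, alternative="two-sided").pvalue)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def ase_table(counts: pd.DataFrame, eff_lengths: pd.Series,
              pairs: list[tuple[str, str, str]], alpha: float = 0.05
              ) -> list[ASEResult]:
    """Allelic-imbalance tests for (pair_id, geneA, geneB) over all tissues.

    BH correction is applied across pairs within each tissue; direction is
    assigned at fdr < alpha (A when the A allele is over-represented).
    Pairs with zero total count in a tissue are excluded from the BH
    denominator and reported with p = NaN.
    """
    tpms = tpm(counts, eff_lengths)
    p0_of = {pid: float(eff_lengths[ga] / (eff_lengths[ga] + eff_lengths[gb]))
             for pid, ga, gb in pairs}
    results: list[ASEResult] = []
    for tissue in counts.columns:
        tested: list[ASEResult] = []
        for pair_id, ga, gb in pairs:
            ca = int(counts.at[ga, tissue])
            cb = int(counts.at[gb, tissue])
            p = ase_test(ca, cb, float(eff_lengths[ga]), float(eff_lengths[gb]))
            res = ASEResult(pair_id, tissue, ca, cb,
                            float(tpms.at[ga, tissue]), float(tpms.at[gb, tissue]),
                            p if p is not None else float("nan"))
            results.append(res)
            if p is not None:
                tested.append(res)
        if tested:
            fdrs = _bh_adjust(np.array([r.p_value for r in tested]))
            for r, f in zip(tested, fdrs):
                r.fdr = float(f)
                if f < alpha:
                    expected_a = p0_of[r.pair_id] * (r.count_a + r.count_b)
                    r.direction = "A" if r.count_a > expected_a else "B"
    return results


def sample_matrix(tpms: pd.DataFrame, pairs: list[tuple[str, str, str]],
                  ) -> pd.DataFrame:
    """Pair-by-sample TPM matrix: one column per (tissue, haplotype side)."""
    cols = {}
    for tissue in tpms.columns:
        cols[f"{tissue}_A"] = [float(tpms.at[ga, tissue]) for _, ga, _ in pairs]
        cols[f"{tissue}_B"] = [float(tpms.at[gb, tissue]) for _, _, gb in pairs]
    return pd.DataFrame(cols, index=[pid for pid, _, _ in pairs])


def sample_correlation_cluster(pair_tpms: pd.DataFrame
                               ) -> tuple[pd.DataFrame, np.ndarray]:
    """Pearson correlation of log2(TPM+1) samples + average-linkage dendrogram.

    Returns (correlation matrix, scipy linkage matrix). Raises if any sample
    vector is constant (correlation undefined).
    """
    if pair_tpms.shape[1] < 2:
        raise ValueError("need at least two samples to cluster")
    X = np.log2(pair_tpms.to_numpy(dtype=float) + 1.0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = list(pair_tpms.columns[sd == 0])
        raise ValueError(f"constant sample vector(s) {bad}: correlation undefined")
    corr = np.corrcoef(X, rowvar=False)
    corr_df = pd.DataFrame(corr, index=pair_tpms.columns, columns=pair_tpms.columns)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method="average")
    return corr_df, Z


def first_merges_tissue_pure(Z: np.ndarray, sample_names: list[str],
                             n_tissues: int) -> bool:
    """True if the first n_tissues merges each join one tissue's A/B samples."""
    n = len(sample_names)
    for i in range(min(n_tissues, len(Z))):
        a, b = int(Z[i, 0]), int(Z[i, 1])
        if a >= n or b >= n:
            return False
        ta = sample_names[a].rsplit("_", 1)[0]
        tb = sample_names[b].rsplit("_", 1)[0]
        if ta != tb:
            return False
    return True
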