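"""Count normalization, DEG calling, and expression/intron association tests.

Normalization follows the median-of-ratios scheme: per-sample size factor =
median over genes of count / geometric mean across samples, computed on genes
with no zero count. DEGs are called at |log2FC| >= 1, BH-FDR <= 0.05, with an
abundance gate of normalized counts > 10 in at least three replicates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEG_MIN_ABS_LOG2FC = 1.0
DEG_FDR_ALPHA = 0.05
DEG_MIN_NORMALIZED = 10.0
DEG_MIN_REPLICATES = 3


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample (genes x samples input).

    The pseudo-reference is the geometric mean of the library-scaled (per
    million) profiles over genes with no zero count, so the factors are
    exactly invariant to rescaling any single library: normalized output is
    on a counts-per-million-like scale.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("negative counts")
    totals = raw.sum(axis=0)
    if not (totals > 0).all():
        raise ValueError("all-zero sample in count matrix")
    cpm = raw.div(totals, axis=1) * 1e6
    positive = (raw > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has nonzero counts in every sample")
    log_ref = np.log(cpm[positive]).mean(axis=1)
    ratios = np.log(raw[positive]).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def normalize_counts(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its median-of-ratios size factor."""
    if raw.shape[1] < 2:
        raise ValueError("need at least two samples to normalize")
    return raw / size_factors(raw)


def call_degs(
    normalized: pd.DataFrame,
    samples_a: list[str],
    samples_b: list[str],
    min_abs_log2fc: float = DEG_MIN_ABS_LOG2FC,
    fdr_alpha: float = DEG_FDR_ALPHA,
) -> pd.DataFrame:
    """Welch's t-test DEG caller on log2(normalized + 1).

    log2_fc is mean(A) - mean(B) on the log scale with a pseudocount of 1.
    The abundance gate requires normalized counts > 10 in at least three
    replicates (any sample of the contrast).
    """
    missing = [s for s in samples_a + samples_b if s not in normalized.columns]
    if missing:
        raise ValueError(f"samples absent from matrix: {missing}")
    if len(samples_a) < DEG_MIN_REPLICATES or len(samples_b) < DEG_MIN_REPLICATES:
        raise ValueError("need >=3 replicates per group")
    a = np.log2(normalized[samples_a] + 1.0)
    b = np.log2(normalized[samples_b] + 1.0)
    log2_fc = a.mean(axis=1) - b.mean(axis=1)
    tstat, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    both = normalized[samples_a + samples_b]
    passes_abundance = (both > DEG_MIN_NORMALIZED).sum(axis=1) >= DEG_MIN_REPLICATES
    out = pd.DataFrame(
        {
            "gene_id": normalized.index,
            "log2_fc": log2_fc.to_numpy(),
            "p_value": pvals,
            "fdr": fdr,
            "passes_abundance": passes_abundance.to_numpy(),
        }
    )
    out["is_deg"] = (
        (out["log2_fc"].abs() >= min_abs_log2fc)
        & (out["fdr"] <= fdr_alpha)
        & out["passes_abundance"]
    )
    return out


def pool_degs(per_timepoint: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of DEGs over timepoints (deduplicated by gene, largest |log2FC| kept)."""
    frames = [df[df["is_deg"]] for df in per_timepoint if not df.empty]
    if not frames:
        return pd.DataFrame(columns=["gene_id", "log2_fc", "fdr"])
    allhits = pd.concat(frames, ignore_index=True)
    allhits["abs_fc"] = allhits["log2_fc"].abs()
    return (
        allhits.sort_values("abs_fc", ascending=False)
        .drop_duplicates("gene_id")
        .drop(columns="abs_fc")
        .sort_values("gene_id")
        .reset_index(drop=True)
    )


def expression_intron_association(
    gene_expression: pd.Series,
    gene_features: pd.DataFrame,
    intron_psi: pd.Series | None = None,
    intron_to_gene: dict[str, str] | None = None,
) -> dict:
    """Association tests between expression and intron architecture.

    ``gene_expression``: mean expression per gene (log scale recommended).
    ``gene_features``: per-gene table with n_introns and first_intron_group
    ("5p"/"middle"/"3p"/"intronless") columns.
    ``intron_psi``: optional mean PSI per intron, correlated against the host
    gene's expression (Pearson).

    Returns Spearman trend of expression on intron number, Mann-Whitney U
    between first-intron position groups, Wilcoxon rank-sum intron-containing
    vs intronless, and the PSI/expression Pearson r. Tests on groups with <2
    members are skipped (reported as None).
    """
    feat = gene_features.copy()
    feat["expression"] = gene_expression
    feat = feat.dropna(subset=["expression"])
    out: dict = {}

    rho, p = stats.spearmanr(feat["n_introns"], feat["expression"])
    out["intron_number_spearman"] = {"rho": float(rho), "p": float(p)}

    groups = {g: feat.loc[feat["first_intron_group"] == g, "expression"] for g in ("5p", "middle", "3p")}
    mw = {}
    pairs = [("5p", "middle"), ("5p", "3p"), ("middle", "3p")]
    for g1, g2 in pairs:
        if len(groups[g1]) < 2 or len(groups[g2]) < 2:
            mw[f"{g1}_vs_{g2}"] = None
            continue
        u, p = stats.mannwhitneyu(groups[g1], groups[g2], alternative="two-sided")
        mw[f"{g1}_vs_{g2}"] = {"U": float(u), "p": float(p)}
    out["first_intron_position_mannwhitney"] = mw

    with_introns = feat.loc[feat["n_introns"] > 0, "expression"]
    without = feat.loc[feat["n_introns"] == 0, "expression"]
    if len(with_introns) >= 2 and len(without) >= 2:
        stat, p = stats.ranksums(with_introns, without)
        out["intron_containing_vs_intronless"] = {"stat": float(stat), "p": float(p)}
    else:
        out["intron_containing_vs_intronless"] = None

    if intron_psi is not None and intron_to_gene is not None:
        expr_of_host = intron_psi.index.map(lambda i: gene_expression.get(intron_to_gene.get(i)))
        mask = pd.notna(expr_of_host) & intron_psi.notna()
        if mask.sum() >= 2:
            r, p = stats.pearsonr(intron_psi[mask], np.asarray(expr_of_host, dtype=float)[mask])
            out["psi_expression_pearson"] = {"r": float(r), "p": float(p)}
        else:
            out["psi_expression_pearson"] = None
    return out
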