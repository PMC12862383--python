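"""Confound-adjusted regression screen of splicing factors on intron retention.

For every (DSI intron, splicing-factor gene) pair the model

    PSI_z = beta0 + beta1 * ln(factor counts + 1)_z + beta2 * cell_type + eps

is fitted by OLS across the 48 replicate samples, with PSI and the log factor
expression z-transformed. Significance of beta1 and beta2 is assessed with
BH-FDR (one family per coefficient across all pairs) at alpha 0.1. Because
both DSIs and factor DEGs were discovered from the symbiotic/aposymbiotic
contrast, the cell type is a confounder: beta1 is set to 0 whenever beta2 is
significant. Factors are classified by the mean adjusted beta1 over their
retained introns: negative = splicing enhancer (more factor, less retention),
positive = splicing repressor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

REGRESSION_FDR_ALPHA = 0.1
MIN_COMPLETE_OBS = 10


def zstandardize(values: np.ndarray | pd.Series) -> np.ndarray:
    """Z-transform to mean 0, sample SD 1 over non-missing entries.

    Missing entries stay missing. Raises on zero variance or <2 observations.
    """
    arr = np.asarray(values, dtype=float)
    obs = arr[~np.isnan(arr)]
    if obs.size < 2:
        raise ValueError("need >=2 non-missing values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    return (arr - obs.mean()) / sd


def fit_pair(psi_z: np.ndarray, factor_z: np.ndarray, cell_type: np.ndarray) -> dict:
    """OLS fit of one intron/factor pair; two-sided t-tests on beta1, beta2.

    Fitted on complete observations only. Returns a dict with coefficients,
    p-values and an ``estimable`` flag (False when factor and cell type are
    perfectly collinear or observations are too few).
    """
    psi_z = np.asarray(psi_z, dtype=float)
    factor_z = np.asarray(factor_z, dtype=float)
    ct = np.asarray(cell_type, dtype=float)
    mask = ~(np.isnan(psi_z) | np.isnan(factor_z) | np.isnan(ct))
    y, x, c = psi_z[mask], factor_z[mask], ct[mask]
    n = y.size
    base = {"n_obs": int(n), "estimable": False, "beta0": np.nan, "beta1": np.nan,
            "beta2": np.nan, "p_beta1": np.nan, "p_beta2": np.nan}
    if n < MIN_COMPLETE_OBS:
        return base
    X = np.column_stack([np.ones(n), x, c])
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < 3:
        return base
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    dof = n - 3
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return {
        "n_obs": int(n),
        "estimable": True,
        "beta0": float(beta[0]),
        "beta1": float(beta[1]),
        "beta2": float(beta[2]),
        "p_beta1": float(pvals[1]),
        "p_beta2": float(pvals[2]),
    }


def screen(
    psi_matrix: pd.DataFrame,
    factor_expression: pd.DataFrame,
    cell_type: pd.Series,
    fdr_alpha: float = REGRESSION_FDR_ALPHA,
) -> pd.DataFrame:
    """Fit all DSI x factor pairs and apply FDR plus the confound rule.

    ``psi_matrix``: introns x samples, PSI in [0,1] or NaN.
    ``factor_expression``: factors x samples, normalized counts (not logged).
    ``cell_type``: 0/1 per sample (1 = symbiotic), aligned on sample ids.

    Returns the long pair-level table with fdr_beta1/fdr_beta2 (one BH family
    per coefficient across all estimable pairs), beta1_adjusted (0 when
    fdr_beta2 < alpha) and the retained flag (fdr_beta1 < alpha and fdr_beta2
    >= alpha). Constant PSI or factor vectors are dropped with a note.
    """
    samples = [s for s in psi_matrix.columns if s in factor_expression.columns]
    if not samples:
        raise ValueError("no shared samples between PSI matrix and expression")
    ct = cell_type.loc[samples].to_numpy(dtype=float)

    def _safe_z(row: np.ndarray):
        try:
            return zstandardize(row)
        except ValueError:
            return None

    psi_z = {i: _safe_z(psi_matrix.loc[i, samples].to_numpy(dtype=float)) for i in psi_matrix.index}
    log_factor = np.log(factor_expression[samples].to_numpy(dtype=float) + 1.0)
    factor_z = {f: _safe_z(log_factor[k]) for k, f in enumerate(factor_expression.index)}

    rows = []
    for intron_id, yz in psi_z.items():
        if yz is None:
            continue
        for factor_id, xz in factor_z.items():
            if xz is None:
                continue
            res = fit_pair(yz, xz, ct)
            res["intron_id"] = intron_id
            res["factor_id"] = factor_id
            rows.append(res)
    results = pd.DataFrame(rows)
    if results.empty or not results["estimable"].any():
        for col in ("fdr_beta1", "fdr_beta2", "beta1_adjusted"):
            results[col] = np.nan
        results["retained"] = False
        return results
    est = results["estimable"].to_numpy()
    fdr1 = np.full(len(results), np.nan)
    fdr2 = np.full(len(results), np.nan)
    fdr1[est] = multipletests(results.loc[est, "p_beta1"], method="fdr_bh")[1]
    fdr2[est] = multipletests(results.loc[est, "p_beta2"], method="fdr_bh")[1]
    results["fdr_beta1"] = fdr1
    results["fdr_beta2"] = fdr2
    confounded = results["fdr_beta2"] < fdr_alpha
    results["beta1_adjusted"] = np.where(confounded, 0.0, results["beta1"])
    results["retained"] = est & (results["fdr_beta1"] < fdr_alpha) & ~confounded
    return results


def retained_introns(results: pd.DataFrame) -> list[str]:
    """Introns with at least one retained (significant, unconfounded) pair."""
    if results.empty:
        return []
    return sorted(results.loc[results["retained"], "intron_id"].unique())


def classify_factors(results: pd.DataFrame) -> pd.DataFrame:
    """Classify each factor by the mean adjusted beta1 over retained introns.

    role: enhancer (mean < 0), repressor (mean > 0), unclassified (no
    retained pairs or mean exactly 0).
    """
    factors = sorted(results["factor_id"].unique()) if not results.empty else []
    rows = []
    for f in factors:
        sub = results[(results["factor_id"] == f) & results["retained"]]
        n_sig = len(sub)
        mean_coef = float(sub["beta1_adjusted"].mean()) if n_sig else float("nan")
        if n_sig == 0 or mean_coef == 0:
            role = "unclassified"
        elif mean_coef < 0:
            role = "enhancer"
        else:
            role = "repressor"
        rows.append(
            {"factor_id": f, "mean_coefficient": mean_coef, "role": role, "n_significant": n_sig}
        )
    return pd.DataFrame(rows, columns=["factor_id", "mean_coefficient", "role", "n_significant"])


def rank_factors(results: pd.DataFrame) -> pd.DataFrame:
    """Rank factors by retained-pair count, ties by |mean coefficient| then id."""
    cls = classify_factors(results)
    if cls.empty:
        return cls
    cls["abs_mean"] = cls["mean_coefficient"].abs().fillna(0.0)
    ranked = cls.sort_values(
        by=["n_significant", "abs_mean", "factor_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).drop(columns="abs_mean")
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    return ranked.reset_index(drop=True)


def compare_role_expression(
    classifications: pd.DataFrame,
    expression: pd.DataFrame,
    cell_type: pd.Series,
) -> dict:
    """Per-role Wilcoxon rank-sum of gene expression between conditions.

    For each role, the per-gene mean log expression in cell_type==1 samples
    is compared with the per-gene mean in cell_type==0 samples. Roles with <2
    genes are skipped (None).
    """
    sym = [s for s in expression.columns if cell_type.get(s) == 1]
    apo = [s for s in expression.columns if cell_type.get(s) == 0]
    out = {}
    for role in ("enhancer", "repressor"):
        genes = classifications.loc[classifications["role"] == role, "factor_id"]
        genes = [g for g in genes if g in expression.index]
        if len(genes) < 2:
            out[role] = None
            continue
        log_expr = np.log(expression.loc[genes] + 1.0)
        a = log_expr[sym].mean(axis=1)
        b = log_expr[apo].mean(axis=1)
        stat, p = stats.ranksums(a, b)
        out[role] = {"stat": float(stat), "p": float(p), "n_genes": len(genes)}
    return out
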