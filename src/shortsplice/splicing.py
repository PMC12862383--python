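"""PSI quantification from junction counts, filters, DSI calling, and A3SS analyses.

The intron retention rate is expressed as PSI with inclusion reads
down-weighted by 0.5 (an intron has two retention-informative boundaries but
one spliced junction):

    PSI = 0.5*I / (0.5*I + S)

where I are reads supporting retention and S are spliced exon-exon junction
reads. Differentially spliced introns (DSIs) between two conditions are
called per timepoint from pooled per-condition counts with a binomial
likelihood-ratio test, gated on |dPSI| >= 0.1, junction support >= 10, and
BH-FDR < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests


@dataclass
class SplicingConfig:
    """Thresholds for PSI filtering and DSI calling."""

    min_junction_reads: int = 10
    max_replicate_sd: float = 0.1
    min_abs_dpsi: float = 0.1
    fdr_alpha: float = 0.05
    n_replicates: int = 3


def sample_id(condition: str, timepoint: int, replicate: int) -> str:
    return f"{condition}_T{timepoint}_R{replicate}"


def parse_sample_id(sid: str) -> tuple[str, int, int]:
    condition, tp, rep = sid.rsplit("_", 2)
    return condition, int(tp[1:]), int(rep[1:])


def compute_psi(inclusion: float, spliced: float) -> float:
    """PSI = 0.5*I / (0.5*I + S); NaN when there are no junction reads."""
    if inclusion < 0 or spliced < 0:
        raise ValueError("negative read counts")
    denom = 0.5 * inclusion + spliced
    if denom == 0:
        return float("nan")
    return 0.5 * inclusion / denom


def psi_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per intron x sample PSI estimates from a junction-count table.

    ``counts`` columns: intron_id, sample_id, inclusion_reads, spliced_reads.
    Adds psi, junction_total and the parsed sample annotation.
    """
    df = counts.copy()
    inc = df["inclusion_reads"].to_numpy(dtype=float)
    spl = df["spliced_reads"].to_numpy(dtype=float)
    if (inc < 0).any() or (spl < 0).any():
        raise ValueError("negative read counts")
    denom = 0.5 * inc + spl
    with np.errstate(invalid="ignore", divide="ignore"):
        df["psi"] = np.where(denom > 0, 0.5 * inc / denom, np.nan)
    df["junction_total"] = (inc + spl).astype(int)
    parsed = df["sample_id"].map(parse_sample_id)
    df["condition"] = [p[0] for p in parsed]
    df["timepoint"] = [p[1] for p in parsed]
    df["replicate"] = [p[2] for p in parsed]
    return df


def filter_psi(psi: pd.DataFrame, config: SplicingConfig | None = None) -> pd.DataFrame:
    """Apply the PSI quality filters.

    A sample-level estimate is retained iff junction_total >=
    min_junction_reads; a (intron, condition, timepoint) replicate triple is
    retained iff all n_replicates estimates survive and their sample SD is
    below max_replicate_sd. Returns the retained long table with a
    replicate_sd column.
    """
    cfg = config or SplicingConfig()
    df = psi[psi["junction_total"] >= cfg.min_junction_reads].copy()
    df = df[df["psi"].notna()]
    grp = df.groupby(["intron_id", "condition", "timepoint"])
    sd = grp["psi"].transform("std")
    n = grp["psi"].transform("size")
    df["replicate_sd"] = sd
    keep = (n == cfg.n_replicates) & (sd < cfg.max_replicate_sd)
    return df[keep].copy()


def _binomial_loglik(x: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    return xlogy(x, p) + xlogy(n - x, 1.0 - p)


def binomial_lrt(x1, n1, x2, n2):
    """Two-sided LRT for equality of two binomial proportions (vectorized).

    Returns the chi-square(1) p-value; NaN where either trial count is 0.
    """
    x1, n1, x2, n2 = (np.asarray(a, dtype=float) for a in (x1, n1, x2, n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = x1 / n1
        p2 = x2 / n2
        p0 = (x1 + x2) / (n1 + n2)
        ll1 = _binomial_loglik(x1, n1, p1) + _binomial_loglik(x2, n2, p2)
        ll0 = _binomial_loglik(x1, n1, p0) + _binomial_loglik(x2, n2, p0)
    g = np.maximum(2.0 * (ll1 - ll0), 0.0)
    pval = stats.chi2.sf(g, df=1)
    return np.where((n1 > 0) & (n2 > 0), pval, np.nan)


def call_dsis(
    counts: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    timepoint: int,
    config: SplicingConfig | None = None,
) -> pd.DataFrame:
    """Call differentially spliced introns between two conditions at one timepoint.

    Counts are pooled across replicates per condition. delta_psi is
    condition_a - condition_b (positive = higher retention in condition_a).
    An intron is tested only when both conditions reach the junction-support
    gate; BH-FDR runs across all tested introns at the timepoint.
    """
    cfg = config or SplicingConfig()
    df = psi_table(counts)
    df = df[df["timepoint"] == timepoint]
    pooled = (
        df.groupby(["intron_id", "condition"])[["inclusion_reads", "spliced_reads"]]
        .sum()
        .unstack("condition")
    )
    for cond in (condition_a, condition_b):
        if ("inclusion_reads", cond) not in pooled.columns:
            raise ValueError(f"condition {cond!r} absent at timepoint {timepoint}")
    ia = pooled[("inclusion_reads", condition_a)].fillna(0.0)
    sa = pooled[("spliced_reads", condition_a)].fillna(0.0)
    ib = pooled[("inclusion_reads", condition_b)].fillna(0.0)
    sb = pooled[("spliced_reads", condition_b)].fillna(0.0)
    support = ((ia + sa) >= cfg.min_junction_reads) & ((ib + sb) >= cfg.min_junction_reads)
    ia, sa, ib, sb = (v[support] for v in (ia, sa, ib, sb))
    if ia.empty:
        return pd.DataFrame(
            columns=["intron_id", "timepoint", "delta_psi", "p_value", "fdr", "is_dsi", "direction"]
        )
    psi_a = 0.5 * ia / (0.5 * ia + sa)
    psi_b = 0.5 * ib / (0.5 * ib + sb)
    # effective binomial: successes = 0.5*I rounded, failures = S
    xa, na = np.round(0.5 * ia), np.round(0.5 * ia) + sa
    xb, nb = np.round(0.5 * ib), np.round(0.5 * ib) + sb
    pvals = binomial_lrt(xa, na, xb, nb)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    delta = (psi_a - psi_b).to_numpy()
    out = pd.DataFrame(
        {
            "intron_id": ia.index,
            "timepoint": timepoint,
            "delta_psi": delta,
            "p_value": pvals,
            "fdr": fdr,
            "is_dsi": (np.abs(delta) >= cfg.min_abs_dpsi) & (fdr < cfg.fdr_alpha),
            "direction": np.where(delta >= 0, f"higher_{condition_a}", f"higher_{condition_b}"),
        }
    ).reset_index(drop=True)
    return out


def pool_dsis(
    per_timepoint: list[pd.DataFrame],
    intron_to_gene: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Union of DSIs across timepoints, deduplicated by intron.

    Direction is taken from the timepoint with the largest |delta_psi|.
    Returns (pooled table, number of distinct genes hosting a DSI; 0 when no
    gene map is supplied).
    """
    frames = [df[df["is_dsi"]] for df in per_timepoint if not df.empty]
    if not frames:
        return pd.DataFrame(columns=["intron_id", "delta_psi", "direction", "n_timepoints"]), 0
    allhits = pd.concat(frames, ignore_index=True)
    allhits["abs_dpsi"] = allhits["delta_psi"].abs()
    best = allhits.sort_values("abs_dpsi", ascending=False).drop_duplicates("intron_id")
    n_tp = allhits.groupby("intron_id").size().rename("n_timepoints")
    pooled = (
        best.set_index("intron_id")[["delta_psi", "direction"]]
        .join(n_tp)
        .reset_index()
        .sort_values("intron_id")
        .reset_index(drop=True)
    )
    n_genes = 0
    if intron_to_gene is not None:
        n_genes = pooled["intron_id"].map(intron_to_gene).nunique()
    return pooled, n_genes


def a3ss_frame_analysis(events: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Distance and reading-frame impact of alternative 3' splice-site events.

    ``events`` columns: intron_id, canonical_3ss, alternative_3ss (transcript
    coordinates). Adds distance (absolute nt) and frameshift (distance not a
    multiple of 3); returns the table and the frameshifting fraction.
    """
    df = events.copy()
    df["distance"] = (df["alternative_3ss"] - df["canonical_3ss"]).abs().astype(int)
    if (df["distance"] == 0).any():
        raise ValueError("zero-distance A3SS event is invalid")
    df["frameshift"] = df["distance"] % 3 != 0
    frac = float(df["frameshift"].mean()) if len(df) else float("nan")
    return df, frac


def frameshift_fraction(n_frameshift: int, n_total: int) -> float:
    """Share of A3SS events that shift the reading frame."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return n_frameshift / n_total


def downstream_junction_enrichment(
    a3ss_introns: pd.DataFrame,
    all_introns: pd.DataFrame,
    seed: int,
) -> tuple[float, float, np.ndarray]:
    """Fisher test of downstream-junction presence: A3SS introns vs random introns.

    Both tables need intron_id and has_downstream_junction columns. The
    background is |a3ss_introns| introns sampled without replacement from
    all_introns. Returns (odds ratio, two-sided p, 2x2 table); the odds ratio
    uses a Haldane 0.5 correction when the table has a zero cell.
    """
    n = len(a3ss_introns)
    if len(all_introns) < n:
        raise ValueError("background smaller than the A3SS set")
    rng = np.random.default_rng(seed)
    bg = all_introns.sample(n=n, random_state=np.random.RandomState(rng.integers(2**31)))
    a_yes = int(a3ss_introns["has_downstream_junction"].sum())
    b_yes = int(bg["has_downstream_junction"].sum())
    table = np.array([[a_yes, n - a_yes], [b_yes, n - b_yes]], dtype=float)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    t = table + 0.5 if (table == 0).any() else table
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p), table.astype(int)


def retention_summary(
    retained_psi: pd.DataFrame,
    features: pd.DataFrame,
    low_psi_threshold: float = 0.1,
) -> dict:
    """Cohort-level retention statistics on the filtered PSI table.

    Returns the fraction of quantified introns whose PSI stays below
    ``low_psi_threshold`` in every retained sample, plus per-length-group and
    per-GC-bin (nearest integer percent) mean PSI with SEM.
    """
    if retained_psi.empty:
        raise ValueError("retained PSI table is empty")
    per_intron_max = retained_psi.groupby("intron_id")["psi"].max()
    frac_low = float((per_intron_max < low_psi_threshold).mean())
    mean_psi = retained_psi.groupby("intron_id")["psi"].mean().rename("mean_psi")
    feat = features.set_index("intron_id").join(mean_psi, how="inner")
    feat["gc_bin"] = (feat["gc"] * 100).round().astype(int)
    by_length = (
        feat.groupby("length_group")["mean_psi"].agg(["mean", "sem", "size"]).dropna(how="all")
    )
    by_gc = feat.groupby("gc_bin")["mean_psi"].agg(["mean", "sem", "size"])
    by_gc = by_gc[by_gc["size"] > 0]
    return {
        "fraction_max_psi_below_threshold": frac_low,
        "psi_by_length_group": by_length,
        "psi_by_gc_bin": by_gc,
        "n_quantified_introns": int(per_intron_max.size),
    }
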