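"""Cross-species intron orthology and parsimony-based intron age assignment.

Intron positions are matched across species through the encoded protein:
orthologous gene pairs are found by reciprocal-best-hit (RBH) local alignment
(BLOSUM62, affine gaps), then each intron's "junction window" (up to 10
amino acids on either side of the splice junction in the protein) is aligned
globally between species. Window pairs with >= 40% identity that are mutual
best scorers (and share the intron phase) are intron orthologs.

Reference-species introns are then dated by Dollo parsimony (one gain,
unlimited losses) on a rooted species tree: the age group is the 1-based
index, along the path from the reference leaf to the root, of the most
recent common ancestor of all species carrying the intron. Introns whose
host gene has no ortholog at all form age group 0; introns in genes with
orthologs in fewer than three of the examined species are excluded from
dating.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

logger = logging.getLogger(__name__)

IDENTITY_THRESHOLD = 0.40
WINDOW_FLANK = 10
MIN_WINDOW_FLANK = 4
GAP_OPEN = -10.0
GAP_EXTEND = -1.0


def _aligner(mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = GAP_OPEN
    al.extend_gap_score = GAP_EXTEND
    al.mode = mode
    return al


def protein_rbh(proteome_a: dict[str, str], proteome_b: dict[str, str]) -> pd.DataFrame:
    """Reciprocal-best-hit ortholog pairs between two proteomes.

    Local alignment, BLOSUM62, affine gaps. A pair is kept iff each protein
    is the other's unique best-scoring hit; ties for best drop the protein.
    Empty sequences are skipped with a warning.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    al = _aligner("local")
    a_ids = [k for k, v in proteome_a.items() if v] or []
    b_ids = [k for k, v in proteome_b.items() if v]
    for name, prot in (("a", proteome_a), ("b", proteome_b)):
        for k, v in prot.items():
            if not v:
                logger.warning("skipping empty sequence %s in proteome %s", k, name)
    scores = np.zeros((len(a_ids), len(b_ids)))
    for i, ka in enumerate(a_ids):
        sa = proteome_a[ka]
        for j, kb in enumerate(b_ids):
            scores[i, j] = al.score(sa, proteome_b[kb])

    def _unique_best(row: np.ndarray) -> int | None:
        best = row.max()
        idx = np.flatnonzero(row == best)
        return int(idx[0]) if idx.size == 1 else None

    best_a = [_unique_best(scores[i]) for i in range(len(a_ids))]
    best_b = [_unique_best(scores[:, j]) for j in range(len(b_ids))]
    rows = []
    for i, j in enumerate(best_a):
        if j is not None and best_b[j] == i:
            rows.append({"gene_a": a_ids[i], "gene_b": b_ids[j], "score": float(scores[i, j])})
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


@dataclass
class JunctionWindow:
    """Amino-acid context around one intron's position in the protein."""

    gene_id: str
    intron_index: int
    window: str
    offset_in_protein: int  # residues fully upstream of the junction
    phase: int  # 0, 1 or 2 nt into the interrupted codon
    left_len: int = 0
    right_len: int = 0

    def __post_init__(self):
        self.left_len = self.offset_in_protein - max(0, self.offset_in_protein - WINDOW_FLANK)


def junction_windows(
    protein: str,
    gene_id: str,
    intron_positions: list[tuple[int, int, int]],
    flank: int = WINDOW_FLANK,
    min_flank: int = MIN_WINDOW_FLANK,
) -> list[JunctionWindow]:
    """Extract junction windows for each intron of one gene.

    ``intron_positions``: (intron_index, residues_upstream, phase) triples,
    where residues_upstream counts complete codons 5' of the junction.
    Windows are truncated at the protein termini; a window with fewer than
    ``min_flank`` residues on either side is excluded and logged. Positions
    outside the coding region are excluded.
    """
    out = []
    n = len(protein)
    for idx, pos, phase in intron_positions:
        if pos < 0 or pos > n:
            logger.info("intron %s.i%d outside CDS; excluded", gene_id, idx)
            continue
        lo = max(0, pos - flank)
        hi = min(n, pos + flank)
        left, right = pos - lo, hi - pos
        if left < min_flank or right < min_flank:
            logger.info("intron %s.i%d window too short (%d/%d); excluded", gene_id, idx, left, right)
            continue
        out.append(
            JunctionWindow(
                gene_id=gene_id,
                intron_index=idx,
                window=protein[lo:hi],
                offset_in_protein=pos,
                phase=phase,
                left_len=left,
                right_len=right,
            )
        )
    return out


def _alignment_identity(al: Align.PairwiseAligner, a: str, b: str) -> tuple[float, float]:
    """(score, identity) for a global window alignment.

    Identity = matched columns / total alignment columns including gaps.
    """
    alignment = al.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    ident = counts.identities / columns if columns else 0.0
    return float(alignment.score), float(ident)


def match_introns(
    windows_a: list[JunctionWindow],
    windows_b: list[JunctionWindow],
    identity_threshold: float = IDENTITY_THRESHOLD,
    require_phase_match: bool = True,
) -> pd.DataFrame:
    """Match intron positions between one RBH gene pair via window alignment.

    All-vs-all global alignments of junction windows; a pair is an intron
    RBH iff identity >= threshold, the score is the unique best in both
    directions, and (by default) the intron phases agree.
    """
    cols = ["intron_a", "intron_b", "score", "identity", "is_rbh"]
    if not windows_a or not windows_b:
        return pd.DataFrame(columns=cols)
    al = _aligner("global")
    score = np.full((len(windows_a), len(windows_b)), -np.inf)
    ident = np.zeros_like(score)
    for i, wa in enumerate(windows_a):
        for j, wb in enumerate(windows_b):
            if require_phase_match and wa.phase != wb.phase:
                continue
            score[i, j], ident[i, j] = _alignment_identity(al, wa.window, wb.window)
    eligible = ident >= identity_threshold
    masked = np.where(eligible, score, -np.inf)

    def _unique_best(row):
        if not np.isfinite(row).any():
            return None
        best = row.max()
        idx = np.flatnonzero(row == best)
        return int(idx[0]) if idx.size == 1 else None

    rows = []
    for i in range(len(windows_a)):
        j = _unique_best(masked[i])
        if j is None:
            continue
        if _unique_best(masked[:, j]) != i:
            continue
        rows.append(
            {
                "intron_a": windows_a[i].intron_index,
                "intron_b": windows_b[j].intron_index,
                "score": float(score[i, j]),
                "identity": float(ident[i, j]),
                "is_rbh": True,
            }
        )
    return pd.DataFrame(rows, columns=cols)


class SpeciesTree:
    """Rooted species tree with a designated reference leaf.

    Age groups index the nodes on the path from the reference leaf to the
    root: the leaf itself is 1 (reference-specific introns), the root is the
    maximum age.
    """

    def __init__(self, newick: str, reference: str):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.tree.is_rooted = True
        self.reference = reference
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if reference not in labels:
            raise ValueError(f"reference {reference!r} not a leaf of the tree")
        self.species = labels
        leaf = self.tree.find_node_with_taxon_label(reference)
        self._path = []
        node = leaf
        while node is not None:
            self._path.append(node)
            node = node.parent_node
        self._node_age = {id(n): i + 1 for i, n in enumerate(self._path)}

    @property
    def max_age(self) -> int:
        return len(self._path)

    def age_of_mrca(self, present: list[str]) -> int:
        """Age class of the MRCA of the present species (reference required)."""
        if self.reference not in present:
            raise ValueError("reference species must carry the intron")
        if len(set(present)) == 1:
            return 1
        mrca = self.tree.mrca(taxon_labels=sorted(set(present)))
        if id(mrca) not in self._node_age:
            raise ValueError("MRCA not on the reference-to-root path")
        return self._node_age[id(mrca)]


def presence_patterns(
    ref_introns: pd.DataFrame,
    gene_orthologs: dict[str, dict[str, str]],
    intron_matches: dict[str, set[str]],
    tree: SpeciesTree,
) -> pd.DataFrame:
    """Per-intron presence pattern across species, plus dating eligibility.

    ``ref_introns``: table with intron_id and gene_id for the reference
    species. ``gene_orthologs``: per non-reference species, mapping of
    reference gene -> ortholog gene. ``intron_matches``: per species, the set
    of reference intron ids with an intron RBH in that species.

    Presence codes: "present", "absent" (gene ortholog exists, intron not
    matched), "gene_missing". Introns in genes with orthologs in fewer than
    3 of the examined species (reference included) are ineligible for age
    groups 1..max; genes with no orthologs at all feed age group 0.
    """
    others = [s for s in tree.species if s != tree.reference]
    rows = []
    for intron_id, gene_id in zip(ref_introns["intron_id"], ref_introns["gene_id"]):
        row = {"intron_id": intron_id, "gene_id": gene_id, tree.reference: "present"}
        n_with_gene = 1
        for sp in others:
            if gene_id not in gene_orthologs.get(sp, {}):
                row[sp] = "gene_missing"
            else:
                n_with_gene += 1
                row[sp] = "present" if intron_id in intron_matches.get(sp, set()) else "absent"
        row["n_species_with_gene"] = n_with_gene
        row["age_zero"] = n_with_gene == 1
        row["eligible"] = n_with_gene >= 3
        rows.append(row)
    return pd.DataFrame(rows)


def assign_age(pattern: dict[str, str], tree: SpeciesTree) -> int:
    """Dollo-parsimony age of one reference intron from its presence pattern.

    ``pattern``: species -> present/absent/gene_missing (reference must be
    present). gene_missing species are excluded from the MRCA: absence of
    the gene carries no information about the intron. Under Dollo parsimony
    (single gain) the gain node minimizing losses is exactly the MRCA of the
    carriers.
    """
    if pattern.get(tree.reference) != "present":
        raise ValueError("reference intron must be present by construction")
    present = [sp for sp, st in pattern.items() if st == "present"]
    return tree.age_of_mrca(present)


def assign_ages(patterns: pd.DataFrame, tree: SpeciesTree) -> pd.DataFrame:
    """Vector version of assign_age over a presence_patterns table.

    age_group: 0 for introns in genes with no orthologs, 1..max_age for
    eligible introns, NaN (excluded) otherwise.
    """
    ages = []
    for _, row in patterns.iterrows():
        if row["age_zero"]:
            ages.append(0)
        elif not row["eligible"]:
            ages.append(np.nan)
        else:
            pat = {sp: row[sp] for sp in tree.species}
            ages.append(assign_age(pat, tree))
    out = patterns[["intron_id", "gene_id"]].copy()
    out["age_group"] = ages
    return out


def age_group_shares(group_sizes: dict[int, int]) -> dict[int, float]:
    """Fraction of introns in each age group (of the groups supplied)."""
    total = sum(group_sizes.values())
    if total <= 0:
        raise ValueError("no introns in any group")
    return {g: n / total for g, n in group_sizes.items()}


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p*(1-p)/n)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.sqrt(p * (1.0 - p) / n))


def cochran_armitage_trend(successes, totals, scores=None) -> tuple[float, float]:
    """Chi-square test for a linear trend in proportions across ordered groups.

    Matches R's prop.trend.test with default scores 1..k. Returns (chi2, p).
    """
    r = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if scores is None:
        scores = np.arange(1, len(r) + 1, dtype=float)
    x = np.asarray(scores, dtype=float)
    pbar = r.sum() / n.sum()
    t = float(((r - n * pbar) * x).sum())
    v = pbar * (1 - pbar) * float((n * x**2).sum() - (n * x).sum() ** 2 / n.sum())
    if v <= 0:
        return 0.0, 1.0
    chi2 = t * t / v
    return chi2, float(stats.chi2.sf(chi2, df=1))


def age_summaries(
    assignments: pd.DataFrame,
    features: pd.DataFrame,
    mean_psi: pd.Series | None = None,
    dsi_ids: set[str] | None = None,
    gene_expression: pd.Series | None = None,
) -> dict:
    """Age-stratified statistics: DSI share per group, trend test, feature tests.

    ``assignments``: intron_id, gene_id, age_group (NaN rows dropped).
    ``features``: per-intron table with gc and length. ``mean_psi``: mean PSI
    per intron. ``gene_expression``: mean (log) expression per gene, compared
    between gene groups defined by the maximum intron age in the gene.
    """
    aged = assignments.dropna(subset=["age_group"]).copy()
    if aged.empty:
        raise ValueError("no aged introns")
    aged["age_group"] = aged["age_group"].astype(int)
    merged = aged.merge(features, on="intron_id", how="left", suffixes=("", "_feat"))
    if mean_psi is not None:
        merged["mean_psi"] = merged["intron_id"].map(mean_psi)
    out: dict = {"groups": {}}
    groups = sorted(merged["age_group"].unique())
    dsi_counts, totals = [], []
    for g in groups:
        sub = merged[merged["age_group"] == g]
        n = len(sub)
        n_dsi = int(sub["intron_id"].isin(dsi_ids).sum()) if dsi_ids is not None else 0
        p = n_dsi / n if n else float("nan")
        out["groups"][g] = {
            "n": n,
            "n_dsi": n_dsi,
            "dsi_proportion": p,
            "dsi_proportion_se": proportion_se(p, n) if n else float("nan"),
            "median_length": float(sub["length"].median()),
            "median_gc": float(sub["gc"].median()),
            "median_psi": float(sub["mean_psi"].median()) if "mean_psi" in sub else float("nan"),
        }
        dsi_counts.append(n_dsi)
        totals.append(n)
    if dsi_ids is not None and len(groups) >= 2:
        chi2, p = cochran_armitage_trend(dsi_counts, totals, scores=groups)
        out["dsi_trend"] = {"chi2": chi2, "p": p}

    def _pairwise(col: str, test) -> dict:
        res = {}
        for g1, g2 in itertools.combinations(groups, 2):
            a = merged.loc[merged["age_group"] == g1, col].dropna()
            b = merged.loc[merged["age_group"] == g2, col].dropna()
            if len(a) < 2 or len(b) < 2:
                res[f"{g1}_vs_{g2}"] = None
                continue
            stat, p = test(a, b)
            res[f"{g1}_vs_{g2}"] = {"stat": float(stat), "p": float(p)}
        return res

    mw = lambda a, b: stats.mannwhitneyu(a, b, alternative="two-sided")  # noqa: E731
    ks = lambda a, b: stats.ks_2samp(a, b)  # noqa: E731
    if "mean_psi" in merged:
        out["psi_by_age_mannwhitney"] = _pairwise("mean_psi", mw)
    out["gc_by_age_mannwhitney"] = _pairwise("gc", mw)
    out["length_by_age_ks"] = _pairwise("length", ks)

    if gene_expression is not None:
        max_age = merged.groupby("gene_id")["age_group"].max()
        expr = gene_expression.reindex(max_age.index)
        res = {}
        for g1, g2 in itertools.combinations(sorted(max_age.unique()), 2):
            a = expr[max_age == g1].dropna()
            b = expr[max_age == g2].dropna()
            if len(a) < 2 or len(b) < 2:
                res[f"{g1}_vs_{g2}"] = None
                continue
            u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            res[f"{g1}_vs_{g2}"] = {"U": float(u), "p": float(p)}
        out["expression_by_max_intron_age"] = res
    return out
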