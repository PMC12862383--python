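"""Synthetic multi-species cohort with planted ground truth.

Emulates the study design the downstream analyses assume: two conditions
(symbiotic / aposymbiotic) x 8 timepoints x 3 replicates (48 samples), genes
carrying short GT..AG introns (15-100 nt, median ~24 nt, GC ~18% vs ~31%
exonic), binomially sampled junction read counts, planted condition effects
on PSI (|dPSI| >= delta_psi_effect), planted splicing-factor -> PSI linear
couplings, planted DEGs, and a multi-species gene family history (single
intron gain on a rooted tree, rare per-branch losses) for the orthology/age
stage.

The count model: with retention rate psi, inclusion reads are drawn
Binomial(depth, p) with p = 2*psi / (1 + psi), which inverts the
0.5-weighted PSI formula so the plug-in estimator is consistent. Everything
is a deterministic function of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .annotation import reverse_complement
from .orthology import SpeciesTree
from .splicing import sample_id

# standard genetic code, sense codons only
_CODON_OF = {
    "F": ["TTT", "TTC"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "I": ["ATT", "ATC", "ATA"], "M": ["ATG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "A": ["GCT", "GCC", "GCA", "GCG"],
    "Y": ["TAT", "TAC"], "H": ["CAT", "CAC"], "Q": ["CAA", "CAG"],
    "N": ["AAT", "AAC"], "K": ["AAA", "AAG"], "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "C": ["TGT", "TGC"], "W": ["TGG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
}
_SENSE_CODONS = sorted(c for cods in _CODON_OF.values() for c in cods)
_AA_OF = {c: aa for aa, cods in _CODON_OF.items() for c in cods}
_AAS = sorted(_CODON_OF)


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort (seed fully determines output)."""

    n_genes: int = 150
    mean_introns_per_gene: float = 2.7
    intron_length_geom_p: float = 0.07  # length = 15 + Geom(p)-1, capped at 100
    intron_min_length: int = 15
    intron_max_length: int = 100
    intron_gc_mean: float = 0.18
    intron_gc_sd: float = 0.05
    exon_gc_mean: float = 0.31
    min_codons: int = 80
    max_codons: int = 180
    n_timepoints: int = 8
    n_replicates: int = 3
    conditions: tuple[str, str] = ("symbiotic", "aposymbiotic")
    # junction read depth: lognormal, shared across introns
    depth_median: float = 60.0
    depth_sigma: float = 0.6
    # condition effects on retention
    frac_dsi: float = 0.08
    delta_psi_effect: float = 0.3
    night_interaction: bool = False  # restrict the condition effect to night timepoints
    # baseline retention model (logit scale)
    psi_base_logit_mean: float = -3.2
    psi_base_logit_sd: float = 0.6
    gc_psi_slope: float = 6.0  # logit units per GC fraction: high-GC introns retained more
    age_psi_slope: float = -0.4  # logit units per age class: old introns spliced better
    psi_sample_logit_sd: float = 0.10
    # splicing factors
    n_factors: int = 40
    frac_enhancers: float = 0.25
    frac_repressors: float = 0.25
    effect_size_beta1: float = 1.0
    factor_noise_sd: float = 0.5
    targets_per_factor: int = 5
    factor_condition_shift: float = 0.0
    target_psi_center: float = 0.4
    target_psi_amplitude: float = 0.12
    # expression
    frac_deg: float = 0.10
    deg_log2fc: float = 2.0
    expr_log_mean: float = math.log(300.0)
    expr_log_sd: float = 1.0
    library_size_sd: float = 0.15
    # species history
    tree_newick: str = "((Pbur,(Ptet,Pcau)),Tthe);"
    reference: str = "Pbur"
    birth_age_probs: tuple[float, ...] = (0.47, 0.43, 0.10)  # ages 1..max_age
    loss_prob: float = 0.01  # per branch below the gain node
    frac_gene_no_ortholog: float = 0.33
    ortholog_presence_prob: float = 0.95
    protein_divergence: float = 0.10
    flank_length: int = 30
    seed: int = 0

    def validate(self) -> None:
        fracs = {
            "frac_dsi": self.frac_dsi, "frac_enhancers": self.frac_enhancers,
            "frac_repressors": self.frac_repressors, "frac_deg": self.frac_deg,
            "frac_gene_no_ortholog": self.frac_gene_no_ortholog,
            "ortholog_presence_prob": self.ortholog_presence_prob,
            "protein_divergence": self.protein_divergence, "loss_prob": self.loss_prob,
            "intron_gc_mean": self.intron_gc_mean, "exon_gc_mean": self.exon_gc_mean,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.frac_enhancers + self.frac_repressors > 1.0:
            raise ValueError("enhancer + repressor fractions exceed 1")
        if self.intron_min_length < 15:
            raise ValueError("intron_min_length must be >= 15")
        if abs(sum(self.birth_age_probs) - 1.0) > 1e-9:
            raise ValueError("birth_age_probs must sum to 1")
        if not 0 < self.delta_psi_effect < 1:
            raise ValueError("delta_psi_effect must be in (0,1)")


@dataclass
class GroundTruth:
    """Planted quantities, exported alongside the cohort."""

    true_psi: pd.DataFrame  # introns x samples
    dsi_flags: dict[str, bool]
    dsi_direction: dict[str, str]
    factor_roles: dict[str, str]  # enhancer / repressor / null
    factor_targets: dict[str, list[str]]
    intron_birth_age: dict[str, int]  # age class of the gain node (1..max)
    gene_has_orthologs: dict[str, bool]
    presence: dict[str, dict[str, bool]]  # intron -> species -> carries intron
    deg_flags: dict[str, bool]
    deg_log2fc: dict[str, float]
    # latent per-sample activity driving each factor and its targets (not exported)
    factor_activity: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SpeciesGene:
    gene_id: str
    species: str
    contig: str
    strand: str
    contig_seq: str
    exons: list[tuple[int, int]]  # genomic 1-based, transcription order
    protein: str
    intron_positions: list[tuple[int, int, int]]  # (index, residues upstream, phase)


@dataclass
class Cohort:
    config: CohortConfig
    tree: SpeciesTree
    genes: dict[str, dict[str, SpeciesGene]]  # species -> gene_id -> gene
    counts: pd.DataFrame  # reference junction counts (long)
    expression: pd.DataFrame  # raw counts, genes x samples
    truth: GroundTruth

    @property
    def species(self) -> list[str]:
        return self.tree.species

    def genome(self, species: str) -> dict[str, str]:
        return {g.contig: g.contig_seq for g in self.genes[species].values()}

    def proteome(self, species: str) -> dict[str, str]:
        return {g.gene_id: g.protein for g in self.genes[species].values()}

    def sample_ids(self) -> list[str]:
        cfg = self.config
        return [
            sample_id(c, t, r)
            for c in cfg.conditions
            for t in range(1, cfg.n_timepoints + 1)
            for r in range(1, cfg.n_replicates + 1)
        ]

    def cell_type(self) -> pd.Series:
        return pd.Series(
            {s: 1 if s.startswith(self.config.conditions[0]) else 0 for s in self.sample_ids()}
        )


# ---------------------------------------------------------------- sequences


def _codon_probs(gc: float) -> np.ndarray:
    w = {b: gc / 2.0 if b in "GC" else (1.0 - gc) / 2.0 for b in "ACGT"}
    p = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in _SENSE_CODONS])
    return p / p.sum()


def _sample_cds(rng: np.random.Generator, n_codons: int, gc: float) -> tuple[str, str]:
    probs = _codon_probs(gc)
    idx = rng.choice(len(_SENSE_CODONS), size=n_codons - 1, p=probs)
    codons = ["ATG"] + [_SENSE_CODONS[i] for i in idx]
    cds = "".join(codons)
    protein = "".join(_AA_OF[c] for c in codons)
    return cds, protein


def _back_translate(rng: np.random.Generator, protein: str, gc: float) -> str:
    w = {b: gc / 2.0 if b in "GC" else (1.0 - gc) / 2.0 for b in "ACGT"}
    out = []
    for aa in protein:
        cods = _CODON_OF[aa]
        p = np.array([w[c[0]] * w[c[1]] * w[c[2]] for c in cods])
        out.append(cods[rng.choice(len(cods), p=p / p.sum())])
    return "".join(out)


def _sample_intron_seq(rng: np.random.Generator, length: int, gc_target: float) -> str:
    interior = length - 4
    g = 0.0 if interior <= 0 else np.clip((gc_target * length - 2.0) / interior, 0.01, 0.9)
    bases = rng.choice(list("ACGT"), size=max(0, interior), p=[(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    return "GT" + "".join(bases) + "AG"


def _intron_length(rng: np.random.Generator, cfg: CohortConfig) -> int:
    ln = cfg.intron_min_length + int(rng.geometric(cfg.intron_length_geom_p)) - 1
    return min(ln, cfg.intron_max_length)


def _random_flank(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------- species history


def _simulate_presence(
    rng: np.random.Generator, tree: SpeciesTree, birth_age: int, loss_prob: float
) -> dict[str, bool]:
    """Leaf presence of one reference intron born at path node ``birth_age``.

    Dollo: single gain at the birth node; each edge below it loses the intron
    independently with ``loss_prob``, except edges on the reference lineage
    (reference introns are observed in the reference annotation by
    construction).
    """
    birth_node = tree._path[birth_age - 1]
    ref_path_ids = {id(n) for n in tree._path}
    present: dict[str, bool] = {sp: False for sp in tree.species}

    def _descend(node, alive: bool):
        if not alive:
            return
        if node.is_leaf():
            present[node.taxon.label] = True
            return
        for child in node.child_nodes():
            lost = id(child) not in ref_path_ids and rng.random() < loss_prob
            _descend(child, not lost)

    _descend(birth_node, True)
    present[tree.reference] = True
    return present


# ------------------------------------------------------------- gene models


def generate_gene_models(config: CohortConfig, rng: np.random.Generator | None = None):
    """Simulate per-species gene models, genomes and intron histories.

    Returns (genes, intron_meta) where genes maps species -> gene_id ->
    SpeciesGene and intron_meta is a per-reference-intron table (intron_id,
    gene_id, index, length, gc_target, birth_age, presence per species,
    gene_has_orthologs).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    tree = SpeciesTree(config.tree_newick, config.reference)
    n_ages = tree.max_age
    probs = np.asarray(config.birth_age_probs, dtype=float)
    if probs.size != n_ages:
        raise ValueError(f"birth_age_probs must have {n_ages} entries for this tree")
    others = [sp for sp in tree.species if sp != config.reference]

    genes: dict[str, dict[str, SpeciesGene]] = {sp: {} for sp in tree.species}
    meta_rows = []
    for gi in range(config.n_genes):
        gene_id = f"g{gi:04d}"
        for attempt in range(20):
            n_codons = int(rng.integers(config.min_codons, config.max_codons + 1))
            n_introns = int(rng.poisson(config.mean_introns_per_gene))
            cds_len = 3 * n_codons
            # junction offsets strictly inside the CDS, distinct
            if n_introns > cds_len - 6:
                continue  # intron budget impossible for this exon length; regenerate
            offsets = np.sort(rng.choice(np.arange(3, cds_len - 2), size=n_introns, replace=False))
            break
        else:
            raise RuntimeError(f"could not place introns in gene {gene_id}")
        cds, protein = _sample_cds(rng, n_codons, config.exon_gc_mean)
        strand = "+" if rng.random() < 0.5 else "-"

        has_orth = rng.random() >= config.frac_gene_no_ortholog
        orth_present = {
            sp: has_orth and rng.random() < config.ortholog_presence_prob for sp in others
        }

        intron_info = []
        for k, off in enumerate(offsets, start=1):
            length = _intron_length(rng, config)
            gc_target = float(
                np.clip(rng.normal(config.intron_gc_mean, config.intron_gc_sd), 0.02, 0.6)
            )
            birth_age = int(rng.choice(np.arange(1, n_ages + 1), p=probs))
            presence = _simulate_presence(rng, tree, birth_age, config.loss_prob)
            intron_info.append(
                {
                    "intron_id": f"{gene_id}.i{k}",
                    "index": k,
                    "offset": int(off),
                    "length": length,
                    "gc_target": gc_target,
                    "birth_age": birth_age,
                    "presence": presence,
                }
            )
            meta_rows.append(
                {
                    "intron_id": f"{gene_id}.i{k}",
                    "gene_id": gene_id,
                    "index": k,
                    "length": length,
                    "gc_target": gc_target,
                    "birth_age": birth_age,
                    "gene_has_orthologs": any(orth_present.values()),
                    **{f"in_{sp}": bool(presence[sp]) for sp in tree.species},
                    **{f"gene_in_{sp}": bool(orth_present.get(sp, sp == config.reference)) for sp in tree.species},
                }
            )

        # per-species realization
        for sp in tree.species:
            if sp == config.reference:
                sp_protein, sp_cds = protein, cds
            else:
                if not orth_present[sp]:
                    continue
                aas = list(protein)
                for p_i in range(1, len(aas)):
                    if rng.random() < config.protein_divergence:
                        choices = [a for a in _AAS if a != aas[p_i]]
                        aas[p_i] = choices[int(rng.integers(len(choices)))]
                sp_protein = "".join(aas)
                sp_cds = _back_translate(rng, sp_protein, config.exon_gc_mean)
            sp_introns = [
                info
                for info in intron_info
                if sp == config.reference or info["presence"][sp]
            ]
            segs, positions = [], []
            prev = 0
            for info in sp_introns:
                off = info["offset"]
                segs.append(sp_cds[prev:off])
                if sp == config.reference:
                    iseq = _sample_intron_seq(rng, info["length"], info["gc_target"])
                    info["seq"] = iseq
                else:
                    iseq = _sample_intron_seq(rng, info["length"], info["gc_target"])
                segs.append(iseq)
                positions.append((info["index"], off // 3, off % 3))
                prev = off
            segs.append(sp_cds[prev:])
            # exon/intron layout in transcript coordinates
            exon_spans, pos = [], 0
            for si, seg in enumerate(segs):
                if si % 2 == 0:
                    exon_spans.append((pos, pos + len(seg)))
                pos += len(seg)
            tx_seq = "".join(segs)
            flank5 = _random_flank(rng, config.flank_length)
            flank3 = _random_flank(rng, config.flank_length)
            L = len(tx_seq)
            fl = config.flank_length
            if strand == "+":
                contig_seq = flank5 + tx_seq + flank3
                exons = [(fl + a + 1, fl + b) for a, b in exon_spans]
            else:
                contig_seq = flank5 + reverse_complement(tx_seq) + flank3
                exons = [(fl + (L - b) + 1, fl + (L - a)) for a, b in exon_spans]
            genes[sp][gene_id] = SpeciesGene(
                gene_id=gene_id,
                species=sp,
                contig=f"{sp}_ctg{gi:04d}",
                strand=strand,
                contig_seq=contig_seq,
                exons=exons,
                protein=sp_protein,
                intron_positions=positions,
            )
    return genes, pd.DataFrame(meta_rows), tree


# --------------------------------------------------------------- retention


def _night_timepoints(n_timepoints: int) -> set[int]:
    return set(range(n_timepoints // 2 + 1, n_timepoints + 1))


def generate_true_psi(
    config: CohortConfig, intron_meta: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per intron x sample true retention rates plus planted effect bookkeeping."""
    samples = [
        sample_id(c, t, r)
        for c in config.conditions
        for t in range(1, config.n_timepoints + 1)
        for r in range(1, config.n_replicates + 1)
    ]
    n_s = len(samples)
    cond_a = np.array([s.startswith(config.conditions[0]) for s in samples])
    tps = np.array([int(s.rsplit("_", 2)[1][1:]) for s in samples])
    night = np.isin(tps, list(_night_timepoints(config.n_timepoints)))

    introns = intron_meta["intron_id"].tolist()
    n_i = len(introns)

    # factor roles and targets
    n_enh = int(round(config.n_factors * config.frac_enhancers))
    n_rep = int(round(config.n_factors * config.frac_repressors))
    factor_ids = [f"sf{k:03d}" for k in range(config.n_factors)]
    roles = (["enhancer"] * n_enh + ["repressor"] * n_rep
             + ["null"] * (config.n_factors - n_enh - n_rep))
    factor_roles = dict(zip(factor_ids, roles))
    planted = [f for f in factor_ids if factor_roles[f] != "null"]
    n_targets_needed = len(planted) * config.targets_per_factor

    order = rng.permutation(n_i)
    target_pool = [introns[i] for i in order[:n_targets_needed]]
    factor_targets = {f: [] for f in factor_ids}
    for j, f in enumerate(planted):
        factor_targets[f] = target_pool[
            j * config.targets_per_factor : (j + 1) * config.targets_per_factor
        ]
    remaining = [introns[i] for i in order[n_targets_needed:]]
    n_dsi = int(round(config.frac_dsi * n_i))
    dsi_set = set(remaining[:n_dsi])

    base_logit = (
        config.psi_base_logit_mean
        + config.psi_base_logit_sd * rng.normal(size=n_i)
        + config.gc_psi_slope * (intron_meta["gc_target"].to_numpy() - config.intron_gc_mean)
        + config.age_psi_slope * (intron_meta["birth_age"].to_numpy() - 1)
    )
    jitter = config.psi_sample_logit_sd * rng.normal(size=(n_i, n_s))

    # latent factor activity across samples (independent of condition by default)
    activity = {f: rng.normal(size=n_s) for f in factor_ids}
    if config.factor_condition_shift:
        for f in factor_ids:
            activity[f] = activity[f] + config.factor_condition_shift * np.where(cond_a, 0.5, -0.5)

    psi = expit(base_logit[:, None] + jitter)
    dsi_flags = {i: False for i in introns}
    dsi_direction: dict[str, str] = {}
    target_of: dict[str, tuple[str, str]] = {}
    for f in planted:
        for t in factor_targets[f]:
            target_of[t] = (f, factor_roles[f])

    delta = config.delta_psi_effect
    for row, intron_id in enumerate(introns):
        if intron_id in target_of:
            f, role = target_of[intron_id]
            sign = -1.0 if role == "enhancer" else 1.0
            raw = (
                config.effect_size_beta1 * sign * activity[f]
                + config.factor_noise_sd * rng.normal(size=n_s)
            )
            psi[row] = np.clip(
                config.target_psi_center + config.target_psi_amplitude * raw, 0.02, 0.98
            )
        elif intron_id in dsi_set:
            low = float(np.clip(expit(base_logit[row]), 0.02, 1.0 - delta - 0.02))
            high = low + delta
            a_high = rng.random() < 0.5
            effect_on = night if config.night_interaction else np.ones(n_s, dtype=bool)
            vals = np.where(cond_a == a_high, high, low)
            vals = np.where(effect_on, vals, low)
            psi[row] = np.clip(vals + config.psi_sample_logit_sd * 0.05 * rng.normal(size=n_s), 0.0, 1.0)
            dsi_flags[intron_id] = True
            dsi_direction[intron_id] = (
                f"higher_{config.conditions[0]}" if a_high else f"higher_{config.conditions[1]}"
            )

    true_psi = pd.DataFrame(psi, index=introns, columns=samples)
    truth = GroundTruth(
        true_psi=true_psi,
        dsi_flags=dsi_flags,
        dsi_direction=dsi_direction,
        factor_roles=factor_roles,
        factor_targets=factor_targets,
        intron_birth_age=dict(zip(introns, intron_meta["birth_age"].astype(int))),
        gene_has_orthologs=dict(
            zip(intron_meta["gene_id"], intron_meta["gene_has_orthologs"].astype(bool))
        ),
        presence={
            i: {sp: bool(v) for sp, v in row.items()}
            for i, row in intron_meta.set_index("intron_id")[
                [c for c in intron_meta.columns if c.startswith("in_")]
            ]
            .rename(columns=lambda c: c[3:])
            .iterrows()
        },
        deg_flags={},
        deg_log2fc={},
        factor_activity=activity,
    )
    return true_psi, truth


# ------------------------------------------------------------------ counts


def generate_junction_counts(
    config: CohortConfig, true_psi: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Binomial junction counts: depth ~ lognormal, inclusion ~ Binom(depth, 2psi/(1+psi))."""
    vals = true_psi.to_numpy()
    if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
        raise ValueError("true PSI must lie in [0,1]")
    n_i, n_s = vals.shape
    if config.depth_sigma > 0:
        depth = np.round(
            rng.lognormal(math.log(config.depth_median), config.depth_sigma, size=(n_i, n_s))
        ).astype(int)
    else:
        depth = np.full((n_i, n_s), int(round(config.depth_median)))
    p_inc = 2.0 * vals / (1.0 + vals)
    inclusion = rng.binomial(depth, p_inc)
    spliced = depth - inclusion
    long = pd.DataFrame(
        {
            "intron_id": np.repeat(true_psi.index.to_numpy(), n_s),
            "sample_id": np.tile(true_psi.columns.to_numpy(), n_i),
            "inclusion_reads": inclusion.ravel(),
            "spliced_reads": spliced.ravel(),
        }
    )
    return long


# -------------------------------------------------------------- expression


def generate_expression(
    config: CohortConfig,
    truth: GroundTruth,
    gene_ids: list[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Raw count matrix (genes + factor genes) x samples with planted effects.

    Ordinary genes get lognormal baselines; a frac_deg subset gets a
    +-deg_log2fc condition effect. Factor genes follow their latent activity:
    ln(counts+1), z-transformed, tracks the same activity that drives their
    target introns' PSI. Per-sample library-size factors exercise the
    median-of-ratios normalization.
    """
    samples = list(truth.true_psi.columns)
    n_s = len(samples)
    cond_a = np.array([s.startswith(config.conditions[0]) for s in samples])
    lib = np.exp(rng.normal(0.0, config.library_size_sd, size=n_s))

    factor_ids = list(truth.factor_roles)
    n_deg = int(round(config.frac_deg * len(gene_ids)))
    deg_genes = list(rng.choice(gene_ids, size=n_deg, replace=False)) if n_deg else []
    deg_sign = {g: (1.0 if rng.random() < 0.5 else -1.0) for g in deg_genes}
    truth.deg_flags = {g: g in deg_sign for g in gene_ids}
    truth.deg_log2fc = {g: deg_sign.get(g, 0.0) * config.deg_log2fc for g in gene_ids}

    rows, index = [], []
    for g in gene_ids:
        lam = math.exp(config.expr_log_mean + config.expr_log_sd * rng.normal())
        fc = 2.0 ** (truth.deg_log2fc[g] / 2.0)
        mu = lam * np.where(cond_a, fc, 1.0 / fc) * lib
        rows.append(rng.poisson(mu))
        index.append(g)

    # factor genes: counts+1 = exp(mu_f + 0.5 * activity) so that the z-scored
    # log expression reproduces the latent activity driving target PSI
    for f in factor_ids:
        act = truth.factor_activity.get(f)
        if act is None:
            raise RuntimeError("factor activity missing; generate_true_psi must run first")
        mu = (np.exp(math.log(300.0) + 0.5 * act) - 1.0).clip(min=0.0) * lib
        rows.append(rng.poisson(mu))
        index.append(f)
    return pd.DataFrame(np.vstack(rows), index=index, columns=samples)


# ---------------------------------------------------------------- assembly


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Run the full generator; a fixed (config, seed) gives identical output."""
    cfg = config or CohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes, intron_meta, tree = generate_gene_models(cfg, rng)
    if intron_meta.empty:
        true_psi = pd.DataFrame(
            columns=[
                sample_id(c, t, r)
                for c in cfg.conditions
                for t in range(1, cfg.n_timepoints + 1)
                for r in range(1, cfg.n_replicates + 1)
            ]
        )
        factor_ids = [f"sf{k:03d}" for k in range(cfg.n_factors)]
        truth = GroundTruth(
            true_psi, {}, {}, {f: "null" for f in factor_ids}, {f: [] for f in factor_ids},
            {}, {}, {}, {}, {},
            factor_activity={f: rng.normal(size=true_psi.shape[1]) for f in factor_ids},
        )
        counts = pd.DataFrame(columns=["intron_id", "sample_id", "inclusion_reads", "spliced_reads"])
    else:
        true_psi, truth = generate_true_psi(cfg, intron_meta, rng)
        counts = generate_junction_counts(cfg, true_psi, rng)
    gene_ids = sorted(genes[cfg.reference])
    expression = generate_expression(cfg, truth, gene_ids, rng)
    return Cohort(config=cfg, tree=tree, genes=genes, counts=counts, expression=expression, truth=truth)


# ---------------------------------------------------- regression test bench


def simulate_regression_dataset(
    n_introns: int = 100,
    n_enhancers: int = 20,
    n_repressors: int = 20,
    n_null_factors: int = 0,
    effect: float = 1.0,
    sigma: float = 0.5,
    n_samples: int = 48,
    targets_per_factor: int = 5,
    seed: int = 0,
):
    """Direct PSI-matrix / factor-expression construction for the screen.

    Each planted factor drives ``targets_per_factor`` introns with
    standardized effect ``effect`` and residual noise ``sigma``; remaining
    introns are null. The cell-type vector alternates blocks and is
    independent of all planted activity. Returns (psi_matrix,
    factor_expression, cell_type, roles, links) with links the set of planted
    (intron, factor) pairs.
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{k:02d}" for k in range(n_samples)]
    cell_type = pd.Series([1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2), index=samples)
    factor_ids = (
        [f"enh{k:02d}" for k in range(n_enhancers)]
        + [f"rep{k:02d}" for k in range(n_repressors)]
        + [f"nul{k:02d}" for k in range(n_null_factors)]
    )
    roles = {f: ("enhancer" if f.startswith("enh") else "repressor" if f.startswith("rep") else "null")
             for f in factor_ids}
    activity = {f: rng.normal(size=n_samples) for f in factor_ids}
    psi = np.empty((n_introns, n_samples))
    links = set()
    intron_ids = [f"i{k:03d}" for k in range(n_introns)]
    planted = [f for f in factor_ids if roles[f] != "null"]
    k = 0
    for f in planted:
        sign = -1.0 if roles[f] == "enhancer" else 1.0
        for _ in range(targets_per_factor):
            if k >= n_introns:
                break
            raw = effect * sign * activity[f] + sigma * rng.normal(size=n_samples)
            psi[k] = np.clip(0.4 + 0.12 * raw, 0.0, 1.0)
            links.add((intron_ids[k], f))
            k += 1
    for row in range(k, n_introns):
        psi[row] = np.clip(0.4 + 0.05 * rng.normal(size=n_samples), 0.0, 1.0)
    psi_matrix = pd.DataFrame(psi, index=intron_ids, columns=samples)
    expr = pd.DataFrame(
        {s: np.exp(np.log(300.0) + 0.5 * np.array([activity[f][j] for f in factor_ids])) - 1.0
         for j, s in enumerate(samples)},
        index=factor_ids,
    )
    return psi_matrix, expr, cell_type, roles, links


# ----------------------------------------------------------------- export


def write_gtf(genes: dict[str, SpeciesGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes.values(), key=lambda x: x.gene_id):
            for s, e in sorted(g.exons):
                fh.write(
                    f"{g.contig}\tshortsplice\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";\n'
                )


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write the cohort as FASTA/GTF/TSV/JSON under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for sp in cohort.species:
        write_gtf(cohort.genes[sp], out / f"{sp}.gtf")
        write_fasta(cohort.genome(sp), out / f"{sp}.genome.fasta")
        write_fasta(cohort.proteome(sp), out / f"{sp}.proteome.fasta")
    cohort.counts.to_csv(out / "junction_counts.tsv", sep="\t", index=False)
    cohort.expression.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    (out / "tree.nwk").write_text(cohort.config.tree_newick + "\n")
    truth = cohort.truth
    payload = {
        "dsi_flags": truth.dsi_flags,
        "dsi_direction": truth.dsi_direction,
        "factor_roles": truth.factor_roles,
        "factor_targets": truth.factor_targets,
        "intron_birth_age": truth.intron_birth_age,
        "gene_has_orthologs": truth.gene_has_orthologs,
        "presence": truth.presence,
        "deg_flags": truth.deg_flags,
        "deg_log2fc": truth.deg_log2fc,
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    truth.true_psi.to_csv(out / "true_psi.tsv", sep="\t", index_label="intron_id")
    pd.Series(truth.factor_roles, name="role").rename_axis("factor_id").to_csv(
        out / "factors.tsv", sep="\t"
    )
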