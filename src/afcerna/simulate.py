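"""Synthetic cohort generator for the full pipeline.

Emulates a three-group atrial-rhythm cohort (SR/SR, AF/SR, AF/AF) with:

* planted co-expression modules driven by per-sample latent factors, with
  configurable within-module correlation and trait effects that shift a
  module's factor in exactly one contrast (susceptibility shifts both AF
  groups relative to SR/SR; persistence shifts only AF/AF);
* negative-binomial RNA-seq counts with a gene-wise dispersion that decays
  with the mean, plus sex, batch and sequencing-depth nuisance factors for
  the surrogate-variable stage to find;
* a miRNA-target database with planted lncRNA-mRNA ceRNA pairs sharing an
  exact number of miRNAs, against an annotated background whose random
  overlaps are calibrated to stay below the hypergeometric selection rule;
* a planted hub lncRNA wired (shared miRNAs plus second-layer functional
  edges) to a majority of the seed disease genes;
* a continuous-valued, batch-shifted independent test cohort drawn from the
  AF/AF and SR/SR generative settings, mimicking cross-platform heterogeneity;
* gene sets (GMT-style) and the ground-truth needed by tests.

Latent factors are mean-centered within each rhythm group before the
configured shifts are added, so planted effects are exact rather than
sampled: the designated contrast carries precisely the configured mean shift
and the other contrast carries none.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cerna import MiRNATargetDB

__all__ = ["SimulationConfig", "SyntheticDataset", "generate_dataset"]

GROUP_ORDER = ("SR/SR", "AF/SR", "AF/AF")
CONTRAST_SHIFTS = {
    # rhythm group -> multiplier applied to the configured effect
    "susceptibility": {"SR/SR": 0.0, "AF/SR": 1.0, "AF/AF": 1.0},
    "persistence": {"SR/SR": 0.0, "AF/SR": 0.0, "AF/AF": 1.0},
}


def _default_groups() -> dict[str, int]:
    return {"SR/SR": 43, "AF/SR": 74, "AF/AF": 118}


def _default_effects() -> dict[int, tuple[str, float]]:
    return {
        1: ("susceptibility", 0.96),
        2: ("susceptibility", 0.77),
        3: ("persistence", 3.0),
        4: ("persistence", -1.32),
    }


def _default_test_groups() -> dict[str, int]:
    return {"SR/SR": 19, "AF/AF": 19}


@dataclass
class SimulationConfig:
    """All generator knobs; the defaults are the study conditions."""

    n_samples_per_group: dict[str, int] = field(default_factory=_default_groups)
    n_genes: int = 5000
    n_lncrna: int | None = None  # default: 9% of n_genes
    n_modules: int = 6
    module_size: int | None = None  # default: min(150, n_genes // (2 * n_modules))
    module_base_cor: float = 0.75
    trait_module_effects: dict[int, tuple[str, float]] = field(
        default_factory=_default_effects
    )
    signal_scale: float = 1.4  # log2 units per latent-factor SD
    base_log2_mean: float = 6.0
    base_log2_sd: float = 1.5
    nb_dispersion: float = 0.02
    nb_dispersion_trend: float = 2.0  # dispersion = nb_dispersion + trend / mean
    sex_effect_sd: float = 0.1
    batch_effect_sd: float = 0.8
    depth_effect_sd: float = 0.4
    n_mirnas: int = 1000
    lnc_target_size: int = 8
    mrna_target_size: int = 7
    lnc_annot_prob: float = 0.4
    mrna_annot_prob: float = 0.15
    planted_cerna_pairs: list[tuple[str, str, int]] | str = "auto"
    planted_shared: int = 7
    pairs_per_module: int = 10
    hub_partner_count: int = 8
    n_seed_genes: int = 20
    layer2_random_edges: int = 1200
    layer2_planted_edges: int = 300
    hub_layer2_seed_edges: int = 6
    batch_shift: float = 1.0
    batch_confound: float = 1.0
    test_scale: float = 0.25  # microarray-like dynamic-range compression
    test_noise_sd: float = 0.3
    n_test_per_group: dict[str, int] = field(default_factory=_default_test_groups)
    n_gene_sets: int = 20
    rng_seed: int = 0

    @property
    def resolved_n_lncrna(self) -> int:
        return self.n_lncrna if self.n_lncrna is not None else round(0.09 * self.n_genes)

    @property
    def resolved_module_size(self) -> int:
        if self.module_size is not None:
            return self.module_size
        return max(3, min(150, self.n_genes // (2 * self.n_modules)))

    def validate(self) -> None:
        for name, val in (
            ("n_genes", self.n_genes),
            ("n_modules", self.n_modules),
            ("n_mirnas", self.n_mirnas),
            ("n_seed_genes", self.n_seed_genes),
        ):
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        if any(v <= 0 for v in self.n_samples_per_group.values()):
            raise ValueError("sample counts must be positive")
        if not 0.0 < self.module_base_cor < 1.0:
            raise ValueError("module_base_cor must lie in (0, 1)")
        if self.n_modules * self.resolved_module_size > self.n_genes:
            raise ValueError("module count exceeds gene capacity")
        for m, (contrast, effect) in self.trait_module_effects.items():
            if contrast not in CONTRAST_SHIFTS:
                raise ValueError(f"unknown contrast for module {m}: {contrast}")
            if not math.isfinite(effect):
                raise ValueError(f"non-finite effect for module {m}")
            if not 1 <= m <= self.n_modules:
                raise ValueError(f"trait module {m} outside 1..{self.n_modules}")


@dataclass
class SyntheticDataset:
    """All pipeline inputs plus the planted ground truth."""

    train_counts: pd.DataFrame  # genes x samples, nonnegative integers
    phenotypes: pd.DataFrame  # samples x (rhythm, sex, batch)
    biotypes: pd.Series  # gene -> lncRNA/mRNA
    mirna_db: MiRNATargetDB
    layer2_edges: pd.DataFrame  # gene_a, gene_b, weight
    seed_genes: list[str]
    test_expression: pd.DataFrame  # genes x test samples, continuous
    test_phenotypes: pd.DataFrame
    gene_sets: dict[str, frozenset]
    truth: dict

    def write_all(self, out_dir) -> None:
        from . import io

        io.write_expression_tsv(self.train_counts, f"{out_dir}/train_counts.tsv")
        io.write_phenotype_tsv(self.phenotypes, f"{out_dir}/phenotypes.tsv")
        io.write_biotypes_tsv(self.biotypes, f"{out_dir}/biotypes.tsv")
        io.write_mirna_targets_tsv(self.mirna_db, f"{out_dir}/mirna_targets.tsv")
        io.write_edges_tsv(self.layer2_edges, f"{out_dir}/layer2_edges.tsv")
        io.write_gene_list(self.seed_genes, f"{out_dir}/seed_genes.txt")
        io.write_expression_tsv(self.test_expression, f"{out_dir}/test_expression.tsv")
        io.write_phenotype_tsv(self.test_phenotypes, f"{out_dir}/test_phenotypes.tsv")
        io.write_gmt(self.gene_sets, f"{out_dir}/gene_sets.gmt")
        io.write_json(self.truth, f"{out_dir}/truth.json")


def _centered_factor(rng, rhythm: np.ndarray, shift: dict[str, float]) -> np.ndarray:
    """Standard-normal factor, mean-centered within each rhythm group, plus the
    configured per-group shift (exact planted effects)."""
    z = rng.standard_normal(rhythm.size)
    f = z.copy()
    for g in np.unique(rhythm):
        mask = rhythm == g
        f[mask] -= z[mask].mean()
        f[mask] += shift.get(g, 0.0)
    return f


def _group_shift(contrast: str, effect: float) -> dict[str, float]:
    return {g: m * effect for g, m in CONTRAST_SHIFTS[contrast].items()}


def _draw_disjoint(rng, pool: np.ndarray, exclude: set, size: int) -> list[str]:
    avail = np.array([m for m in pool if m not in exclude])
    if avail.size < size:
        raise ValueError("miRNA pool exhausted while planting targets")
    return list(rng.choice(avail, size=size, replace=False))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full synthetic study; bitwise-deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    c = config.module_base_cor
    a = config.signal_scale
    K = config.n_modules
    msize = config.resolved_module_size
    n_lnc = config.resolved_n_lncrna

    # ---- samples ---------------------------------------------------------
    groups = [g for g in GROUP_ORDER if g in config.n_samples_per_group]
    rhythm = np.concatenate(
        [[g] * config.n_samples_per_group[g] for g in groups]
    )
    n_samples = rhythm.size
    sample_ids = [f"T{i + 1:04d}" for i in range(n_samples)]
    sex = np.where(rng.integers(0, 2, n_samples) == 1, "M", "F")
    batch = np.where(rng.integers(0, 2, n_samples) == 1, "B2", "B1")
    phenotypes = pd.DataFrame(
        {"rhythm": rhythm, "sex": sex, "batch": batch}, index=pd.Index(sample_ids, name="sample_id")
    )

    # ---- gene table ------------------------------------------------------
    lnc_per_module = min(
        max(1, round(msize * n_lnc / config.n_genes)), max(1, n_lnc // K)
    )
    gene_ids: list[str] = []
    biotype_list: list[str] = []
    module_labels: list[int] = []
    lnc_i = pcg_i = 0
    for m in range(1, K + 1):
        for _ in range(lnc_per_module):
            lnc_i += 1
            gene_ids.append(f"LNC{lnc_i:05d}")
            biotype_list.append("lncRNA")
            module_labels.append(m)
        for _ in range(msize - lnc_per_module):
            pcg_i += 1
            gene_ids.append(f"PCG{pcg_i:05d}")
            biotype_list.append("mRNA")
            module_labels.append(m)
    n_bg = config.n_genes - K * msize
    n_bg_lnc = max(0, n_lnc - K * lnc_per_module)
    n_bg_lnc = min(n_bg_lnc, n_bg)
    for _ in range(n_bg_lnc):
        lnc_i += 1
        gene_ids.append(f"LNC{lnc_i:05d}")
        biotype_list.append("lncRNA")
        module_labels.append(0)
    for _ in range(n_bg - n_bg_lnc):
        pcg_i += 1
        gene_ids.append(f"PCG{pcg_i:05d}")
        biotype_list.append("mRNA")
        module_labels.append(0)
    genes = pd.Index(gene_ids, name="gene_id")
    biotypes = pd.Series(biotype_list, index=genes, name="biotype")
    modules = pd.Series(module_labels, index=genes, name="module")
    module_genes = {m: list(genes[modules == m]) for m in range(1, K + 1)}

    # ---- latent factors and log-scale expression -------------------------
    factors = {}
    for m in range(1, K + 1):
        if m in config.trait_module_effects:
            contrast, effect = config.trait_module_effects[m]
            shift = _group_shift(contrast, effect)
        else:
            shift = {}
        factors[m] = _centered_factor(rng, rhythm, shift)

    x = rng.standard_normal((config.n_genes, n_samples)) * math.sqrt(1.0 - c)
    for m in range(1, K + 1):
        rows = (modules == m).to_numpy()
        x[rows] += math.sqrt(c) * factors[m]
    bg_rows = (modules == 0).to_numpy()
    x[bg_rows] /= math.sqrt(1.0 - c)  # background genes: pure unit-variance noise

    # ---- planted ceRNA structure (needs gene lists, not expression) ------
    mirnas = np.array([f"MIR{i + 1:04d}" for i in range(config.n_mirnas)])
    planted: list[tuple[str, str, int]]
    hub = None
    if config.planted_cerna_pairs == "auto":
        planted = []
        persistence = [
            (m, e) for m, (ctr, e) in config.trait_module_effects.items()
            if ctr == "persistence"
        ]
        if persistence:
            hub_module = max(persistence, key=lambda me: abs(me[1]))[0]
        elif config.trait_module_effects:
            hub_module = max(
                config.trait_module_effects,
                key=lambda m: abs(config.trait_module_effects[m][1]),
            )
        else:
            hub_module = 1
        for m in range(1, K + 1):
            lncs = [g for g in module_genes[m] if biotypes[g] == "lncRNA"]
            mrnas = [g for g in module_genes[m] if biotypes[g] == "mRNA"]
            if not lncs or not mrnas:
                continue
            budget = min(config.pairs_per_module, len(mrnas))
            mr_iter = iter(mrnas)
            if m == hub_module:
                hub = lncs[0]
                for _ in range(min(config.hub_partner_count, budget)):
                    planted.append((hub, next(mr_iter), config.planted_shared))
                rest = lncs[1:] or [hub]
                i = 0
                while len([p for p in planted if p[0] in lncs]) < budget:
                    try:
                        planted.append((rest[i % len(rest)], next(mr_iter), config.planted_shared))
                    except StopIteration:
                        break
                    i += 1
            else:
                use = lncs[: max(1, min(5, len(lncs)))]
                i = 0
                added = 0
                while added < budget:
                    try:
                        planted.append((use[i % len(use)], next(mr_iter), config.planted_shared))
                    except StopIteration:
                        break
                    i += 1
                    added += 1
    else:
        planted = [tuple(p) for p in config.planted_cerna_pairs]
        known = set(genes)
        for lnc, mr, t in planted:
            if lnc not in known or mr not in known:
                raise ValueError(f"planted pair references unknown gene: {(lnc, mr)}")
            if biotypes[lnc] != "lncRNA" or biotypes[mr] != "mRNA":
                raise ValueError(f"planted pair has wrong biotypes: {(lnc, mr)}")

    # assign miRNA targets so each planted pair shares exactly t miRNAs
    lnc_targets: dict[str, set] = {}
    mrna_targets: dict[str, set] = {}
    by_lnc: dict[str, list[tuple[str, int]]] = {}
    for lnc, mr, t in planted:
        by_lnc.setdefault(lnc, []).append((mr, t))
    for lnc in sorted(by_lnc):
        pairs = by_lnc[lnc]
        tmax = max(t for _, t in pairs)
        shared = _draw_disjoint(rng, mirnas, set(), tmax)
        extra_n = max(0, config.lnc_target_size - tmax)
        targets = set(shared) | set(
            _draw_disjoint(rng, mirnas, set(shared), extra_n)
        )
        lnc_targets[lnc] = targets
        for mr, t in pairs:
            mt = set(shared[:t])
            extra_m = max(0, config.mrna_target_size - t)
            if extra_m:
                mt |= set(_draw_disjoint(rng, mirnas, targets, extra_m))
            if mr in mrna_targets:
                raise ValueError(f"mRNA {mr} planted in more than one pair")
            mrna_targets[mr] = mt
    for g in genes:  # background annotation
        if biotypes[g] == "lncRNA" and g not in lnc_targets:
            if rng.random() < config.lnc_annot_prob:
                lnc_targets[g] = set(
                    rng.choice(mirnas, size=config.lnc_target_size, replace=False)
                )
        elif biotypes[g] == "mRNA" and g not in mrna_targets:
            if rng.random() < config.mrna_annot_prob:
                mrna_targets[g] = set(
                    rng.choice(mirnas, size=config.mrna_target_size, replace=False)
                )
    db = MiRNATargetDB(
        {g: frozenset(s) for g, s in lnc_targets.items()},
        {g: frozenset(s) for g, s in mrna_targets.items()},
    )

    # ---- seed disease genes ---------------------------------------------
    trait_mods = set(config.trait_module_effects)
    hub_partners = [mr for lnc, mr, _ in planted if hub is not None and lnc == hub]
    pool = list(hub_partners)
    trait_mrnas = [
        mr for _, mr, _ in planted
        if int(modules[mr]) in trait_mods and mr not in pool
    ]
    other_mrnas = [mr for _, mr, _ in planted if mr not in pool and mr not in trait_mrnas]
    pool += list(rng.permutation(trait_mrnas)) + list(rng.permutation(other_mrnas))
    all_mrnas = [g for g in genes if biotypes[g] == "mRNA" and g not in pool]
    pool += list(rng.permutation(np.array(all_mrnas)))
    seed_genes = pool[: config.n_seed_genes]

    # ---- second-layer functional interaction edges ------------------------
    edge_set: set[frozenset] = set()
    rows = []

    def add_edge(u, v, w):
        key = frozenset((u, v))
        if u == v or key in edge_set:
            return
        edge_set.add(key)
        rows.append((u, v, w))

    if hub is not None:
        wired = 0
        for s in seed_genes:
            if wired >= config.hub_layer2_seed_edges:
                break
            if s not in hub_partners and s != hub:
                add_edge(hub, s, round(float(rng.uniform(0.8, 1.0)), 4))
                wired += 1
    planted_nodes = sorted({g for lnc, mr, _ in planted for g in (lnc, mr)})
    if len(planted_nodes) >= 2:
        for _ in range(config.layer2_planted_edges):
            u, v = rng.choice(planted_nodes, size=2, replace=False)
            add_edge(u, v, round(float(rng.uniform(0.5, 1.0)), 4))
    for _ in range(config.layer2_random_edges):
        u, v = rng.choice(genes.to_numpy(), size=2, replace=False)
        add_edge(u, v, round(float(rng.uniform(0.5, 1.0)), 4))
    layer2 = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])

    # ---- counts ----------------------------------------------------------
    b = rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_genes)
    special = set(seed_genes) | set(g for p in planted for g in p[:2])
    if hub is not None:
        special.add(hub)
    special_rows = genes.isin(special)
    b[special_rows] = np.maximum(b[special_rows], config.base_log2_mean)

    batch_ind = (batch == "B2").astype(float)
    depth = rng.standard_normal(n_samples)
    sex_ind = (sex == "M").astype(float)
    l_batch = rng.normal(0.0, config.batch_effect_sd, config.n_genes)
    l_depth = rng.normal(0.0, config.depth_effect_sd, config.n_genes)
    l_sex = rng.normal(0.0, config.sex_effect_sd, config.n_genes)

    log_mu = (
        b[:, None]
        + a * x
        + l_batch[:, None] * batch_ind
        + l_depth[:, None] * depth
        + l_sex[:, None] * sex_ind
    )
    mu = np.exp2(np.clip(log_mu, -10.0, 20.0))
    disp = config.nb_dispersion + config.nb_dispersion_trend / mu
    r_nb = 1.0 / disp
    p_nb = r_nb / (r_nb + mu)
    counts = rng.negative_binomial(r_nb, p_nb).astype(np.int64)
    train_counts = pd.DataFrame(counts, index=genes, columns=sample_ids)

    # ---- independent test cohort (continuous, batch-shifted) --------------
    t_groups = [g for g in GROUP_ORDER if g in config.n_test_per_group]
    t_rhythm = np.concatenate([[g] * config.n_test_per_group[g] for g in t_groups])
    n_test = t_rhythm.size
    test_ids = [f"V{i + 1:04d}" for i in range(n_test)]
    t_factors = {}
    for m in range(1, K + 1):
        if m in config.trait_module_effects:
            contrast, effect = config.trait_module_effects[m]
            shift = _group_shift(contrast, effect)
        else:
            shift = {}
        t_factors[m] = _centered_factor(rng, t_rhythm, shift)
    xt = rng.standard_normal((config.n_genes, n_test)) * math.sqrt(1.0 - c)
    for m in range(1, K + 1):
        xt[(modules == m).to_numpy()] += math.sqrt(c) * t_factors[m]
    xt[bg_rows] /= math.sqrt(1.0 - c)

    delta = np.zeros(config.n_genes)  # expected AF/AF-minus-SR/SR log2 shift
    for m, (contrast, effect) in config.trait_module_effects.items():
        delta[(modules == m).to_numpy()] = a * math.sqrt(c) * effect
    loc_shift = rng.normal(0.0, config.batch_shift, config.n_genes)
    loc_shift -= config.batch_confound * delta
    scale_shift = config.test_scale * np.exp(rng.normal(0.0, 0.1, config.n_genes))
    test_vals = (
        b[:, None]
        + loc_shift[:, None]
        + scale_shift[:, None] * (a * xt)
        + rng.normal(0.0, config.test_noise_sd, (config.n_genes, n_test))
    )
    test_expression = pd.DataFrame(test_vals, index=genes, columns=test_ids)
    test_phenotypes = pd.DataFrame(
        {
            "rhythm": t_rhythm,
            "sex": np.where(rng.integers(0, 2, n_test) == 1, "M", "F"),
            "batch": "B3",
        },
        index=pd.Index(test_ids, name="sample_id"),
    )

    # ---- gene sets -------------------------------------------------------
    gene_sets: dict[str, frozenset] = {}
    for m in range(1, K + 1):
        size = min(40, len(module_genes[m]))
        gene_sets[f"GS_MODULE{m}"] = frozenset(
            rng.choice(module_genes[m], size=size, replace=False)
        )
    for i in range(config.n_gene_sets):
        size = int(rng.integers(15, 121))
        size = min(size, config.n_genes)
        gene_sets[f"GS_RAND{i + 1:03d}"] = frozenset(
            rng.choice(genes.to_numpy(), size=size, replace=False)
        )

    truth = {
        "module_labels": {g: int(m) for g, m in modules.items()},
        "latent_factors": {str(m): factors[m].tolist() for m in factors},
        "test_latent_factors": {str(m): t_factors[m].tolist() for m in t_factors},
        "trait_modules": {
            str(m): [ctr, float(e)] for m, (ctr, e) in config.trait_module_effects.items()
        },
        "planted_pairs": [[lnc, mr, int(t)] for lnc, mr, t in planted],
        "hub_lncrna": hub,
        "seed_genes": list(seed_genes),
        "batch_indicator": batch_ind.tolist(),
        "depth_factor": depth.tolist(),
        "expected_af_shift_log2": {
            g: float(d) for g, d in zip(genes, delta) if d != 0.0
        },
    }

    return SyntheticDataset(
        train_counts=train_counts,
        phenotypes=phenotypes,
        biotypes=biotypes,
        mirna_db=db,
        layer2_edges=layer2,
        seed_genes=list(seed_genes),
        test_expression=test_expression,
        test_phenotypes=test_phenotypes,
        gene_sets=gene_sets,
        truth=truth,
    )
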