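"""Synthetic data with known ground truth for every pipeline stage.

Generates pure-birth species trees, win-loss matrices from latent
abilities, per-individual benefit tables with a chosen rank-benefit
correlation, and complete effect-size datasets with species/group/
phylogenetic random effects.  Every latent quantity is kept in a truth
ledger so recovery can be tested exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .dominance import InteractionMatrix, davids_scores, steepness_from_scores
from .effect_sizes import BenefitTable, benefit_category_for
from .phylo import (
    PhyloCorrelation,
    SpeciesTree,
    correlation_matrix,
    parse_newick,
)

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_tree",
    "simulate_matrix",
    "simulate_benefits",
    "simulate_effect_records",
    "simulate_dataset",
    "write_dataset",
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_species: int = 10
    groups_per_species: int = 2
    records_per_group: int = 1
    n_individuals: int = 5  # >= 4
    n_individuals_max: int | None = 9  # per-group N ~ U{n_individuals..max}
    delta_max: float = 3.0  # per-group ability dispersion ~ U(0, delta_max)
    mu_interactions: float = 15.0  # Poisson mean of per-dyad interaction counts
    mu_z: float = 0.2  # true mean effect on the Fisher-Z scale
    beta_steep: float = 0.0  # coefficient of standardized steepness
    sigma2_species: float = 0.05
    sigma2_group: float = 0.02
    sigma2_phylo: float = 0.02
    benefit_type_probs: tuple[float, float, float, float] = (0.2, 0.1, 0.3, 0.4)
    p_published: float = 0.5
    p_female: float = 0.5  # remainder split between male and both

    def __post_init__(self):
        if self.n_individuals < 4:
            raise ValueError("N >= 4 individuals per group required")
        if self.mu_interactions <= 0:
            raise ValueError("mu_interactions must be positive")
        for s2 in (self.sigma2_species, self.sigma2_group, self.sigma2_phylo):
            if s2 < 0:
                raise ValueError("variance components must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_BENEFIT_TYPES = ("fecundity", "infant_survival", "mating_success", "feeding_success")
_SETTINGS = ("wild", "provisioned", "captive")
_DISPERSAL = ("female_philopatry", "male_philopatry", "none")
_SOCIAL_ORG = ("OMG", "MMG", "MLS")


class _Node:
    __slots__ = ("children", "time", "label")

    def __init__(self, time: float, label: str | None = None):
        self.children: list[_Node] = []
        self.time = time
        self.label = label


def _newick(node: _Node, parent_time: float, total: float) -> str:
    if not node.children:
        return f"{node.label}:{(total - parent_time) / total:.10f}"
    inner = ",".join(_newick(ch, node.time, total) for ch in node.children)
    return f"({inner}):{(node.time - parent_time) / total:.10f}"


def simulate_tree(n_species: int, seed=None) -> SpeciesTree:
    """Pure-birth (Yule, rate 1) tree rescaled to depth 1, tips sp1..spS."""
    if n_species < 2:
        raise ValueError("at least 2 species required")
    rng = np.random.default_rng(seed)
    root = _Node(0.0)
    tips = [_Node(0.0), _Node(0.0)]
    root.children = list(tips)
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        idx = rng.integers(len(tips))
        parent = tips.pop(idx)
        parent.time = t
        parent.children = [_Node(t), _Node(t)]
        tips.extend(parent.children)
    total = t + rng.exponential(1.0 / n_species)
    for i, tip in enumerate(tips):
        tip.time = total
    # label tips in left-to-right (newick) order for reproducibility
    counter = [0]

    def label(node: _Node):
        if not node.children:
            counter[0] += 1
            node.label = f"sp{counter[0]}"
        for ch in node.children:
            label(ch)

    label(root)
    inner = ",".join(_newick(ch, 0.0, total) for ch in root.children)
    return parse_newick(f"({inner});")


def latent_abilities(n: int, delta: float) -> np.ndarray:
    """Equally spaced abilities delta * (N-1-2i)/2, i = 0..N-1 (sum 0)."""
    return delta * (n - 1 - 2 * np.arange(n)) / 2.0


def simulate_matrix(
    n: int, delta: float, mu: float, seed=None, prefix: str = "ind"
) -> tuple[InteractionMatrix, np.ndarray]:
    """Win-loss matrix from logistic contests on an ability grid.

    n_ij ~ Poisson(mu) per dyad and s_ij ~ Binomial(n_ij,
    logistic(a_i - a_j)).  Returns the matrix and the latent abilities.
    """
    if n < 2:
        raise ValueError("N >= 2 required")
    rng = np.random.default_rng(seed)
    a = latent_abilities(n, delta)
    counts = np.zeros((n, n), dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    n_dyad = rng.poisson(mu, size=iu.size)
    p_win = expit(a[iu] - a[ju])
    wins_i = rng.binomial(n_dyad, p_win)
    counts[iu, ju] = wins_i
    counts[ju, iu] = n_dyad - wins_i
    ids = tuple(f"{prefix}{i + 1}" for i in range(n))
    counts.setflags(write=False)
    return InteractionMatrix(ids=ids, counts=counts), a


def simulate_benefits(
    scores,
    true_r: float,
    seed=None,
    benefit_type: str = "feeding_success",
    ids=None,
) -> BenefitTable:
    """Benefits jointly normal with the standardized scores at ``true_r``."""
    if not abs(true_r) < 1:
        raise ValueError("|true_r| must be < 1")
    x = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    sd = x.std()
    xs = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    y = true_r * xs + np.sqrt(1.0 - true_r**2) * rng.normal(size=x.size)
    if ids is None:
        ids = tuple(f"ind{i + 1}" for i in range(x.size))
    return BenefitTable(ids=tuple(ids), values=y, benefit_type=benefit_type)


def _draw_moderators(rng, cfg: SimConfig) -> dict:
    bt = _BENEFIT_TYPES[rng.choice(4, p=np.asarray(cfg.benefit_type_probs))]
    u = rng.random()
    sex = "female" if u < cfg.p_female else ("male" if u < (1 + cfg.p_female) / 2 else "both")
    return {
        "benefit_type": bt,
        "setting": _SETTINGS[rng.integers(3)],
        "sex": sex,
        "duration_months": float(np.round(rng.uniform(6, 60), 1)),
    }


def _species_traits(species_index: int) -> dict:
    # cycle through trait combinations so every level occurs with >= 3 species
    return {
        "dispersal": _DISPERSAL[species_index % 3],
        "social_org": _SOCIAL_ORG[(species_index + species_index // 3) % 3],
    }


def simulate_effect_records(
    n_species: int = 40,
    groups_per_species: int = 2,
    records_per_group: int = 2,
    n: int = 30,
    sigma2: tuple[float, float, float] = (0.10, 0.05, 0.10),
    mu_z: float = 0.2,
    beta_steep: float = 0.0,
    seed=None,
    with_moderators: bool = False,
) -> tuple[pd.DataFrame, PhyloCorrelation, dict]:
    """Direct effect-size records with known meta-regression structure.

    A fast generator for calibration of the meta module: z_r ~ N(mu_z +
    beta_steep * standardized steepness + u_species + u_group + u_phylo,
    v) with v = 1/(n-3), skipping the matrix/benefit stages.  Returns
    (records frame, species correlation matrix, truth ledger).
    """
    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, rng)
    A = correlation_matrix(tree)
    s2s, s2g, s2p = sigma2
    u_s = rng.normal(0.0, np.sqrt(s2s), size=n_species)
    chol = np.linalg.cholesky(A.matrix + 1e-10 * np.eye(n_species))
    u_p = np.sqrt(s2p) * (chol @ rng.normal(size=n_species))
    rows = []
    steeps = rng.uniform(0.0, 1.0, size=n_species * groups_per_species)
    steep_std = (steeps - steeps.mean()) / steeps.std(ddof=1)
    v = 1.0 / (n - 3)
    gidx = 0
    traits = [_species_traits(si) for si in range(n_species)]
    for si, sp in enumerate(A.ids):
        for g in range(groups_per_species):
            u_g = rng.normal(0.0, np.sqrt(s2g))
            group = f"{sp}_g{g + 1}"
            for r in range(records_per_group):
                true_z = mu_z + beta_steep * steep_std[gidx] + u_s[si] + u_g + u_p[si]
                row = {
                    "record_id": f"{group}_r{r + 1}",
                    "z_r": true_z + rng.normal(0.0, np.sqrt(v)),
                    "v": v,
                    "n": n,
                    "group": group,
                    "species": sp,
                    "steepness": steeps[gidx],
                }
                if with_moderators:
                    mod = _draw_moderators(rng, SimConfig())
                    row.update(
                        benefit_category=benefit_category_for(mod["benefit_type"]),
                        duration_months=mod["duration_months"],
                        setting=mod["setting"],
                        sex=mod["sex"],
                        origin="published" if rng.random() < 0.5 else "unpublished",
                        pub_year=float(rng.integers(1980, 2022)),
                        **traits[si],
                    )
                rows.append(row)
            gidx += 1
    truth = {
        "sigma2": list(sigma2),
        "mu_z": mu_z,
        "beta_steep": beta_steep,
        "u_species": u_s.tolist(),
        "u_phylo": u_p.tolist(),
        "steepness": steeps.tolist(),
    }
    return pd.DataFrame(rows), A, truth


@dataclasses.dataclass
class SimulatedDataset:
    config: SimConfig
    tree: SpeciesTree
    table: pd.DataFrame  # one row per record
    matrices: dict[str, InteractionMatrix]  # by group id
    benefits: dict[str, BenefitTable]  # by record id
    truth: dict


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full synthetic dataset: tree, matrices, benefits, moderators, truth.

    Per group, ability dispersion delta_g ~ U(0, delta_max) induces a real
    steepness gradient; each record's true Fisher-Z is mu_z + beta_steep *
    (standardized group NDS steepness) + species + group + phylogenetic
    random effects, and benefits are drawn conditional on the true latent
    abilities at correlation tanh(true Z).
    """
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_tree(cfg.n_species, rng)
    A = correlation_matrix(tree)
    u_s = rng.normal(0.0, np.sqrt(cfg.sigma2_species), size=cfg.n_species)
    chol = np.linalg.cholesky(A.matrix + 1e-10 * np.eye(cfg.n_species))
    u_p = np.sqrt(cfg.sigma2_phylo) * (chol @ rng.normal(size=cfg.n_species))

    groups = []
    matrices: dict[str, InteractionMatrix] = {}
    abilities: dict[str, np.ndarray] = {}
    for si, sp in enumerate(A.ids):
        traits = _species_traits(si)
        for g in range(cfg.groups_per_species):
            group = f"{sp}_g{g + 1}"
            delta = float(rng.uniform(0.0, cfg.delta_max))
            if cfg.n_individuals_max and cfg.n_individuals_max > cfg.n_individuals:
                n_group = int(rng.integers(cfg.n_individuals, cfg.n_individuals_max + 1))
            else:
                n_group = cfg.n_individuals
            m, a = simulate_matrix(n_group, delta, cfg.mu_interactions, rng)
            steep = steepness_from_scores(davids_scores(m)).estimate
            groups.append(
                {
                    "group": group,
                    "species": sp,
                    "species_index": si,
                    "delta": delta,
                    "nds_steepness": steep,
                    "u_group": float(rng.normal(0.0, np.sqrt(cfg.sigma2_group))),
                    **traits,
                }
            )
            matrices[group] = m
            abilities[group] = a
    steeps = np.array([g["nds_steepness"] for g in groups])
    ssd = steeps.std(ddof=1)
    if cfg.beta_steep != 0.0 and (ssd == 0 or np.unique(steeps).size < 2):
        import warnings

        warnings.warn(
            "fewer than 2 distinct steepness values: beta_steep unidentifiable",
            RuntimeWarning,
        )
        steep_std = np.zeros_like(steeps)
    else:
        steep_std = (steeps - steeps.mean()) / (ssd if ssd > 0 else 1.0)

    rows = []
    benefits: dict[str, BenefitTable] = {}
    rec_truth = []
    for gi, g in enumerate(groups):
        mod_base = {k: g[k] for k in ("dispersal", "social_org")}
        for r in range(cfg.records_per_group):
            rec_id = f"{g['group']}_r{r + 1}"
            mod = _draw_moderators(rng, cfg)
            true_z = (
                cfg.mu_z
                + cfg.beta_steep * steep_std[gi]
                + u_s[g["species_index"]]
                + g["u_group"]
                + u_p[g["species_index"]]
            )
            true_r = float(np.tanh(true_z))
            bt = simulate_benefits(
                abilities[g["group"]],
                true_r,
                rng,
                benefit_type=mod["benefit_type"],
                ids=matrices[g["group"]].ids,
            )
            origin = "published" if rng.random() < cfg.p_published else "unpublished"
            rows.append(
                {
                    "record_id": rec_id,
                    "group": g["group"],
                    "species": g["species"],
                    "matrix": f"matrices/{g['group']}.csv",
                    "benefit": f"benefits/{rec_id}.csv",
                    "benefit_type": mod["benefit_type"],
                    "duration_months": mod["duration_months"],
                    "setting": mod["setting"],
                    "sex": mod["sex"],
                    "dispersal": mod_base["dispersal"],
                    "social_org": mod_base["social_org"],
                    "origin": origin,
                    "pub_year": int(rng.integers(1980, 2022)) if origin == "published" else "",
                    "n": matrices[g["group"]].n,
                }
            )
            benefits[rec_id] = bt
            rec_truth.append({"record_id": rec_id, "true_z": float(true_z), "true_r": true_r})
    truth = {
        "config": cfg.to_dict(),
        "u_species": u_s.tolist(),
        "u_phylo": u_p.tolist(),
        "groups": [
            {k: g[k] for k in ("group", "species", "delta", "nds_steepness", "u_group")}
            for g in groups
        ],
        "records": rec_truth,
    }
    return SimulatedDataset(
        config=cfg,
        tree=tree,
        table=pd.DataFrame(rows),
        matrices=matrices,
        benefits=benefits,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, path) -> Path:
    """Write a dataset directory: dataset.csv, matrices/, benefits/,
    tree.nwk and truth.json."""
    root = Path(path)
    (root / "matrices").mkdir(parents=True, exist_ok=True)
    (root / "benefits").mkdir(parents=True, exist_ok=True)
    ds.table.to_csv(root / "dataset.csv", index=False)
    for group, m in ds.matrices.items():
        m.to_dataframe().to_csv(root / "matrices" / f"{group}.csv")
    for rec_id, bt in ds.benefits.items():
        pd.DataFrame({"individual": list(bt.ids), "benefit_value": bt.values}).to_csv(
            root / "benefits" / f"{rec_id}.csv", index=False
        )
    with open(root / "tree.nwk", "w", encoding="utf-8") as fh:
        fh.write(ds.tree.as_newick() + "\n")
    with open(root / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(ds.truth, fh, indent=1)
    return root
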