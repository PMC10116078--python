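"""Synthetic landscapes, species pools, tree sets and community tables.

The generators emulate the statistical structure of a state-wide breeding-bird
point-count design: ~287 landscape units on a regular grid, each holding 3-18
local communities (mean ~7.2), a pool of ~162 species with 20 functional
traits, a set of candidate phylogenies, spatially autocorrelated unit
covariates, and abundances responding to those covariates with a tunable
specialist-loss (homogenization) mechanism.  Every generator is a pure
function of its :class:`SimulationConfig`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field as dc_field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from betascape.distances import scale_traits
from betascape.io import (
    COVARIATE_COLS,
    DIET_COLS,
    FORAGE_COLS,
    TRAIT_COLS,
    CommunityTable,
    TraitTable,
    TreeSet,
    UnitCovariates,
)
from betascape.spatial_stats import build_weights


def _default_effects() -> dict[str, float]:
    # log-abundance slope per SD of each (standardized) covariate
    return {"hfi": 0.0, "forest_loss": -0.10, "npp": 0.10,
            "habitat_div": 0.08, "mean_temp": 0.10}


@dataclass
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Defaults mirror the emulated field design: 287 units, 3-18 communities
    per unit with mean ~7.2 (sd ~2.9), 162 species, spatially autocorrelated
    covariates, 1000 candidate trees.
    """

    seed: int = 0
    n_units: int = 287
    communities_min: int = 3
    communities_max: int = 18
    communities_mean: float = 7.2
    n_species: int = 162
    rho: float = 0.6                      # covariate spatial autocorrelation
    effects: dict[str, float] = dc_field(default_factory=_default_effects)
    homogenization_strength: float = 0.02  # specialist occupancy decay per unit HFI
    homogenization_mode: str = "local"     # local (per-community) | uniform (per-unit)
    n_trees: int = 1000
    tree_perturbation: float = 0.1         # NNI probability per internal branch
    branch_jitter: float = 0.1             # lognormal sd of branch-length noise
    nb_dispersion: float = 2.0             # negative-binomial size parameter
    unit_spacing: float = 19.3             # km between unit centroids
    k_neighbors: int = 8                   # kNN graph for the SAR covariate fields

    def __post_init__(self) -> None:
        if self.n_units < 10:
            raise ValueError("n_units must be at least 10")
        if not (0 < self.communities_min <= self.communities_max):
            raise ValueError("invalid communities range")
        if not self.communities_min <= self.communities_mean <= self.communities_max:
            raise ValueError("communities_mean outside range")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if self.homogenization_mode not in ("local", "uniform"):
            raise ValueError("homogenization_mode must be 'local' or 'uniform'")
        if self.n_species < 2 or self.n_trees < 1:
            raise ValueError("need at least 2 species and 1 tree")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic generator per stream."""
        return np.random.default_rng([self.seed, stream])


def _unit_ids(n: int) -> list[str]:
    w = len(str(n))
    return [f"u{i + 1:0{w}d}" for i in range(n)]


def _species_ids(n: int) -> list[str]:
    w = len(str(n))
    return [f"sp{i + 1:0{w}d}" for i in range(n)]


def _sar_field(rng, solve_op) -> np.ndarray:
    """Standardized spatially autocorrelated field x = (I - rho W)^-1 eps."""
    x = solve_op(rng.standard_normal(solve_op.n))
    return (x - x.mean()) / x.std()


class _SarSolver:
    def __init__(self, w: np.ndarray, rho: float):
        self.n = w.shape[0]
        self._lu = np.linalg.inv(np.eye(self.n) - rho * w)

    def __call__(self, eps: np.ndarray) -> np.ndarray:
        return self._lu @ eps


def simulate_landscape(cfg: SimulationConfig) -> tuple[pd.DataFrame, UnitCovariates]:
    """Unit centroids on a near-regular grid plus spatially structured covariates.

    Covariates are SAR fields with parameter ``cfg.rho`` on the unit kNN
    graph.  HFI and forest loss load on a shared latent field with opposite
    signs, so areas of high human influence and areas of forest loss are
    spatially segregated.  HFI is clipped to [0, 100]; forest loss is a
    right-skewed percentage clipped to [0, 100].
    """
    rng = cfg.rng(0)
    n = cfg.n_units
    side = int(np.ceil(np.sqrt(n)))
    ii, jj = np.divmod(np.arange(n), side)
    coords = pd.DataFrame(
        {"x": jj * cfg.unit_spacing, "y": ii * cfg.unit_spacing},
        index=_unit_ids(n),
    )
    weights = build_weights(coords, k=cfg.k_neighbors)
    solve = _SarSolver(weights.w, cfg.rho)

    latent = _sar_field(rng, solve)
    noise = [_sar_field(rng, solve) for _ in range(6)]

    hfi_z = 0.8 * latent + 0.6 * noise[0]
    loss_z = -0.8 * latent + 0.6 * noise[1]
    hfi = np.clip(30.0 + 15.0 * hfi_z, 0.0, 100.0)
    forest_loss = np.clip(4.0 * np.exp(0.9 * loss_z), 0.0, 100.0)
    npp = np.clip(0.5 + 0.08 * noise[2], 0.05, None)
    habitat_div = np.clip(4.0 + 1.2 * noise[3], 1.0, 11.0)
    mean_temp = 4.5 + 1.5 * noise[4]

    # beta-binomial point counts: 3 + Binomial(15, p_u), p_u ~ Beta, giving
    # mean ~7.2 and sd ~2.9 on the 3-18 range
    extra_max = cfg.communities_max - cfg.communities_min
    p_mean = (cfg.communities_mean - cfg.communities_min) / extra_max
    conc = 7.33
    p_u = rng.beta(p_mean * conc, (1 - p_mean) * conc, size=n)
    n_points = cfg.communities_min + rng.binomial(extra_max, p_u)

    cov = pd.DataFrame(
        {"hfi": hfi, "forest_loss": forest_loss, "npp": npp,
         "habitat_div": habitat_div, "mean_temp": mean_temp,
         "n_points": n_points},
        index=coords.index,
    )[COVARIATE_COLS]
    return coords, UnitCovariates(cov)


# ---------------------------------------------------------------------------
# species pool
# ---------------------------------------------------------------------------

def _grid_proportions(rng, n_rows: int, n_cats: int, step_count: int) -> np.ndarray:
    """Rows of proportions on a 100/step_count grid summing to 100."""
    out = np.empty((n_rows, n_cats))
    for i in range(n_rows):
        conc = rng.uniform(0.2, 1.5)
        probs = rng.dirichlet(np.full(n_cats, conc))
        out[i] = rng.multinomial(step_count, probs) * (100 // step_count)
    return out


def _random_nni(tree: dendropy.Tree, rng: np.random.Generator, prob: float) -> None:
    """Apply nearest-neighbour-interchange moves, each internal branch with
    probability ``prob``."""
    internal = [nd for nd in tree.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()]
    for v in internal:
        if rng.random() >= prob:
            continue
        u = v.parent_node
        siblings = [c for c in u.child_nodes() if c is not v]
        children = v.child_nodes()
        if not siblings or len(children) < 2:
            continue
        s = siblings[rng.integers(len(siblings))]
        c = children[rng.integers(len(children))]
        u.remove_child(s)
        v.remove_child(c)
        u.add_child(c)
        v.add_child(s)


def simulate_species_pool(
    cfg: SimulationConfig, *, return_base_tree: bool = False,
):
    """Trait table plus a set of noisy candidate phylogenies.

    Traits: 10 diet proportions summing to 100 in 10-unit steps, 8
    foraging-stratum proportions summing to 100, an activity-time ordinal in
    20-unit steps (skewed towards fully diurnal), and log-normal body mass.
    Phylogeny: a Yule tree over the pool, plus ``cfg.n_trees`` variants
    obtained by random NNI moves and multiplicative branch-length jitter, so
    consensus building is exercised nontrivially.
    """
    rng = cfg.rng(1)
    n = cfg.n_species
    ids = _species_ids(n)

    diet = _grid_proportions(rng, n, 10, 10)
    forage = _grid_proportions(rng, n, 8, 10)
    activity = rng.choice([0, 20, 40, 60, 80, 100], size=n,
                          p=[0.02, 0.03, 0.05, 0.10, 0.20, 0.60])
    mass = np.round(np.exp(rng.normal(np.log(30.0), 1.0, size=n)), 2)
    traits = pd.DataFrame(
        np.column_stack([diet, forage, activity, mass]),
        index=pd.Index(ids, name="species_id"), columns=TRAIT_COLS,
    )
    trait_table = TraitTable(traits)

    pyrng = random.Random(int(rng.integers(2**31)))
    base = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, rng=pyrng,
    )
    taxa = dendropy.TaxonNamespace(ids)
    order = rng.permutation(n)
    for leaf, j in zip(base.leaf_node_iter(), order):
        leaf.taxon = taxa.get_taxon(ids[j])
    base.taxon_namespace = taxa

    trees = dendropy.TreeList(taxon_namespace=taxa)
    for _ in range(cfg.n_trees):
        t = base.clone(depth=1)
        if cfg.tree_perturbation > 0:
            _random_nni(t, rng, cfg.tree_perturbation)
        if cfg.branch_jitter > 0:
            for edge in t.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= float(np.exp(rng.normal(0.0, cfg.branch_jitter)))
        trees.append(t)
    tree_set = TreeSet(trees)
    if return_base_tree:
        return trait_table, tree_set, base
    return trait_table, tree_set


# ---------------------------------------------------------------------------
# communities
# ---------------------------------------------------------------------------

def simulate_communities(
    cfg: SimulationConfig,
    landscape: tuple[pd.DataFrame, UnitCovariates],
    pool,
) -> CommunityTable:
    """Negative-binomial point-count communities responding to the landscape.

    Each species gets a specialism score (trait-space distance from the pool
    centroid, scaled to [0, 1]).  Expected log-abundance per community is a
    species baseline plus covariate effects plus a unit random effect.
    Specialist occupancy decays with unit HFI at ``homogenization_strength``:
    in "local" mode the decay thins each community independently (eroding
    alpha while the unit-level pool, hence gamma, is comparatively spared);
    in "uniform" mode whole-unit presence decays (eroding alpha and gamma
    together, shrinking compositional differences among communities).
    """
    rng = cfg.rng(2)
    coords, covariates = landscape
    traits = pool[0]
    cov = covariates.table
    ids = traits.species_ids
    n_sp = len(ids)

    scaled = scale_traits(traits)
    centroid = scaled.mean(axis=0)
    spec = np.linalg.norm(scaled.to_numpy() - centroid.to_numpy(), axis=1)
    spec = spec / spec.max()

    base_logab = rng.normal(np.log(0.6), 1.0, size=n_sp)
    base_occ = 1.0 / (1.0 + np.exp(-rng.normal(0.0, 1.0, size=n_sp)))

    z = {}
    for name in cfg.effects:
        col = cov[name].to_numpy(dtype=float)
        z[name] = (col - col.mean()) / (col.std() or 1.0)

    records = {}
    unit_of = {}
    comm_xy = {}
    comm_dates = {}
    k_nb = cfg.nb_dispersion
    h = cfg.homogenization_strength

    for u_idx, unit in enumerate(cov.index):
        hfi_u = cov.at[unit, "hfi"]
        re_u = rng.normal(0.0, 0.3)
        eta = base_logab + re_u
        for name, slope in cfg.effects.items():
            eta = eta + slope * z[name][u_idx]
        mu = np.exp(eta)

        retain = np.exp(-h * spec * hfi_u)  # specialist decay with HFI
        if cfg.homogenization_mode == "uniform":
            present_unit = rng.random(n_sp) < base_occ * retain
        else:
            present_unit = rng.random(n_sp) < base_occ

        n_comm = int(cov.at[unit, "n_points"])
        for c in range(n_comm):
            cid = f"{unit}_p{c + 1:02d}"
            occ = present_unit.copy()
            if cfg.homogenization_mode == "local" and h > 0:
                occ = occ & (rng.random(n_sp) < retain)
            counts = np.zeros(n_sp, dtype=int)
            for _ in range(10):
                lam = mu * occ
                counts = rng.negative_binomial(k_nb, k_nb / (k_nb + lam + 1e-12))
                counts[~occ] = 0
                if counts.sum() > 0:
                    break
            if counts.sum() == 0:
                counts[int(np.argmax(mu))] = 1  # force the most common species
            records[cid] = counts
            unit_of[cid] = unit
            half = cfg.unit_spacing / 2.0
            comm_xy[cid] = (
                coords.at[unit, "x"] + rng.uniform(-half, half),
                coords.at[unit, "y"] + rng.uniform(-half, half),
            )
            comm_dates[cid] = int(rng.integers(150, 191))  # late May - early July

    abundance = pd.DataFrame.from_dict(records, orient="index", columns=ids)
    abundance.index.name = "community_id"
    return CommunityTable(
        abundance=abundance,
        unit_of=pd.Series(unit_of, name="unit_id").reindex(abundance.index),
        unit_coords=coords,
        community_coords=pd.DataFrame.from_dict(comm_xy, orient="index", columns=["x", "y"]),
        dates=pd.Series(comm_dates, name="date"),
    )


def simulate_dataset(cfg: SimulationConfig) -> dict:
    """Run all three generators; returns a dict with coords, covariates,
    traits, trees, base_tree and communities."""
    coords, covariates = simulate_landscape(cfg)
    traits, trees, base = simulate_species_pool(cfg, return_base_tree=True)
    communities = simulate_communities(cfg, (coords, covariates), (traits, trees))
    return {
        "coords": coords, "covariates": covariates, "traits": traits,
        "trees": trees, "base_tree": base, "communities": communities,
    }
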