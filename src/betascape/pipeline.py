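"""End-to-end orchestration: filters -> distances -> diversity -> models.

A complete run fits the six-predictor model (hfi, forest_loss, npp,
habitat_div, mean_temp, n_points) to each of nine responses (3 facets x
alpha/beta/gamma) through the residual-diagnostics model chooser, after a
VIF screen, and collects everything in a :class:`RunReport`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from betascape.distances import (
    functional_distance,
    majority_consensus,
    phylo_distance,
    scale_traits,
    taxonomic_distance,
)
from betascape.diversity import partition_all
from betascape.io import COVARIATE_COLS, CommunityTable, check_species_order
from betascape.spatial_stats import ModelResult, build_weights, select_and_fit, vif

logger = logging.getLogger(__name__)

PREDICTORS = COVARIATE_COLS  # hfi, forest_loss, npp, habitat_div, mean_temp, n_points
LEVELS = {"alpha": "alpha_eqv", "gamma": "gamma_eqv", "beta": "beta_prop"}


class VifScreenError(RuntimeError):
    """Raised when the multicollinearity screen fails; carries the report."""

    def __init__(self, vifs: pd.Series, threshold: float):
        self.vifs = vifs
        super().__init__(
            f"VIF screen failed (threshold {threshold}):\n{vifs.to_string()}"
        )


@dataclass
class RunReport:
    """Everything a complete analysis run produced."""

    models: dict[str, ModelResult]
    diversity: pd.DataFrame
    vifs: pd.Series
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        parts = [m.summary() for m in self.models.values()]
        return ("\n" + "-" * 70 + "\n").join(parts)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.diversity.to_csv(out / "diversity.csv", index=False)
        meta = dict(self.metadata)
        meta["vif"] = {k: float(v) for k, v in self.vifs.items()}
        meta["models"] = {}
        for name, m in self.models.items():
            m.coef_table().to_csv(out / f"coef_{name}.csv", index_label="term")
            meta["models"][name] = {
                "family": m.family, "branch": m.branch, "transform": m.transform,
                "log_likelihood": float(m.llf),
                "moran_i": None if m.moran_i is None else float(m.moran_i),
                "moran_p": None if m.moran_p is None else float(m.moran_p),
                "lambda": None if m.lam is None else float(m.lam),
            }
        with open(out / "run_summary.yaml", "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=True)


def dedupe_points(
    communities: CommunityTable, min_dist: float = 200.0, seed: int = 0,
) -> CommunityTable:
    """Drop one point of every pair closer than ``min_dist``.

    The earlier-dated observation of a too-close pair is kept; date ties are
    broken by a seeded random choice.  Applied before unit screening.
    ``min_dist`` is in the coordinate units of the community coordinates.
    """
    if communities.community_coords is None:
        raise ValueError("point de-duplication requires community coordinates")
    if communities.dates is None:
        raise ValueError("point de-duplication requires observation dates")
    rng = np.random.default_rng(seed)
    ids = communities.community_ids
    xy = communities.community_coords.loc[ids].to_numpy(dtype=float)
    dates = communities.dates.loc[ids]

    pairs = sorted(cKDTree(xy).query_pairs(r=min_dist))
    dropped: set = set()
    for i, j in pairs:
        a, b = ids[i], ids[j]
        if a in dropped or b in dropped:
            continue
        if dates[a] < dates[b]:
            dropped.add(b)
        elif dates[b] < dates[a]:
            dropped.add(a)
        else:
            dropped.add(a if rng.random() < 0.5 else b)
    if not dropped:
        return communities
    logger.info("point de-duplication removed %d of %d communities", len(dropped), len(ids))
    keep = [c for c in ids if c not in dropped]
    return _subset(communities, keep)


def screen_units(communities: CommunityTable, min_points: int = 3) -> CommunityTable:
    """Drop units with fewer than ``min_points`` local communities."""
    counts = communities.unit_of.value_counts()
    good_units = set(counts.index[counts >= min_points])
    if not good_units:
        raise ValueError(f"no units with at least {min_points} communities survive")
    keep = [c for c in communities.community_ids
            if communities.unit_of[c] in good_units]
    filtered = _subset(communities, keep)
    logger.info("unit screening: %d of %d units retained (%d of %d points)",
                len(good_units), counts.size, len(keep), len(communities.community_ids))
    return filtered


def _subset(ct: CommunityTable, keep: list) -> CommunityTable:
    unit_of = ct.unit_of.loc[keep]
    units = pd.unique(unit_of)
    return CommunityTable(
        abundance=ct.abundance.loc[keep],
        unit_of=unit_of,
        unit_coords=ct.unit_coords.loc[units],
        community_coords=None if ct.community_coords is None else ct.community_coords.loc[keep],
        dates=None if ct.dates is None else ct.dates.loc[keep],
    )


def fit_all_models(
    diversity: pd.DataFrame,
    predictors: pd.DataFrame,
    unit_coords: pd.DataFrame,
    *,
    seed: int = 0,
    k_neighbors: int = 8,
    n_perm: int = 1000,
    skew_threshold: float = 0.5,
    moran_alpha: float = 0.05,
) -> dict[str, ModelResult]:
    """The inferential stage alone: one chooser-selected model per
    (facet, level) response in a tidy diversity table.

    ``diversity`` has columns unit_id, facet, alpha_eqv, gamma_eqv, beta_prop
    (the serialized output of the diversity stage can seed this directly);
    ``predictors`` is indexed by unit_id.  Deterministic given the seed.
    """
    units = list(predictors.index)
    weights = build_weights(unit_coords.loc[units], k=k_neighbors)
    wide = diversity.pivot(index="unit_id", columns="facet")
    models: dict[str, ModelResult] = {}
    rng = np.random.default_rng(seed)
    for facet in pd.unique(diversity["facet"]):
        for level, column in LEVELS.items():
            name = f"{facet}_{level}"
            y = wide[(column, facet)].loc[units].to_numpy(dtype=float)
            models[name] = select_and_fit(
                y, predictors, weights, seed=rng, response=name,
                skew_threshold=skew_threshold, moran_alpha=moran_alpha,
                n_perm=n_perm,
            )
    return models


def run_analysis(
    data: dict,
    *,
    seed: int = 0,
    min_points: int = 3,
    dedupe_min_dist: float | None = None,
    k_neighbors: int = 8,
    n_perm: int = 1000,
    facets: tuple[str, ...] = ("taxonomic", "functional", "phylogenetic"),
    consensus_threshold: float = 0.5,
    gamma_weighting: str = "equal",
    alpha_averaging: str = "mean_q",
    skew_threshold: float = 0.5,
    moran_alpha: float = 0.05,
    vif_threshold: float = 3.0,
) -> RunReport:
    """Run the full analysis on in-memory inputs.

    ``data`` holds ``communities`` (CommunityTable), ``covariates``
    (UnitCovariates) and, depending on the requested facets, ``traits``
    (TraitTable) and ``trees`` (TreeSet) — the structure returned by
    :func:`betascape.synthetic_data.simulate_dataset` or assembled from the
    io readers.
    """
    communities: CommunityTable = data["communities"]
    n_in = len(communities.community_ids)
    if dedupe_min_dist is not None:
        communities = dedupe_points(communities, dedupe_min_dist, seed=seed)
    communities = screen_units(communities, min_points)
    species = communities.species_ids

    # facet distance matrices
    dmats = {}
    dropped_species: list[str] = []
    if "taxonomic" in facets:
        dmats["taxonomic"] = taxonomic_distance(species)
    if "functional" in facets:
        traits = data["traits"]
        check_species_order(traits.species_ids, species, "traits vs communities")
        dmats["functional"] = functional_distance(scale_traits(traits))
    if "phylogenetic" in facets:
        consensus = majority_consensus(data["trees"], threshold=consensus_threshold)
        dmat = phylo_distance(consensus)
        dropped_species = sorted(set(species) - set(dmat.species_ids))
        if dropped_species:
            logger.info("phylogenetic facet drops %d species absent from the consensus",
                        len(dropped_species))
        dmats["phylogenetic"] = dmat

    diversity = partition_all(
        communities, dmats, min_communities=min_points,
        gamma_weighting=gamma_weighting, alpha_averaging=alpha_averaging,
    )

    # covariates aligned to surviving units; n_points recomputed from data
    units = communities.unit_ids
    cov = data["covariates"].table.loc[units].copy()
    cov["n_points"] = communities.n_points().loc[units].to_numpy()
    X = cov[PREDICTORS]

    vifs = vif(X)
    if (vifs >= vif_threshold).any():
        raise VifScreenError(vifs, vif_threshold)

    models = fit_all_models(
        diversity, X, communities.unit_coords.loc[units], seed=seed,
        k_neighbors=k_neighbors, n_perm=n_perm,
        skew_threshold=skew_threshold, moran_alpha=moran_alpha,
    )

    metadata = {
        "seed": seed,
        "n_communities_in": n_in,
        "n_communities_used": len(communities.community_ids),
        "n_units_used": len(units),
        "n_species": len(species),
        "dropped_species_phylo": dropped_species,
        "k_neighbors": k_neighbors,
        "n_perm": n_perm,
        "facets": list(dmats),
        "gamma_weighting": gamma_weighting,
        "alpha_averaging": alpha_averaging,
    }
    return RunReport(models=models, diversity=diversity, vifs=vifs, metadata=metadata)
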