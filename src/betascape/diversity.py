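"""Rao quadratic-entropy diversity partitioning.

For a sampling unit holding several local communities, diversity is measured
as Rao's quadratic entropy Q = sum_ij d_ij p_i p_j — the expected
dissimilarity between two randomly drawn individuals — converted to an
equivalent number 1/(1-Q) (Jost's correction).  Alpha is the equivalent
number of the mean community-level Q, gamma the equivalent number of the
pooled unit, and beta the proportion of gamma not explained by alpha,

    beta_prop = 100 * (gamma_eqv - alpha_eqv) / gamma_eqv ,

which is comparable across units with unequal numbers of local communities
and across diversity facets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from betascape.distances import DistanceMatrix
from betascape.io import CommunityTable, check_species_order

logger = logging.getLogger(__name__)

#: tolerance for relative-abundance normalization
P_TOL = 1e-9


def _as_prob(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be non-negative")
    s = p.sum()
    if s <= 0:
        raise ValueError("empty community (zero total abundance)")
    if abs(s - 1.0) > P_TOL:
        raise ValueError(f"relative abundances sum to {s!r}, not 1")
    return p


def rao_q(p: np.ndarray, d: DistanceMatrix | np.ndarray) -> float:
    """Rao's quadratic entropy Q = sum_ij d_ij p_i p_j.

    ``p`` must be a relative-abundance vector (summing to 1) over the same
    species, in the same order, as ``d``.
    """
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    p = _as_prob(p)
    if p.shape[0] != dm.shape[0]:
        raise ValueError(f"abundance length {p.shape[0]} != distance size {dm.shape[0]}")
    return float(p @ dm @ p)


def equivalent_number(q: float) -> float:
    """Jost's equivalent number 1/(1-Q) for Rao's quadratic entropy.

    With all inter-species distances equal to 1 this is the inverse Simpson
    index 1/sum(p^2).
    """
    if not 0 <= q < 1:
        raise ValueError(f"Q must lie in [0, 1), got {q!r}")
    return 1.0 / (1.0 - q)


def partition_unit(
    abundances: np.ndarray,
    d: DistanceMatrix | np.ndarray,
    *,
    min_communities: int = 3,
    gamma_weighting: str = "equal",
    alpha_averaging: str = "mean_q",
) -> tuple[float, float, float]:
    """Partition one unit's diversity into (alpha_eqv, gamma_eqv, beta_prop).

    Parameters
    ----------
    abundances : array (n_communities, n_species)
        Raw (or relative) abundances, one row per local community; rows are
        normalized internally.
    d : DistanceMatrix
        Pairwise species dissimilarities for the facet, same species order.
    min_communities : int
        Units below this community count are rejected (field rule: 3).
    gamma_weighting : {"equal", "abundance"}
        "equal" pools the equal-weight mean of community relative-abundance
        vectors (default; gamma insensitive to unequal counts); "abundance"
        pools raw counts.
    alpha_averaging : {"mean_q", "mean_eqv"}
        "mean_q" applies the equivalent-number transform to the mean raw Q
        (default); "mean_eqv" averages community-wise equivalent numbers.

    Returns
    -------
    (alpha_eqv, gamma_eqv, beta_prop) with beta_prop on a 0-100 scale.
    """
    ab = np.asarray(abundances, dtype=float)
    if ab.ndim != 2:
        raise ValueError("abundances must be a 2-D (communities x species) array")
    if ab.shape[0] < min_communities:
        raise ValueError(
            f"unit has {ab.shape[0]} communities; at least {min_communities} required"
        )
    totals = ab.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("empty community (zero total abundance)")
    rel = ab / totals[:, None]

    qs = np.array([rao_q(row, d) for row in rel])
    if alpha_averaging == "mean_q":
        alpha = equivalent_number(float(qs.mean()))
    elif alpha_averaging == "mean_eqv":
        alpha = float(np.mean([equivalent_number(q) for q in qs]))
    else:
        raise ValueError(f"unknown alpha_averaging {alpha_averaging!r}")

    if gamma_weighting == "equal":
        pooled = rel.mean(axis=0)
    elif gamma_weighting == "abundance":
        pooled = ab.sum(axis=0) / ab.sum()
    else:
        raise ValueError(f"unknown gamma_weighting {gamma_weighting!r}")
    gamma = equivalent_number(rao_q(pooled, d))

    beta = 100.0 * (gamma - alpha) / gamma
    return alpha, gamma, beta


def partition_all(
    communities: CommunityTable,
    distance_matrices: dict[str, DistanceMatrix],
    *,
    min_communities: int = 3,
    gamma_weighting: str = "equal",
    alpha_averaging: str = "mean_q",
) -> pd.DataFrame:
    """Per-unit alpha/gamma/beta for every facet's distance matrix.

    ``distance_matrices`` maps facet name -> DistanceMatrix.  A facet matrix
    covering only a subset of the species pool (the phylogenetic facet may
    exclude species absent from the consensus tree) triggers an explicit,
    logged drop of the missing species followed by renormalization; a matrix
    with a species ordering that merely disagrees with the community table
    raises.

    Returns a tidy frame with columns unit_id, facet, alpha_eqv, gamma_eqv,
    beta_prop.
    """
    species = communities.species_ids
    rows = []
    for facet, dm in distance_matrices.items():
        if set(dm.species_ids) == set(species):
            check_species_order(dm.species_ids, species, f"{facet} distances vs communities")
            cols = species
        elif set(dm.species_ids) < set(species):
            dropped = sorted(set(species) - set(dm.species_ids))
            logger.info("facet %s: dropping %d species absent from its distance matrix: %s",
                        facet, len(dropped), dropped)
            cols = dm.species_ids
        else:
            extra = sorted(set(dm.species_ids) - set(species))
            raise ValueError(f"facet {facet}: distance matrix has unknown species {extra}")

        sub = communities.abundance[cols]
        for unit in communities.unit_ids:
            ab = sub.loc[communities.unit_of[communities.unit_of == unit].index].to_numpy()
            if (ab.sum(axis=1) == 0).any():
                # a community can lose all individuals under a facet drop
                raise ValueError(
                    f"unit {unit}: a community is empty after dropping species for facet {facet}"
                )
            a, g, b = partition_unit(
                ab, dm, min_communities=min_communities,
                gamma_weighting=gamma_weighting, alpha_averaging=alpha_averaging,
            )
            rows.append({"unit_id": unit, "facet": facet,
                         "alpha_eqv": a, "gamma_eqv": g, "beta_prop": b})
    return pd.DataFrame(rows)
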