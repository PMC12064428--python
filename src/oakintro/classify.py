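"""Species assignment from cluster memberships and the introgression index.

Cluster membership proportions are summed within species, individuals are
binned into pure / admixed / highly-admixed categories by fixed thresholds,
and per-population introgression is the weighted hybrid fraction
(n_highly_admixed + 0.5 * n_admixed) / n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TaxonAssignment",
    "species_q_sums",
    "classify",
    "classify_all",
    "introgression_index",
    "population_summary",
]

T_PURE = 0.875
T_ADMIXED = 0.625


@dataclass
class TaxonAssignment:
    individual_id: str
    species_q: dict[str, float]
    category: str  # "pure:<species>" | "admixed" | "highly_admixed"


def species_q_sums(Q: np.ndarray, cluster_species_map: dict[int, str]) -> list[dict[str, float]]:
    """Sum cluster memberships within species, per individual.

    ``cluster_species_map`` must cover every cluster column of Q.
    """
    Q = np.asarray(Q, float)
    K = Q.shape[1]
    missing = [k for k in range(K) if k not in cluster_species_map]
    if missing:
        raise ValueError(f"cluster_species_map does not cover clusters {missing}")
    species = sorted(set(cluster_species_map.values()))
    cols = {s: [k for k in range(K) if cluster_species_map[k] == s] for s in species}
    return [{s: float(Q[i, cols[s]].sum()) for s in species} for i in range(Q.shape[0])]


def classify(species_q: dict[str, float], t_pure: float = T_PURE, t_adm: float = T_ADMIXED) -> str:
    """Bin one individual by its maximum summed species membership.

    Strictly above ``t_pure`` -> pure:<species>; in (t_adm, t_pure] ->
    admixed; at or below ``t_adm`` -> highly_admixed. The boundary points
    0.875 and 0.625 fall into admixed and highly_admixed respectively.
    """
    if not 0.5 < t_adm < t_pure < 1:
        raise ValueError("thresholds must satisfy 0.5 < t_adm < t_pure < 1")
    best = max(species_q, key=species_q.get)
    qmax = species_q[best]
    if qmax > t_pure:
        return f"pure:{best}"
    if qmax > t_adm:
        return "admixed"
    return "highly_admixed"


def classify_all(
    Q: np.ndarray,
    cluster_species_map: dict[int, str],
    individual_ids,
    t_pure: float = T_PURE,
    t_adm: float = T_ADMIXED,
) -> list[TaxonAssignment]:
    sums = species_q_sums(Q, cluster_species_map)
    return [
        TaxonAssignment(ind, sq, classify(sq, t_pure, t_adm))
        for ind, sq in zip(individual_ids, sums)
    ]


def introgression_index(categories, n: int | None = None) -> float:
    """(n_highly_admixed + 0.5 * n_admixed) / n over classified individuals."""
    categories = list(categories)
    if n is None:
        n = len(categories)
    if n <= 0:
        raise ValueError("introgression index undefined for n = 0")
    n_had = sum(c == "highly_admixed" for c in categories)
    n_ad = sum(c == "admixed" for c in categories)
    return (n_had + 0.5 * n_ad) / n


def population_summary(
    assignments: list[TaxonAssignment],
    pop_ids,
    focal_species: str,
) -> pd.DataFrame:
    """Per-population category counts and introgression index.

    Individuals pure for a *non-focal* species are excluded before counting,
    mirroring the removal of reference-species trees from the index.
    """
    if len(assignments) != len(pop_ids):
        raise ValueError("assignments and pop_ids must be parallel")
    rows = []
    frame = pd.DataFrame(
        {
            "pop_id": [str(p) for p in pop_ids],
            "category": [a.category for a in assignments],
        }
    )
    for pop, grp in frame.groupby("pop_id", sort=False):
        cats = grp["category"]
        keep = cats[~(cats.str.startswith("pure:") & (cats != f"pure:{focal_species}"))]
        n = len(keep)
        if n == 0:
            raise ValueError(f"population {pop}: empty after exclusions")
        n_pure = int((keep == f"pure:{focal_species}").sum())
        n_ad = int((keep == "admixed").sum())
        n_had = int((keep == "highly_admixed").sum())
        rows.append(
            {
                "pop_id": pop,
                "n": n,
                "n_excluded": len(cats) - n,
                "n_pure": n_pure,
                "n_admixed": n_ad,
                "n_highly_admixed": n_had,
                "introgression_index": (n_had + 0.5 * n_ad) / n,
            }
        )
    return pd.DataFrame(rows)
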