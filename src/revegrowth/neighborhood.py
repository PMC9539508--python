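"""Per-focal neighborhood density and diversity metrics.

The neighborhood of a focal plant is every other plant in its plot (all
genera, not only the focal genera).  Because stems are not mapped within
plots, metrics are plot-level quantities with the focal removed:

* density — neighbors per hectare, ``(n_plot - 1) / (area / 10^4)``;
* proportion of intraspecific neighbors;
* rarefied species richness — the expected number of species among ``n``
  neighbors drawn without replacement (hypergeometric rarefaction,
  default ``n = 9``);
* functional evenness (FEve) — regularity of abundance-weighted species
  spacing along the minimum spanning tree of trait space, in [0, 1];
* functional dispersion (FDis) — abundance-weighted mean distance of
  species to the abundance-weighted trait-space centroid;
* functional range — product of per-trait ranges; computed for reports but
  never entered in growth models (it duplicates richness).

Trait space is Euclidean on z-standardized SLA, wood density and maximum
height, standardized over the full species pool of the dataset so that
plots are comparable.  Species with any missing trait are dropped from
FEve/FDis, with abundances renormalized over the retained species.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csgraph
from scipy.special import gammaln

from .growth import TRAIT_COLUMNS

__all__ = [
    "neighbor_density",
    "prop_intraspecific",
    "rarefied_richness",
    "functional_evenness",
    "functional_dispersion",
    "functional_range",
    "standardize_traits",
    "neighborhood_table",
]


def neighbor_density(n_plants_incl_focal: int, plot_area_m2: float) -> float:
    """Neighbors per hectare: the plot's plants minus the focal, over area in ha."""
    if plot_area_m2 <= 0:
        raise ValueError("plot area must be positive")
    if n_plants_incl_focal < 1:
        raise ValueError("a plot holding a focal has at least one plant")
    return (n_plants_incl_focal - 1) / (plot_area_m2 / 1e4)


def prop_intraspecific(neighbor_abundances: dict[str, int] | pd.Series, focal_species: str) -> float:
    """Fraction of neighbors sharing the focal's species; NaN for an empty neighborhood."""
    ab = pd.Series(neighbor_abundances, dtype=float)
    total = ab.sum()
    if total < 1:
        return float("nan")
    return float(ab.get(focal_species, 0.0) / total)


def rarefied_richness(abundances, n: int = 9) -> float:
    """Expected species count in a random subsample of ``n`` individuals.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)] with the binomial
    coefficients evaluated in log space.  Requires total N >= n; plots with
    fewer neighbors are under-occupied and must be treated as missing by
    the caller.
    """
    counts = np.asarray([a for a in abundances if a > 0], dtype=float)
    if n < 1:
        raise ValueError("subsample size n must be >= 1")
    total = counts.sum()
    if total < n:
        raise ValueError(f"under-occupied plot: N={int(total)} < n={n}")

    def log_choose(a, k):
        return gammaln(a + 1.0) - gammaln(k + 1.0) - gammaln(a - k + 1.0)

    log_denom = log_choose(total, n)
    with np.errstate(invalid="ignore"):
        terms = np.where(
            total - counts >= n,
            np.exp(log_choose(total - counts, n) - log_denom),
            0.0,
        )
    return float(np.sum(1.0 - terms))


def _clean_community(trait_matrix, abundances):
    x = np.asarray(trait_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    a = np.asarray(abundances, dtype=float)
    if x.shape[0] != a.shape[0]:
        raise ValueError("trait matrix rows must match abundance vector")
    keep = (a > 0) & ~np.isnan(x).any(axis=1)
    return x[keep], a[keep]


def functional_evenness(trait_matrix, abundances) -> float:
    """Minimum-spanning-tree functional evenness in [0, 1].

    For each MST edge l joining species i and j, the abundance-weighted
    evenness is ``EW_l = d(i, j) / (w_i + w_j)`` with w the relative
    abundances; FEve rescales the sum of ``min(PEW_l, 1/(S-1))`` so that a
    perfectly regular arrangement scores 1.  Undefined (NaN) below three
    species; invariant to uniform abundance rescaling.
    """
    x, a = _clean_community(trait_matrix, abundances)
    s = x.shape[0]
    if s < 3:
        return float("nan")
    if a.sum() <= 0:
        raise ValueError("total abundance must be positive")
    w = a / a.sum()
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2))
    # MST on the complete trait-distance graph; zero-length edges are kept
    # distinct from absent ones by a constant offset removed afterwards
    mst = csgraph.minimum_spanning_tree(np.triu(d + 1.0, k=1)).tocoo()
    ew = np.array(
        [(d[i, j]) / (w[i] + w[j]) for i, j in sorted(zip(mst.row, mst.col))]
    )
    tot = ew.sum()
    if tot == 0:
        return 0.0
    pew = ew / tot
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_dispersion(trait_matrix, abundances) -> float:
    """Abundance-weighted mean distance to the abundance-weighted centroid."""
    x, a = _clean_community(trait_matrix, abundances)
    if x.shape[0] == 0 or a.sum() <= 0:
        raise ValueError("need at least one species with positive abundance")
    w = a / a.sum()
    centroid = w @ x
    z = np.sqrt(((x - centroid) ** 2).sum(axis=1))
    return float(w @ z)


def functional_range(trait_matrix) -> float:
    """Product of per-trait ranges on the standardized scale; NaN below 2 species.

    Report-only: highly redundant with species richness, so the model
    ladder never includes it.
    """
    x = np.asarray(trait_matrix, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 2:
        return float("nan")
    return float(np.prod(x.max(axis=0) - x.min(axis=0)))


def standardize_traits(species_traits: pd.DataFrame) -> pd.DataFrame:
    """z-score the three traits over the full species pool (NaN-aware)."""
    out = species_traits.set_index("species")[list(TRAIT_COLUMNS)].astype(float)
    return (out - out.mean()) / out.std(ddof=1)


def neighborhood_table(
    plants: pd.DataFrame,
    plots: pd.DataFrame,
    species_traits: pd.DataFrame,
    rarefaction_n: int = 9,
) -> pd.DataFrame:
    """Compute all neighborhood metrics for every focal-candidate plant.

    Parameters
    ----------
    plants
        One row per plant with ``plant_id, plot_id, species, genus`` and a
        boolean ``is_focal_candidate`` column marking plants whose
        neighborhoods are needed.
    plots
        ``plot_id, area_m2``.
    species_traits
        Species pool with ``species, genus`` and the three trait columns.

    Returns one row per candidate: density (plants/ha), prop_intra,
    richness (rarefied, NaN when the plot holds fewer than
    ``rarefaction_n + 1`` plants), feve, fdis, frange and a
    ``metrics_complete`` flag.  FEve/FDis reuse a per-(plot, focal-species)
    cache since metrics depend only on the plot composition minus one
    individual of the focal's species.
    """
    z = standardize_traits(species_traits)
    z_mat = z.to_numpy()
    sp_row = {sp: i for i, sp in enumerate(z.index)}
    areas = plots.set_index("plot_id")["area_m2"].to_dict()

    sp_codes = plants["species"].map(sp_row).to_numpy()
    plot_groups: dict = {}
    for pid, idx in plants.groupby("plot_id").indices.items():
        codes, counts = np.unique(sp_codes[idx], return_counts=True)
        plot_groups[pid] = (codes, counts)

    cache: dict[tuple, dict] = {}
    rows = []
    cand = plants[plants["is_focal_candidate"]]
    for plant_id, plot_id, species in cand[["plant_id", "plot_id", "species"]].itertuples(index=False):
        key = (plot_id, species)
        if key not in cache:
            codes, counts = plot_groups[plot_id]
            ab = counts.astype(float).copy()
            ab[codes == sp_row[species]] -= 1.0  # remove the focal itself
            keep = ab > 0
            codes_k, ab_k = codes[keep], ab[keep]
            n_neighbors = int(ab_k.sum())
            area = float(areas[plot_id])
            traits = z_mat[codes_k]
            known = ~np.isnan(traits).any(axis=1)
            n_con = float(ab_k[codes_k == sp_row[species]].sum())
            metrics = {
                "density": n_neighbors / (area / 1e4),
                "prop_intra": n_con / n_neighbors if n_neighbors >= 1 else float("nan"),
                "richness": (
                    rarefied_richness(ab_k, rarefaction_n)
                    if n_neighbors >= rarefaction_n
                    else float("nan")
                ),
                "feve": functional_evenness(traits[known], ab_k[known])
                if known.sum() >= 3
                else float("nan"),
                "fdis": functional_dispersion(traits[known], ab_k[known])
                if known.sum() >= 1 and ab_k[known].sum() > 0
                else float("nan"),
                "frange": functional_range(traits[known]),
                "n_neighbors": n_neighbors,
            }
            cache[key] = metrics
        m = cache[key]
        rows.append({"plant_id": plant_id, "plot_id": plot_id, "species": species, **m})
    out = pd.DataFrame(rows)
    model_cols = ["density", "prop_intra", "richness", "feve", "fdis"]
    out["metrics_complete"] = out[model_cols].notna().all(axis=1)
    return out
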