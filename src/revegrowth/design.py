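"""Fixed-effect design construction for the growth-rate model ladder.

Continuous predictors are transformed (natural log for planting age, species
maximum height and solar radiation; square root for neighbor density) and
then z-standardized over the pooled focal dataset so that partial slopes are
directly comparable across predictors and genera.  Genus enters by treatment
contrast with Acacia as the reference level, so ``genus_E`` coefficients are
Eucalyptus offsets and per-genus slopes are linear combinations of terms.

Seven nested model specifications of increasing complexity are built over
this design:

==========================  =====================================================
base                        intercept only
no_genus                    all continuous predictors (+ plot_area x prop_intra)
genus_intercepts            + genus main effect
genus_slopes                + genus x predictor two-way interactions
no_genus_moisture           no_genus + moisture x predictor interactions
genus_intercepts_moisture   + genus main effect
genus_slopes_moisture       genus_slopes + moisture two-ways + moisture x genus
                            x predictor three-ways
==========================  =====================================================

Marginality is enforced: every lower-order term of any interaction is in the
spec.  All specs share the same four random-intercept factors (subregion,
planting, plot, species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONTINUOUS_PREDICTORS",
    "TRANSFORMS",
    "RANDOM_FACTORS",
    "LADDER_NAMES",
    "Standardizer",
    "ModelSpec",
    "transform_predictors",
    "build_model_ladder",
    "build_design",
    "vif",
    "screen_plot_area_interactions",
]

#: model-entering continuous predictors, in canonical order
CONTINUOUS_PREDICTORS = (
    "moisture",
    "radiation",
    "age",
    "plot_area",
    "sla",
    "wood_density",
    "max_height",
    "density",
    "prop_intra",
    "richness",
    "feve",
    "fdis",
)

#: linearizing transforms applied before standardization
TRANSFORMS = {
    "age": ("log", np.log),
    "max_height": ("log", np.log),
    "radiation": ("log", np.log),
    "density": ("sqrt", np.sqrt),
}

RANDOM_FACTORS = ("subregion", "planting", "plot", "species")

LADDER_NAMES = (
    "base",
    "no_genus",
    "genus_intercepts",
    "genus_slopes",
    "no_genus_moisture",
    "genus_intercepts_moisture",
    "genus_slopes_moisture",
)


def transform_predictors(raw: pd.DataFrame, columns=CONTINUOUS_PREDICTORS) -> pd.DataFrame:
    """Apply the linearizing transforms; other continuous predictors pass through.

    Raises on domain violations (non-positive values under a log, negative
    under a sqrt), listing the offending row labels.
    """
    out = raw.copy()
    for col in columns:
        if col not in out.columns:
            continue
        spec = TRANSFORMS.get(col)
        if spec is None:
            continue
        kind, fn = spec
        vals = out[col].astype(float)
        bad = vals <= 0 if kind == "log" else vals < 0
        bad &= vals.notna()
        if bad.any():
            raise ValueError(
                f"{kind} transform of {col!r} undefined for rows {list(out.index[bad])[:10]}"
            )
        out[col] = fn(vals)
    return out


@dataclass
class Standardizer:
    """Column-wise z-scaling with stored means and (n-1) standard deviations.

    The stored scaling maps raw-scale values onto the modeled z-scale, which
    is how fixed moisture conditions (e.g. a moisture ratio of 0.27) are
    located in the standardized design.
    """

    means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    sds: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def fit(self, df: pd.DataFrame, columns) -> "Standardizer":
        cols = [c for c in columns if c in df.columns]
        self.means = df[cols].mean()
        self.sds = df[cols].std(ddof=1)
        zero = self.sds[self.sds == 0]
        if len(zero):
            raise ValueError(f"constant columns cannot be standardized: {list(zero.index)}")
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def fit_transform(self, df: pd.DataFrame, columns) -> pd.DataFrame:
        return self.fit(df, columns).transform(df)

    def to_z(self, column: str, raw_value: float, transformed: bool = False) -> float:
        """Map a raw predictor value to the z-scale (transform then z-score)."""
        v = float(raw_value)
        if not transformed and column in TRANSFORMS:
            v = float(TRANSFORMS[column][1](v))
        return (v - float(self.means[column])) / float(self.sds[column])


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effect term list plus the random-intercept grouping factors.

    Interaction terms are colon-joined column products; ``genus_E`` is the
    Eucalyptus dummy.
    """

    name: str
    terms: tuple[str, ...]
    random_factors: tuple[str, ...] = RANDOM_FACTORS

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)

    @property
    def n_fixed(self) -> int:
        return len(self.terms)


def build_model_ladder(predictors=CONTINUOUS_PREDICTORS) -> dict[str, ModelSpec]:
    """The seven nested model specifications, keyed by name."""
    predictors = tuple(predictors)
    area_inter = (
        ("plot_area:prop_intra",)
        if {"plot_area", "prop_intra"} <= set(predictors)
        else ()
    )
    others = tuple(p for p in predictors if p != "moisture")

    base = ("intercept",)
    no_genus = base + predictors + area_inter
    genus_intercepts = no_genus + ("genus_E",)
    genus_slopes = genus_intercepts + tuple(f"{p}:genus_E" for p in predictors)
    moist_two_way = tuple(f"moisture:{p}" for p in others)
    no_genus_moisture = no_genus + moist_two_way
    genus_intercepts_moisture = no_genus_moisture + ("genus_E",)
    genus_slopes_moisture = (
        genus_slopes + moist_two_way + tuple(f"moisture:{p}:genus_E" for p in others)
    )
    specs = {
        "base": base,
        "no_genus": no_genus,
        "genus_intercepts": genus_intercepts,
        "genus_slopes": genus_slopes,
        "no_genus_moisture": no_genus_moisture,
        "genus_intercepts_moisture": genus_intercepts_moisture,
        "genus_slopes_moisture": genus_slopes_moisture,
    }
    return {name: ModelSpec(name, terms) for name, terms in specs.items()}


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    n = len(data)
    if term == "intercept":
        return np.ones(n)
    col = np.ones(n)
    for part in term.split(":"):
        if part == "genus_E":
            col = col * (data["genus"].to_numpy() == "Eucalyptus").astype(float)
        else:
            col = col * data[part].to_numpy(dtype=float)
    return col


def build_design(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Materialize the fixed-effect design matrix for ``spec``.

    ``data`` holds the transformed+standardized continuous predictors and a
    ``genus`` column with levels Acacia/Eucalyptus.
    """
    x = np.column_stack([_term_column(data, t) for t in spec.terms])
    return pd.DataFrame(x, columns=list(spec.terms), index=data.index)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factors, ``1 / (1 - R^2_j)``, per non-intercept column.

    Computed on a main-effects design (an intercept is added internally if
    absent).  Raises on rank deficiency, naming the collinear columns.
    """
    cols = [c for c in design.columns if c != "intercept"]
    x = design[cols].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # identify a minimal offending set by greedy elimination
        r = np.linalg.qr(x, mode="r")
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [cols[i - 1] for i in range(1, x.shape[1]) if diag[i] < tol]
        raise np.linalg.LinAlgError(f"rank-deficient design; collinear columns include {bad}")
    out = {}
    for j, c in enumerate(cols, start=1):
        others = [k for k in range(x.shape[1]) if k != j]
        beta, _, _, _ = np.linalg.lstsq(x[:, others], x[:, j], rcond=None)
        resid = x[:, j] - x[:, others] @ beta
        tss = np.sum((x[:, j] - x[:, j].mean()) ** 2)
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[c] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def screen_plot_area_interactions(
    data: pd.DataFrame,
    y: np.ndarray,
    fit_fn,
    predictors=CONTINUOUS_PREDICTORS,
    z_crit: float = 1.96,
) -> list[str]:
    """Pre-analysis screen of plot_area x predictor interactions.

    Fits the no-genus model augmented with every ``plot_area:p`` interaction
    and returns the interactions whose coefficient |z| exceeds ``z_crit``.
    The default ladder hard-codes retaining only ``plot_area:prop_intra``;
    this function exposes the selection procedure itself.  ``fit_fn`` is a
    callback ``(y, spec, data) -> FitResult`` (typically the mixed-model
    fitter).
    """
    others = tuple(p for p in predictors if p != "plot_area")
    terms = ("intercept",) + tuple(predictors) + tuple(f"plot_area:{p}" for p in others)
    spec = ModelSpec("plot_area_screen", terms)
    fit = fit_fn(y, spec, data)
    retained = []
    for p in others:
        term = f"plot_area:{p}"
        z = fit.beta[term] / fit.beta_se[term]
        if abs(z) >= z_crit:
            retained.append(term)
    return retained
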