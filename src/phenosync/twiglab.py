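"""Analytics for twig-cutting experiments.

Two designs are supported.  In the trait-estimation design, twigs from
each individual are forced in climate chambers under crossed day-length
(8/12/16 h) and chilling (collection date) treatments; per-individual
cue requirements fall out as

* forcing requirement — degree-days until leaf-out in the fully-released
  cell (longest chilling, 16 h day length);
* day-length sensitivity — OLS slope of degree-days on treatment hours
  at the longest chilling (more negative = more sensitive);
* chilling sensitivity — OLS slope of degree-days on chilling hours at
  collection, under 16 h day length.

In the variance-decomposition design, replicate twigs at several
chilling levels under natural day length are decomposed into treatment,
between-individual and within-individual (residual) variance, either as
sequential ANOVA sums of squares against the estimated traits or as
random-effect variance components (individuals nested within
treatments, method-of-moments on the nested-ANOVA expected mean
squares).

Observation tables are tidy frames with columns
``individual_id, collection_chill_h, daylength_h, replicate,
leafout_doy, dd_at_leafout`` (degree-days from the first collection
date, 10 December, in the experiments emulated here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .climate import IndividualTraits
from .exceptions import DegenerateInputError, InvalidParameterError, MissingDataError

TRAIT_ORDER = ("forcing", "daylength", "chilling")


def mean_leafout_first_k(dates: np.ndarray, k: int = 8) -> tuple[float, bool]:
    """Mean of the ``k`` earliest leaf-out dates among replicates.

    Returns ``(mean, complete)``; when fewer than ``k`` replicates leafed
    out the mean is over the available ones and ``complete`` is False.
    """
    dates = np.asarray(dates, dtype=float)
    dates = dates[~np.isnan(dates)]
    if dates.size == 0:
        raise MissingDataError("no leafed-out replicates")
    complete = dates.size >= k
    earliest = np.sort(dates)[:k]
    return float(earliest.mean()), complete


def _slope(x: np.ndarray, y: np.ndarray, what: str) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2:
        raise DegenerateInputError(f"need >= 2 {what} levels for a slope")
    return float(stats.linregress(x, y).slope)


def daylength_sensitivity(dd: np.ndarray, treatment_hours: np.ndarray) -> float:
    """OLS slope of degree-days at leaf-out on day-length treatment (DD/h).

    More negative slopes mean stronger day-length sensitivity: a
    sensitive individual needs far more warming under short days.
    """
    return _slope(treatment_hours, dd, "day-length")


def chilling_sensitivity(dd: np.ndarray, chilling_hours: np.ndarray) -> float:
    """OLS slope of degree-days at leaf-out on chilling hours at collection."""
    return _slope(chilling_hours, dd, "chilling")


def forcing_requirement(
    table: pd.DataFrame,
    collection_chill_h: float | None = None,
    daylength_h: float = 16.0,
) -> float:
    """Degree-day requirement in the fully-released cell.

    The cell at the longest chilling (default: maximum present) and 16 h
    day length, where chilling and photoperiod requirements are assumed
    met; its mean ``dd_at_leafout`` is the forcing requirement.
    """
    if collection_chill_h is None:
        collection_chill_h = table["collection_chill_h"].max()
    cell = table[
        (table["collection_chill_h"] == collection_chill_h)
        & (table["daylength_h"] == daylength_h)
    ]["dd_at_leafout"].dropna()
    if cell.empty:
        raise MissingDataError(
            f"no observations at chilling {collection_chill_h} h / {daylength_h} h days"
        )
    return float(cell.mean())


@dataclass(frozen=True)
class TraitEstimates:
    individual_id: str
    forcing_req: float
    daylength_sensitivity: float
    chilling_sensitivity: float


def estimate_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Per-individual trait estimates from a crossed-treatment experiment.

    Uses per-cell mean degree-days: the day-length slope across the 8/12/16 h
    treatments at the longest chilling, the chilling slope across collection
    dates at 16 h, and the forcing requirement from the fully-released cell.
    Returns one row per individual.
    """
    rows = []
    max_chill = table["collection_chill_h"].max()
    for ind, sub in table.groupby("individual_id", sort=True):
        cells = (
            sub.groupby(["collection_chill_h", "daylength_h"])["dd_at_leafout"]
            .mean()
            .reset_index()
        )
        dl_cells = cells[cells["collection_chill_h"] == max_chill]
        ch_cells = cells[cells["daylength_h"] == 16.0]
        rows.append(
            TraitEstimates(
                individual_id=str(ind),
                forcing_req=forcing_requirement(sub),
                daylength_sensitivity=daylength_sensitivity(
                    dl_cells["dd_at_leafout"].to_numpy(),
                    dl_cells["daylength_h"].to_numpy(),
                ),
                chilling_sensitivity=chilling_sensitivity(
                    ch_cells["dd_at_leafout"].to_numpy(),
                    ch_cells["collection_chill_h"].to_numpy(),
                ),
            )
        )
    return pd.DataFrame([vars(r) for r in rows]).set_index("individual_id")


def partition_variance_anova(
    data: pd.DataFrame,
    traits: pd.DataFrame,
    response: str = "leafout_doy",
    order: tuple[str, ...] = TRAIT_ORDER,
    by_level: str | None = "collection_chill_h",
) -> pd.DataFrame:
    """Sequential (Type I) sums-of-squares shares of the three cue traits.

    Leaf-out dates are regressed on the per-individual trait estimates in
    the fixed entry order forcing -> day length -> chilling (configurable
    via ``order``); the share of each term and of the residual is its
    sequential SS as a percentage of the total, so shares sum to 100.
    Computed separately per chilling level when ``by_level`` is set.
    Near-collinear predictors are flagged in the ``collinear`` column
    (sequential attribution then depends on the entry order).
    """
    colmap = {
        "forcing": "forcing_req",
        "daylength": "daylength_sensitivity",
        "chilling": "chilling_sensitivity",
    }
    if set(order) != set(TRAIT_ORDER):
        raise InvalidParameterError(f"order must permute {TRAIT_ORDER}")
    merged = data.merge(traits, left_on="individual_id", right_index=True)
    terms = [colmap[o] for o in order]
    groups = merged.groupby(by_level) if by_level else [(None, merged)]
    rows = []
    for level, sub in groups:
        formula = f"{response} ~ " + " + ".join(terms)
        fit = smf.ols(formula, data=sub).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        total_ss = float(table["sum_sq"].sum())
        if total_ss == 0:
            raise DegenerateInputError("response has no variance")
        x = sub[terms].to_numpy(dtype=float)
        collinear = np.linalg.matrix_rank(x - x.mean(axis=0)) < len(terms)
        row = {"level": level, "collinear": bool(collinear)}
        for o in order:
            row[f"pct_{o}"] = 100.0 * float(table.loc[colmap[o], "sum_sq"]) / total_ss
            row[f"p_{o}"] = float(table.loc[colmap[o], "PR(>F)"])
        row["pct_residual"] = 100.0 * float(table.loc["Residual", "sum_sq"]) / total_ss
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


@dataclass
class VarianceComponents:
    """Random-effects decomposition of leaf-out variation.

    Shares are percentages of the total variance and sum to 100;
    components whose moment estimate came out negative are truncated at
    zero and listed in ``truncated``.
    """

    var_treatment: float
    var_individual: float
    var_residual: float
    truncated: list[str]
    method: str = "method-of-moments (nested ANOVA expected mean squares)"

    @property
    def shares(self) -> dict[str, float]:
        total = self.var_treatment + self.var_individual + self.var_residual
        if total == 0:
            raise DegenerateInputError("all variance components are zero")
        return {
            "treatment": 100.0 * self.var_treatment / total,
            "individual": 100.0 * self.var_individual / total,
            "residual": 100.0 * self.var_residual / total,
        }


def variance_components(
    data: pd.DataFrame,
    response: str = "leafout_doy",
    treatment_col: str = "collection_chill_h",
    individual_col: str = "individual_id",
) -> VarianceComponents:
    """Treatment / individual / residual variance components.

    Random-effects-only model with individuals nested within treatments,
    estimated by method-of-moments from the balanced nested-ANOVA
    expected mean squares: sigma2_e = MS_within, sigma2_ind =
    (MS_ind(trt) - MS_within) / n, sigma2_trt = (MS_trt - MS_ind(trt)) /
    (b n), with n replicates per cell and b individuals per treatment.
    Unbalanced tables use the mean cell counts (adequate for mildly
    unbalanced designs).  Negative moment estimates are truncated at 0
    and flagged.
    """
    df = data[[response, treatment_col, individual_col]].dropna()
    treatments = df[treatment_col].unique()
    if len(treatments) < 2:
        raise InvalidParameterError("need at least two treatments")
    cell = df.groupby([treatment_col, individual_col])[response]
    cell_counts = cell.size()
    if (cell_counts < 2).all():
        raise InvalidParameterError("need replicate twigs within cells")
    if df.groupby(treatment_col)[individual_col].nunique().min() < 2:
        raise InvalidParameterError("need at least two individuals per treatment")

    grand = df[response].mean()
    n_bar = float(cell_counts.mean())
    b_bar = float(df.groupby(treatment_col)[individual_col].nunique().mean())

    cell_means = cell.mean()
    trt_means = df.groupby(treatment_col)[response].mean()
    a = len(treatments)

    ss_trt = float(
        (df.groupby(treatment_col)[response].size() * (trt_means - grand) ** 2).sum()
    )
    trt_of_cell = cell_means.index.get_level_values(0)
    ss_ind = float(
        (cell_counts * (cell_means - trt_means.loc[trt_of_cell].to_numpy()) ** 2).sum()
    )
    fitted = cell_means.loc[list(zip(df[treatment_col], df[individual_col]))].to_numpy()
    ss_resid = float(((df[response].to_numpy() - fitted) ** 2).sum())

    df_trt = a - 1
    df_ind = int(cell_counts.size - a)
    df_resid = int(len(df) - cell_counts.size)
    ms_trt = ss_trt / df_trt
    ms_ind = ss_ind / df_ind
    ms_resid = ss_resid / df_resid

    truncated: list[str] = []
    var_resid = ms_resid
    var_ind = (ms_ind - ms_resid) / n_bar
    if var_ind < 0:
        truncated.append("individual")
        var_ind = 0.0
    var_trt = (ms_trt - ms_ind) / (b_bar * n_bar)
    if var_trt < 0:
        truncated.append("treatment")
        var_trt = 0.0
    return VarianceComponents(
        var_treatment=var_trt,
        var_individual=var_ind,
        var_residual=var_resid,
        truncated=truncated,
    )


def simulate_twig_experiment(
    traits: list[IndividualTraits],
    collection_chill_h: np.ndarray,
    daylengths_h: np.ndarray = np.array([8.0, 12.0, 16.0]),
    chill_ref: float | None = None,
    daylength_ref: float = 16.0,
    noise_sd: float = 5.0,
    n_replicates: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic crossed-treatment experiment from the linear trait model.

    Per replicate twig, degree-days at leaf-out are the individual's
    effective requirement (forcing plus linear day-length and chilling
    terms, referenced at 16 h and the longest chilling by default) plus
    Gaussian chamber noise.  The companion ``leafout_doy`` assumes the
    chambers' 16 degC mean (11 degree-days per day above the 5 degC base).
    """
    rng = np.random.default_rng(seed)
    if chill_ref is None:
        chill_ref = float(np.max(collection_chill_h))
    rows = []
    for t in traits:
        for ch in collection_chill_h:
            for dl in daylengths_h:
                req = (
                    t.forcing_req
                    + t.daylength_sensitivity * (dl - daylength_ref)
                    + t.chilling_sensitivity * (ch - chill_ref)
                )
                req = max(req, 1.0)
                for rep in range(n_replicates):
                    dd = max(req + rng.normal(0.0, noise_sd), 1.0)
                    rows.append(
                        {
                            "individual_id": t.id,
                            "collection_chill_h": float(ch),
                            "daylength_h": float(dl),
                            "replicate": rep,
                            "dd_at_leafout": dd,
                            "leafout_doy": dd / 11.0,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_nested_twigs(
    n_treatments: int = 8,
    n_individuals: int = 11,
    n_replicates: int = 8,
    var_treatment: float = 33.0,
    var_individual: float = 52.0,
    var_residual: float = 15.0,
    mean: float = 110.0,
    seed: int = 0,
    exact_components: bool = True,
) -> pd.DataFrame:
    """Synthetic nested design with planted variance components.

    Generates ``leafout_doy`` = mean + treatment effect + individual
    effect (nested within treatment) + replicate noise.  With
    ``exact_components`` (the default) the drawn treatment and individual
    effect vectors are centered and rescaled so their sample variances
    equal the nominal components exactly — the data then really contains
    the planted shares and a recovery check measures estimator error
    rather than the chi-square draw noise of a handful of effects (8
    treatments give only 7 degrees of freedom).  Replicate noise is left
    as drawn; its degrees of freedom are ample.
    """
    rng = np.random.default_rng(seed)

    def _effects(var, size):
        e = rng.normal(0.0, np.sqrt(var), size)
        if exact_components and var > 0 and size > 1:
            e = e - e.mean()
            e *= np.sqrt(var / e.var(ddof=1))
        return e

    t_eff = _effects(var_treatment, n_treatments)
    rows = []
    for t in range(n_treatments):
        i_eff = _effects(var_individual, n_individuals)
        for i in range(n_individuals):
            noise = rng.normal(0.0, np.sqrt(var_residual), n_replicates)
            for r in range(n_replicates):
                rows.append(
                    {
                        "collection_chill_h": 200.0 * (t + 1),
                        "individual_id": f"ind{i:02d}",
                        "replicate": r,
                        "leafout_doy": mean + t_eff[t] + i_eff[i] + noise[r],
                    }
                )
    return pd.DataFrame(rows)
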