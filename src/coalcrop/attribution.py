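"""Fixed-effects attribution of NO2 over cropland to coal generation.

One linear panel model per (season type, 10-km distance band) regresses the
seasonal mean NO2 column density at each cropland point on the five
directional generation-exposure totals plus weather controls, absorbing
point and state-season fixed effects, with standard errors clustered at
the state-season level:

    NO2[i,t] = b_up * Gen_up[i,t] + b_up' * Gen_up'[i,t] + b_cross * ...
               + b_down * Gen_down[i,t] + b_W * W[i,t] + p[i] + c[s,t] + e[i,t]

Coal-attributable NO2 at a point is the fitted directional part summed over
all ten bands, evaluated on the *full* (unfiltered) exposure, and can be
decomposed exactly by station because the model is linear in generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import EXPOSURE_COLUMNS, N_BANDS

#: season types paired with the two crops
SEASON_TYPES = ("monsoon", "winter")
CROP_OF_SEASON_TYPE = {"monsoon": "rice", "winter": "wheat"}
SEASON_TYPE_OF_CROP = {"rice": "monsoon", "wheat": "winter"}

DEFAULT_WEATHER = ("temp_c", "precip_mm")


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when the demeaned design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear or degenerate design columns: {self.columns}")


def demean_two_way(
    panel: pd.DataFrame,
    unit_key: str,
    group_key: str,
    columns=None,
    tol: float = 1e-10,
    max_sweeps: int = 1000,
) -> pd.DataFrame:
    """Remove unit and group means by alternating projections.

    Equivalent to partialling out two sets of additive fixed effects
    (Frisch-Waugh). Iterates unit-demeaning and group-demeaning until every
    within-unit and within-group column mean is below ``tol`` in absolute
    value. Works on balanced and unbalanced panels.
    """
    if columns is None:
        columns = [
            c
            for c in panel.columns
            if c not in (unit_key, group_key) and pd.api.types.is_numeric_dtype(panel[c])
        ]
    u = pd.factorize(panel[unit_key])[0]
    g = pd.factorize(panel[group_key])[0]
    X = demean_arrays(panel[columns].to_numpy(float), u, g, tol=tol, max_sweeps=max_sweeps)
    out = panel.copy()
    out[columns] = X
    return out


def demean_arrays(
    X: np.ndarray, u: np.ndarray, g: np.ndarray, tol: float = 1e-10, max_sweeps: int = 1000
) -> np.ndarray:
    """Array core of two-way demeaning: codes ``u`` (units) and ``g`` (groups)."""
    nu, ng = int(u.max()) + 1, int(g.max()) + 1
    # empty codes (e.g. clusters absent from a band's panel) get a harmless
    # divisor of 1; no row references them so their zero mean is never used
    cu = np.maximum(np.bincount(u, minlength=nu), 1).astype(float)
    cg = np.maximum(np.bincount(g, minlength=ng), 1).astype(float)
    X = np.array(X, dtype=float, copy=True)
    for _ in range(max_sweeps):
        worst = 0.0
        for codes, counts, n in ((u, cu, nu), (g, cg, ng)):
            means = np.empty((n, X.shape[1]))
            for k in range(X.shape[1]):
                means[:, k] = np.bincount(codes, weights=X[:, k], minlength=n) / counts
            X -= means[codes]
            worst = max(worst, np.abs(means).max(initial=0.0))
        if worst < tol:
            return X
    raise np.linalg.LinAlgError(
        f"two-way demeaning did not converge below {tol} in {max_sweeps} sweeps"
    )


def clustered_vcov(
    X: np.ndarray,
    resid: np.ndarray,
    cluster_labels,
    df_absorbed: int = 0,
) -> np.ndarray:
    """Cluster-robust sandwich covariance for OLS coefficients.

    Applies the small-sample factor G/(G-1) * (N-1)/(N-K) where K counts
    the slope parameters plus any absorbed fixed-effect degrees of freedom.
    Inference downstream uses a t distribution with G-1 degrees of freedom.
    """
    codes, uniq = pd.factorize(np.asarray(cluster_labels))
    G = len(uniq)
    if G < 2:
        raise ValueError("clustered covariance requires at least 2 clusters")
    N, k = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    Xu = X * resid[:, None]
    # per-cluster score sums
    S = np.zeros((G, k))
    for j in range(k):
        S[:, j] = np.bincount(codes, weights=Xu[:, j], minlength=G)
    meat = S.T @ S
    K = k + df_absorbed
    correction = G / (G - 1)
    if N - K > 0:
        correction *= (N - 1) / (N - K)
    return correction * (XtX_inv @ meat @ XtX_inv)


@dataclass
class DistanceBandFit:
    """Estimates for one (season type, distance band) exposure model."""

    season_type: str
    band: int
    params: pd.Series  # 5 exposure betas then weather betas
    vcov: pd.DataFrame
    n_obs: int
    n_points: int
    n_clusters: int
    resid_var: float
    weather_names: tuple = DEFAULT_WEATHER

    @property
    def betas(self) -> pd.Series:
        """The five directional coefficients, in category order."""
        return self.params[list(EXPOSURE_COLUMNS)]

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """t intervals with G-1 degrees of freedom (G = number of clusters)."""
        tcrit = stats.t.ppf(1 - alpha / 2, self.n_clusters - 1)
        se = self.bse
        return pd.DataFrame(
            {"lo": self.params - tcrit * se, "hi": self.params + tcrit * se}
        )

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se_clustered": self.bse,
                "ci_lo": ci["lo"],
                "ci_hi": ci["hi"],
            }
        )

    def to_dict(self) -> dict:
        return {
            "season_type": self.season_type,
            "band": self.band,
            "params": self.params.to_dict(),
            "se": self.bse.to_dict(),
            "vcov": self.vcov.to_numpy().tolist(),
            "n_obs": self.n_obs,
            "n_points": self.n_points,
            "n_clusters": self.n_clusters,
            "resid_var": self.resid_var,
        }


def _band_panel(observations, exposures, band):
    """Merge one band's single-station exposures onto the observation table."""
    sub = exposures[
        (exposures["band_index"] == band) & (exposures["n_stations_in_band"] == 1)
    ]
    panel = observations.merge(
        sub[["point_id", "season_id", *EXPOSURE_COLUMNS]],
        on=["point_id", "season_id"],
        how="inner",
    )
    if "cluster" not in panel.columns:
        # relabelled bootstrap copies supply their own cluster column
        panel["cluster"] = panel["state"].astype(str) + "|" + panel["season_id"].astype(str)
    return panel


def fit_band_model(
    observations: pd.DataFrame,
    exposures: pd.DataFrame,
    season_type: str,
    band: int,
    weather=DEFAULT_WEATHER,
    quadratic_weather: bool = False,
    demean_tol: float = 1e-10,
) -> DistanceBandFit:
    """Fit one distance band's exposure model on single-station points.

    ``observations`` must already be restricted to seasons of
    ``season_type`` and carry point_id, season_id, state, no2_umol_m2 and
    the weather columns. Exposure rows are filtered to the band and to
    points with exactly one station there.
    """
    panel = _band_panel(observations, exposures, band)
    if panel.empty:
        raise SingularDesignError(["<no eligible observations in band>"])
    xcols = list(EXPOSURE_COLUMNS) + list(weather)
    if quadratic_weather:
        for w in weather:
            panel[w + "_sq"] = panel[w] ** 2
            xcols.append(w + "_sq")

    clusters = panel["cluster"].to_numpy()
    if len(np.unique(clusters)) < 2:
        raise ValueError("inference requires at least 2 state-season clusters")

    dm = demean_two_way(
        panel, "point_id", "cluster", columns=["no2_umol_m2"] + xcols, tol=demean_tol
    )
    X = dm[xcols].to_numpy(float)
    y = dm["no2_umol_m2"].to_numpy(float)

    scale = np.abs(X).max(axis=0)
    dead = scale < 1e-12
    if dead.any() or np.linalg.matrix_rank(X[:, ~dead]) < (~dead).sum():
        bad = [c for c, d in zip(xcols, dead) if d]
        if not bad:  # collinearity among live columns: report via QR pivoting
            r = np.linalg.qr(X, mode="r")
            bad = [xcols[i] for i in np.where(np.abs(np.diag(r)) < 1e-9)[0]]
        raise SingularDesignError(bad or xcols)

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n_points = panel["point_id"].nunique()
    n_groups = len(np.unique(clusters))
    df_absorbed = n_points + n_groups - 1
    vcov = clustered_vcov(X, resid, clusters, df_absorbed=df_absorbed)
    dof = max(len(y) - len(xcols) - df_absorbed, 1)
    return DistanceBandFit(
        season_type=season_type,
        band=band,
        params=pd.Series(beta, index=xcols),
        vcov=pd.DataFrame(vcov, index=xcols, columns=xcols),
        n_obs=len(y),
        n_points=n_points,
        n_clusters=n_groups,
        resid_var=float(resid @ resid) / dof,
        weather_names=tuple(weather),
    )


def fit_all_bands(
    observations: pd.DataFrame,
    exposures: pd.DataFrame,
    seasons: pd.DataFrame,
    weather=DEFAULT_WEATHER,
    quadratic_weather: bool = False,
) -> dict:
    """Fit the 10 band models for each season type present in ``seasons``.

    Returns {(season_type, band): DistanceBandFit}. Raises if any band with
    exposure data cannot be fitted.
    """
    obs = add_season_type(observations, seasons)
    fits = {}
    for st in SEASON_TYPES:
        obs_st = obs[obs["season_type"] == st]
        if obs_st.empty:
            continue
        exp_st = exposures[exposures["season_id"].isin(obs_st["season_id"].unique())]
        for band in range(N_BANDS):
            fits[(st, band)] = fit_band_model(
                obs_st, exp_st, st, band, weather=weather, quadratic_weather=quadratic_weather
            )
    return fits


def add_season_type(df: pd.DataFrame, seasons: pd.DataFrame) -> pd.DataFrame:
    """Attach a season_type column derived from each season's crop."""
    stype = seasons.set_index("season_id")["crop"].map(SEASON_TYPE_OF_CROP)
    out = df.copy()
    out["season_type"] = out["season_id"].map(stype)
    if out["season_type"].isna().any():
        missing = out.loc[out["season_type"].isna(), "season_id"].unique()
        raise KeyError(f"seasons missing from season table: {list(missing)}")
    return out


class MissingBandFitError(KeyError):
    pass


def attribute_no2(
    exposures: pd.DataFrame,
    fits: dict,
    seasons: pd.DataFrame,
    per_station_exposures: pd.DataFrame | None = None,
):
    """Coal-attributable NO2 per point x season.

    Applies each band's fitted directional coefficients to the FULL
    exposure (all stations, no single-station filter) and sums over bands.
    Negative contributions are kept as estimated.

    Returns ``totals`` (point_id, season_id, coal_no2_total) and, when a
    per-station exposure table is supplied, ``by_station`` with a
    station_id column whose entries sum exactly to the totals.
    """
    totals = _apply_fits(exposures, fits, seasons, ["point_id", "season_id"])
    totals = totals.rename(columns={"attr": "coal_no2_total"})
    by_station = None
    if per_station_exposures is not None:
        by_station = _apply_fits(
            per_station_exposures, fits, seasons, ["point_id", "season_id", "station_id"]
        ).rename(columns={"attr": "coal_no2"})
    return totals, by_station


def _apply_fits(exposures, fits, seasons, keys):
    exp = add_season_type(exposures, seasons)
    for (st, band) in set(zip(exp["season_type"], exp["band_index"])):
        if (st, band) not in fits:
            raise MissingBandFitError(
                f"no fitted model for season_type={st!r} band={band}"
            )
    beta_mat = {
        (st, band): getattr(fit, "betas", fit)[list(EXPOSURE_COLUMNS)].to_numpy()
        for (st, band), fit in fits.items()
    }
    G = exp[list(EXPOSURE_COLUMNS)].to_numpy(float)
    attr = np.zeros(len(exp))
    key = list(zip(exp["season_type"], exp["band_index"]))
    key_codes, key_uniq = pd.factorize(pd.Series(key))
    for code, k in enumerate(key_uniq):
        m = key_codes == code
        attr[m] = G[m] @ beta_mat[tuple(k)]
    exp = exp[keys].copy()
    exp["attr"] = attr
    return exp.groupby(keys, as_index=False)["attr"].sum()
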