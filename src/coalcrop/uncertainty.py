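"""State-season cluster bootstrap for attribution-derived quantities.

Each iteration resamples whole state-season clusters with replacement
(relabelling drawn copies as distinct clusters), re-applies the
single-station filter, refits the ten distance-band models, draws the
NO2->NIRv coefficient once from its Gaussian, and recomputes four quantity
families on the FULL (non-resampled) data:

* state-level attributable NO2 (average over the state's cropland points),
* cropland fractions by yield-gain category,
* state output gains (tons and USD),
* station-level damages (USD).

95% prediction intervals are the empirical 2.5th/97.5th percentiles of the
iteration distributions. One bootstrap is run per season type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .attribution import (
    DEFAULT_WEATHER,
    SingularDesignError,
    attribute_no2,
    demean_arrays,
)
from .damages import EconomicParams, state_output_table, station_damage_table, yield_change
from .exposure import EXPOSURE_COLUMNS, N_BANDS

logger = logging.getLogger(__name__)

#: lower edges of the yield-gain bins reported as cropland fractions
YIELD_GAIN_BINS = (0.0, 0.01, 0.05, 0.10)
YIELD_GAIN_LABELS = ("lt1pct", "1to5pct", "5to10pct", "ge10pct")


@dataclass
class BootstrapConfig:
    n_iterations: int = 2500
    level: float = 0.95
    seed: int = 0
    season_type: str = "monsoon"
    max_skip_fraction: float = 0.05
    keep_samples: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0 < self.level < 1:
            raise ValueError("level must be in (0,1)")
        if self.season_type not in ("monsoon", "winter"):
            raise ValueError("season_type must be monsoon or winter")


@dataclass
class BootstrapResult:
    """Percentile interval per key for one quantity family."""

    quantity: str
    keys: pd.DataFrame  # one row per key
    lo: np.ndarray
    hi: np.ndarray
    point: np.ndarray | None = None
    samples: np.ndarray | None = None  # (n_iterations, n_keys) if kept
    n_effective: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = self.keys.copy()
        if self.point is not None:
            out["estimate"] = self.point
        out["lo"] = self.lo
        out["hi"] = self.hi
        out["quantity"] = self.quantity
        out["n_effective"] = self.n_effective
        return out


def percentile_interval(samples, level: float = 0.95):
    """Empirical percentile interval, linear interpolation between order stats."""
    s = np.asarray(samples, float)
    if s.size == 0:
        raise ValueError("percentile_interval requires at least one sample")
    a = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(s, [a, 100.0 - a], axis=0, method="linear")
    return lo, hi


def resample_clusters(panel: pd.DataFrame, cluster_key, rng) -> pd.DataFrame:
    """Draw the panel's clusters with replacement, relabelling copies.

    ``cluster_key`` is a column name or list of column names identifying
    the cluster. The returned frame carries a ``cluster`` column in which
    each drawn copy is a distinct label, so fixed-effect demeaning and
    clustered inference treat copies as separate groups.
    """
    keys = [cluster_key] if isinstance(cluster_key, str) else list(cluster_key)
    labels = panel[keys].astype(str).agg("|".join, axis=1)
    uniq = np.sort(labels.unique())
    if len(uniq) < 2:
        draws = uniq  # degenerate: single cluster resamples to itself
    else:
        draws = rng.choice(uniq, size=len(uniq), replace=True)
    parts = []
    for k, lab in enumerate(draws):
        part = panel[labels == lab].copy()
        part["cluster"] = f"{lab}#{k}"
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


class ClusterResampler:
    """Pre-indexed per-band panels for fast repeated cluster refits.

    Stores, for each distance band, the single-station regression arrays of
    the original panel grouped by state-season cluster, so a bootstrap
    iteration only concatenates row blocks and re-runs demeaned OLS. The
    estimator is identical to :func:`fit_band_model` on the relabelled
    resampled panel (asserted in the test suite).
    """

    def __init__(self, obs_st, exp_st, season_type, weather=DEFAULT_WEATHER):
        self.season_type = season_type
        self.xcols = list(EXPOSURE_COLUMNS) + list(weather)
        labels_all = obs_st["state"].astype(str) + "|" + obs_st["season_id"].astype(str)
        self.clusters = np.sort(labels_all.unique())
        self.bands = {}
        empty = np.empty(0, dtype=int)
        for band in range(N_BANDS):
            sub = exp_st[(exp_st["band_index"] == band) & (exp_st["n_stations_in_band"] == 1)]
            panel = obs_st.merge(
                sub[["point_id", "season_id", *self.xcols[:5]]],
                on=["point_id", "season_id"],
                how="inner",
            )
            labels = (panel["state"].astype(str) + "|" + panel["season_id"].astype(str)).to_numpy()
            self.bands[band] = {
                "y": panel["no2_umol_m2"].to_numpy(float),
                "X": panel[self.xcols].to_numpy(float),
                "point": pd.factorize(panel["point_id"])[0],
                "idx": {
                    lab: np.flatnonzero(labels == lab) for lab in np.unique(labels)
                },
                "empty": empty,
            }

    def draw(self, rng):
        """One cluster draw (with replacement) over the cluster universe."""
        if len(self.clusters) < 2:
            return np.array(self.clusters)
        return rng.choice(self.clusters, size=len(self.clusters), replace=True)

    def refit(self, draws) -> dict:
        """Refit all bands on the drawn clusters; {(season_type, band): betas}."""
        betas = {}
        for band, bd in self.bands.items():
            blocks = [bd["idx"].get(lab, bd["empty"]) for lab in draws]
            rows = np.concatenate(blocks) if blocks else bd["empty"]
            if len(rows) == 0:
                raise SingularDesignError([f"band {band}: no observations in resample"])
            g = np.concatenate(
                [np.full(len(b), k, dtype=int) for k, b in enumerate(blocks)]
            )
            u = np.unique(bd["point"][rows], return_inverse=True)[1]
            mat = np.column_stack([bd["y"][rows], bd["X"][rows]])
            dm = demean_arrays(mat, u, g)
            X, y = dm[:, 1:], dm[:, 0]
            if np.any(np.abs(X).max(axis=0) < 1e-12) or (
                np.linalg.matrix_rank(X) < X.shape[1]
            ):
                raise SingularDesignError([f"band {band}: rank-deficient resample"])
            beta = np.linalg.lstsq(X, y, rcond=None)[0]
            betas[(self.season_type, band)] = pd.Series(beta, index=self.xcols)
        return betas


def compute_quantities(
    fits: dict,
    beta_no2: float,
    observations: pd.DataFrame,
    exposures: pd.DataFrame,
    per_station_exposures: pd.DataFrame,
    seasons: pd.DataFrame,
    outputs: pd.DataFrame,
    target_season_ids,
    econ: EconomicParams,
) -> dict:
    """The four quantity families for one coefficient set, on the full data.

    Returns {name: Series indexed by key}. ``observations`` must carry
    point_id, season_id, state, crop_fraction, nirv, no2_umol_m2.
    """
    target_season_ids = list(target_season_ids)
    exp_t = exposures[exposures["season_id"].isin(target_season_ids)]
    per_st_t = per_station_exposures[
        per_station_exposures["season_id"].isin(target_season_ids)
    ]
    obs_t = observations[observations["season_id"].isin(target_season_ids)]
    totals, by_station = attribute_no2(exp_t, fits, seasons, per_station_exposures=per_st_t)

    merged = obs_t.merge(totals, on=["point_id", "season_id"], how="left")
    merged["coal_no2_total"] = merged["coal_no2_total"].fillna(0.0)

    out = {}
    state_no2 = merged.groupby("state")["coal_no2_total"].mean()
    out["state_attributable_no2"] = state_no2

    ok = merged[merged["nirv"] > econ.nirv_baseline].copy()
    ok["ygain"] = yield_change(ok["nirv"], ok["coal_no2_total"], beta_no2)
    bins = list(YIELD_GAIN_BINS) + [np.inf]
    ok["gain_cat"] = pd.cut(
        ok["ygain"].clip(lower=0.0), bins=bins, labels=YIELD_GAIN_LABELS, right=False,
        include_lowest=True,
    )
    w = ok.groupby(["state", "gain_cat"], observed=False)["crop_fraction"].sum()
    tot = ok.groupby("state")["crop_fraction"].sum()
    frac = (w / tot).fillna(0.0)
    out["cropland_fraction_by_gain"] = frac

    beta_by_season = {sid: beta_no2 for sid in target_season_ids}
    st = state_output_table(totals, obs_t, outputs, beta_by_season)
    crop_of = seasons.set_index("season_id")["crop"]
    st["usd_lost"] = [
        t * econ.price(crop_of[sid]) for t, sid in zip(st["tons_lost"], st["season_id"])
    ]
    out["state_output_gain_tons"] = st.set_index(["state", "season_id"])["tons_lost"]
    out["state_output_gain_usd"] = st.set_index(["state", "season_id"])["usd_lost"]

    sd = station_damage_table(
        by_station, obs_t, outputs, seasons, econ, beta_no2_by_season=beta_by_season
    )
    out["station_damage_usd"] = sd.set_index(["station_id", "season_id"])["usd_lost"]
    return out


class QuantityEngine:
    """Precomputed linear maps from band coefficients to the four quantities.

    For fixed data every bootstrap quantity is built from the point-level
    attributable NO2, which is linear in the 50 directional coefficients
    (10 bands x 5 categories). This class aggregates the exposure tables
    into matrices once, so each iteration is a handful of matrix-vector
    products. Results match :func:`compute_quantities` exactly (asserted in
    the test suite).
    """

    def __init__(
        self, observations, exposures, per_station_exposures, seasons, outputs,
        target_season_ids, econ, season_type,
    ):
        self.econ = econ
        self.season_ids = list(target_season_ids)
        self.season_type = season_type
        crop_of = seasons.set_index("season_id")["crop"]
        self.crops = {sid: crop_of[sid] for sid in self.season_ids}
        cats = list(EXPOSURE_COLUMNS)

        obs = observations[observations["season_id"].isin(self.season_ids)]
        self.states = np.sort(obs["state"].unique())
        state_code = {s: i for i, s in enumerate(self.states)}
        ns = len(self.states)

        def beta_col(band_series):
            return band_series.to_numpy(int)

        per = {}
        for sid in self.season_ids:
            o = obs[obs["season_id"] == sid].reset_index(drop=True)
            pt_code = {p: i for i, p in enumerate(o["point_id"])}
            npt = len(o)
            e = exposures[exposures["season_id"] == sid]
            # P: point x 50 exposure aggregation (col = band*5 + category)
            P = np.zeros((npt, 50))
            rows = e["point_id"].map(pt_code).to_numpy()
            ok_rows = ~pd.isna(rows)
            rows = rows[ok_rows].astype(int)
            eb = beta_col(e["band_index"][ok_rows])
            G = e[cats].to_numpy(float)[ok_rows]
            for c in range(5):
                np.add.at(P, (rows, eb * 5 + c), G[:, c])

            st_codes = o["state"].map(state_code).to_numpy(int)
            nirv = o["nirv"].to_numpy(float)
            cf = o["crop_fraction"].to_numpy(float)
            good = nirv > econ.nirv_baseline

            # state mean attributable NO2: (ns x 50) / state point counts
            M = np.zeros((ns, 50))
            np.add.at(M, st_codes, P)
            M /= np.maximum(np.bincount(st_codes, minlength=ns), 1)[:, None].astype(float)

            # output-gain pieces: state numerator matrix and scalar denominator
            NUM = np.zeros((ns, 50))
            np.add.at(NUM, st_codes[good], P[good] * cf[good, None])
            den = np.bincount(
                st_codes[good], weights=(nirv[good] - econ.nirv_baseline) * cf[good],
                minlength=ns,
            )
            out_tons = (
                outputs.set_index(["state", "season_id"])["output_tons"]
                .reindex(pd.MultiIndex.from_product([self.states, [sid]]))
                .to_numpy(float)
            )
            if np.isnan(out_tons).any():
                missing = [s for s, v in zip(self.states, out_tons) if np.isnan(v)]
                raise KeyError(f"states missing from output table: {missing} ({sid})")

            # station damages: (state, station) x 50 over nirv-good points
            ps = per_station_exposures[per_station_exposures["season_id"] == sid]
            ps_rows = ps["point_id"].map(pt_code).to_numpy()
            ps_ok = ~pd.isna(ps_rows)
            ps_rows = ps_rows[ps_ok].astype(int)
            ps_good = good[ps_rows]
            ps_rows_g = ps_rows[ps_good]
            stations = np.sort(ps["station_id"].unique())
            stat_code = {s: i for i, s in enumerate(stations)}
            nstat = len(stations)
            sc = ps["station_id"].map(stat_code).to_numpy(int)[ps_ok][ps_good]
            pb = beta_col(ps["band_index"][ps_ok]) [ps_good]
            PG = ps[cats].to_numpy(float)[ps_ok][ps_good]
            D = np.zeros((ns * nstat, 50))
            flat = st_codes[ps_rows_g] * nstat + sc
            for c in range(5):
                np.add.at(D, (flat, pb * 5 + c), PG[:, c] * cf[ps_rows_g, None][:, 0])
            per[sid] = {
                "P": P, "good": good, "nirv": nirv, "cf": cf, "st_codes": st_codes,
                "M": M, "NUM": NUM, "den": den, "out_tons": out_tons,
                "D": D.reshape(ns, nstat, 50), "stations": stations,
            }
        self._per = per

    def _betavec(self, fits):
        vec = np.empty(50)
        for band in range(N_BANDS):
            b = fits[(self.season_type, band)]
            b = getattr(b, "betas", b)
            vec[band * 5 : band * 5 + 5] = np.asarray(b[: 5] if not hasattr(b, "loc") else b[list(EXPOSURE_COLUMNS)])
        return vec

    def compute(self, fits, beta_no2: float) -> dict:
        vec = self._betavec(fits)
        econ = self.econ
        out = {}
        no2_parts, frac_parts, tons_parts, usd_parts, stat_parts = [], [], [], [], []
        for sid in self.season_ids:
            d = self._per[sid]
            no2_parts.append(pd.Series(d["M"] @ vec, index=pd.Index(self.states, name="state")))

            coal = d["P"] @ vec
            good = d["good"]
            ygain = np.clip(
                coal[good] * beta_no2 / (d["nirv"][good] - econ.nirv_baseline), 0.0, None
            )
            binidx = np.searchsorted(np.array(YIELD_GAIN_BINS[1:]), ygain, side="right")
            ns = len(self.states)
            wsum = np.bincount(
                d["st_codes"][good] * 4 + binidx, weights=d["cf"][good], minlength=ns * 4
            ).reshape(ns, 4)
            tot = wsum.sum(axis=1)
            frac = wsum / np.maximum(tot, 1e-300)[:, None]
            frac_parts.append(
                pd.Series(
                    frac.ravel(),
                    index=pd.MultiIndex.from_product(
                        [self.states, list(YIELD_GAIN_LABELS)], names=["state", "gain_cat"]
                    ),
                )
            )

            with np.errstate(invalid="ignore", divide="ignore"):
                tons = d["out_tons"] * beta_no2 * (d["NUM"] @ vec) / d["den"]
            tons = np.where(d["den"] > 0, tons, 0.0)
            idx = pd.MultiIndex.from_product([self.states, [sid]], names=["state", "season_id"])
            price = econ.price(self.crops[sid])
            tons_parts.append(pd.Series(tons, index=idx))
            usd_parts.append(pd.Series(tons * price, index=idx))

            stat_tons = np.einsum(
                "spk,k->sp", d["D"], vec
            ) * beta_no2 / np.maximum(d["den"], 1e-300)[:, None] * (
                d["out_tons"][:, None]
            )
            stat_usd = stat_tons.sum(axis=0) * price
            stat_parts.append(
                pd.Series(stat_usd, index=pd.MultiIndex.from_product([d["stations"], [sid]], names=["station_id", "season_id"]))
            )
        out["state_attributable_no2"] = _mean_concat(no2_parts)
        out["cropland_fraction_by_gain"] = _mean_concat(frac_parts)
        out["state_output_gain_tons"] = pd.concat(tons_parts)
        out["state_output_gain_usd"] = pd.concat(usd_parts)
        out["station_damage_usd"] = pd.concat(stat_parts)
        return out


def _mean_concat(parts):
    if len(parts) == 1:
        return parts[0]
    return pd.concat(parts, axis=1).mean(axis=1)


def bootstrap_run(
    observations: pd.DataFrame,
    exposures: pd.DataFrame,
    per_station_exposures: pd.DataFrame,
    seasons: pd.DataFrame,
    outputs: pd.DataFrame,
    econ: EconomicParams,
    config: BootstrapConfig,
    target_year: int | None = None,
) -> dict:
    """Run the cluster bootstrap for one season type.

    The band models are refit on resampled state-season clusters; the
    quantities are evaluated on the full data for the target year's season
    of the configured type (default: the latest year).
    """
    st = config.season_type
    crop = {"monsoon": "rice", "winter": "wheat"}[st]
    sids = seasons.loc[seasons["crop"] == crop, "season_id"]
    obs_st = observations[observations["season_id"].isin(sids)].copy()
    exp_st = exposures[exposures["season_id"].isin(sids)]
    if target_year is None:
        target_year = int(seasons.loc[seasons["crop"] == crop, "year"].max())
    target_ids = seasons.loc[
        (seasons["crop"] == crop) & (seasons["year"] == target_year), "season_id"
    ]

    rng = np.random.default_rng(config.seed)
    beta_mean, beta_se = econ.beta(crop), econ.beta_se(crop)
    resampler = ClusterResampler(obs_st, exp_st, st)
    engine = QuantityEngine(
        observations, exp_st, per_station_exposures, seasons, outputs,
        target_ids, econ, st,
    )

    records = []
    n_skipped = 0
    for it in range(config.n_iterations):
        draws = resampler.draw(rng)
        beta_draw = beta_mean + (beta_se * rng.standard_normal() if beta_se > 0 else 0.0)
        try:
            fits = resampler.refit(draws)
        except (SingularDesignError, np.linalg.LinAlgError, ValueError) as e:
            n_skipped += 1
            logger.info("bootstrap iteration %d skipped: %s", it, e)
            continue
        records.append(engine.compute(fits, beta_draw))

    if n_skipped > config.max_skip_fraction * config.n_iterations:
        raise RuntimeError(
            f"bootstrap failed: {n_skipped}/{config.n_iterations} iterations skipped"
        )
    if not records:
        raise RuntimeError("bootstrap produced no successful iterations")

    results = {}
    for name in records[0]:
        frame = pd.DataFrame([r[name] for r in records])  # rows = iterations
        frame = frame.fillna(0.0)
        lo, hi = percentile_interval(frame.to_numpy(), config.level)
        keys = frame.columns.to_frame(index=False)
        if keys.shape[1] == 1 and keys.columns[0] == 0:
            keys.columns = ["key"]
        results[name] = BootstrapResult(
            quantity=name,
            keys=keys,
            lo=lo,
            hi=hi,
            samples=frame.to_numpy() if config.keep_samples else None,
            n_effective=len(records),
        )
    return results
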