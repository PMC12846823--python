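"""Growth-and-yield regression linking wood volume to age, climate and CO2.

The model is a log-linear yield function estimated by OLS on plot-level
inventory observations::

    ln V_i = alpha_g + f(age_i)
             + sum_s sum_{k=1..3} [ bT_{s,k} * Tbar_{s,i}^k + bP_{s,k} * Pbar_{s,i}^k ]
             + gamma * ln(CO2bar_i) + FE + eps_i

where ``V_i`` is aboveground wood volume density (m^3 ha^-1), ``g`` the
forest group, ``f(age)`` a saturating age curve (default the Clutter form
``-theta/age``), ``Tbar_s``/``Pbar_s`` the lifetime-mean temperature and
precipitation of season ``s`` over the stand's lifetime window, and
``CO2bar`` the lifetime-mean atmospheric CO2 concentration, entering in
logs so ``gamma`` is an elasticity.  Seasonal climate enters as a cubic
polynomial in the centred (and, for precipitation, rescaled) lifetime
mean.  Optional time-varying fixed effects absorb slow secular drivers
such as nitrogen deposition.  Standard errors are cluster-robust by
location (county).

Usage follows the Model/Results convention::

    model = YieldModel.from_tables(plots, climate, co2, spec=ModelSpec())
    res = model.fit()
    res.summary()
    res.predict_volume(exposure, age=40, group="Oak/Hickory")
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .exposure import SEASONS, CO2Index, ClimateIndex, ExposureCovariates, exposure_table

# Precipitation lifetime means are O(100 mm); rescale before powering so the
# cubic basis is well conditioned.  Temperature is already O(1-10).
T_SCALE = 1.0
P_SCALE = 100.0

AGE_FORMS = ("clutter", "log", "cubic")


class ScopeWarning(UserWarning):
    """Prediction requested outside the fitted model's support."""


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one yield regression.

    Parameters
    ----------
    age_form : {'clutter', 'log', 'cubic'}
        Shape of the per-group age curve: ``-theta/age`` (saturating,
        default), ``theta * ln(age)``, or a cubic in ``age/100``.
    origin_filter : {'natural', 'planted', None}
        Stand-origin restriction applied before fitting; the cross-type
        fit uses naturally regenerated stands only.
    groups : tuple of str, optional
        Forest groups to keep (None keeps all present).
    age_range : (int, int)
        Inclusive stand-age support of the fit.
    fixed_effects : {None, 'period', 'year'}
        Time-varying fixed effects; 'period' bins measurement years at
        ``period_breaks``.
    climate_centers : 'sample_mean' or mapping
        Centres subtracted from seasonal lifetime means before powering.
        A mapping uses keys like ``'T_winter'``/``'P_summer'``.
    """

    age_form: str = "clutter"
    origin_filter: str | None = "natural"
    groups: tuple[str, ...] | None = None
    age_range: tuple[int, int] = (1, 150)
    fixed_effects: str | None = None
    period_breaks: tuple[int, ...] = (1990, 2000, 2010)
    climate_centers: str | Mapping[str, float] = "sample_mean"

    def __post_init__(self):
        if self.age_form not in AGE_FORMS:
            raise ValueError(f"age_form must be one of {AGE_FORMS}, got {self.age_form!r}")
        if self.origin_filter not in ("natural", "planted", None):
            raise ValueError(f"invalid origin_filter {self.origin_filter!r}")
        if self.fixed_effects not in (None, "period", "year"):
            raise ValueError(f"invalid fixed_effects {self.fixed_effects!r}")


def climate_columns() -> list[str]:
    """Names of the 24 seasonal climate polynomial coefficients."""
    return [f"{v}_{s}^{k}" for s in SEASONS for v in ("T", "P") for k in (1, 2, 3)]


def _age_columns(age: np.ndarray, form: str) -> dict[str, np.ndarray]:
    if form == "clutter":
        return {"neg_inv_age": -1.0 / age}
    if form == "log":
        return {"log_age": np.log(age)}
    return {f"age^{k}": (age / 100.0) ** k for k in (1, 2, 3)}


def _climate_basis(
    t_means: Mapping[str, np.ndarray], p_means: Mapping[str, np.ndarray],
    centers: Mapping[str, float],
) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for s in SEASONS:
        t = (np.asarray(t_means[s]) - centers[f"T_{s}"]) / T_SCALE
        p = (np.asarray(p_means[s]) - centers[f"P_{s}"]) / P_SCALE
        for k in (1, 2, 3):
            cols[f"T_{s}^{k}"] = t ** k
            cols[f"P_{s}^{k}"] = p ** k
    return cols


def _cr2_pieces(X: np.ndarray, groups: pd.Series):
    """Per-cluster CR2 adjustment pieces shared by the covariance and the dfs.

    Returns (xtx_inv, list of (row positions, X_g, A_g)) where
    A_g = (I - H_gg)^{-1/2} is the inverse symmetric square root of the
    cluster's own leverage block.
    """
    xtx_inv = np.linalg.inv(X.T @ X)
    codes, _ = pd.factorize(groups.to_numpy())
    pieces = []
    for g in range(codes.max() + 1):
        pos = np.flatnonzero(codes == g)
        Xg = X[pos]
        Hgg = Xg @ xtx_inv @ Xg.T
        w, V = np.linalg.eigh(np.eye(len(pos)) - Hgg)
        w = np.clip(w, 1e-10, None)
        Ag = (V * (w ** -0.5)) @ V.T
        pieces.append((pos, Xg, Ag))
    return xtx_inv, pieces


def _cr2_covariance(X: np.ndarray, resid: np.ndarray, groups: pd.Series,
                    pieces=None) -> np.ndarray:
    """Bias-reduced (CR2) cluster-robust covariance.

    Each cluster's residuals are rescaled by (I - H_gg)^{-1/2} before
    entering the sandwich meat; under homoskedastic errors the result is
    an unbiased estimate of the OLS coefficient covariance.
    """
    if pieces is None:
        pieces = _cr2_pieces(X, groups)
    xtx_inv, per_cluster = pieces
    k = X.shape[1]
    meat = np.zeros((k, k))
    for pos, Xg, Ag in per_cluster:
        s = Xg.T @ (Ag @ resid[pos])
        meat += np.outer(s, s)
    return xtx_inv @ meat @ xtx_inv


def _satterthwaite_dfs(X: np.ndarray, groups: pd.Series, target_idx: np.ndarray,
                       pieces=None) -> np.ndarray:
    """Bell-McCaffrey effective degrees of freedom per coefficient.

    The CR2 variance estimator of coefficient j is a quadratic form in
    the residuals; under homoskedastic errors its distribution is a
    weighted chi-square mixture with weights given by the eigenvalues of
    B = Cov(q)/sigma^2, q_g = z_g' u_g, z_g = A_g X_g (X'X)^{-1} e_j.
    The Satterthwaite approximation df = (tr B)^2 / tr(B^2) can be far
    below the cluster count when a coefficient's identification is
    concentrated in a few high-leverage clusters (the cubic climate
    terms are the canonical case here).
    """
    if pieces is None:
        pieces = _cr2_pieces(X, groups)
    xtx_inv, per_cluster = pieces
    G = len(per_cluster)
    k = X.shape[1]
    # P_g = M_g'M_g and Q_g = X_g'M_g with M_g = A_g X_g (X'X)^{-1}
    P = np.empty((G, k, k))
    Q = np.empty((G, k, k))
    for g, (pos, Xg, Ag) in enumerate(per_cluster):
        Mg = Ag @ Xg @ xtx_inv
        P[g] = Mg.T @ Mg
        Q[g] = Xg.T @ Mg
    dfs = np.empty(len(target_idx))
    for j, i in enumerate(target_idx):
        s = P[:, i, i]                      # z_g'z_g
        t = Q[:, :, i]                      # X_g'z_g, (G, k)
        W = t @ xtx_inv @ t.T               # cross-cluster hat corrections
        tr_b = s.sum() - np.trace(W)
        b_diag_adjust = np.diag(s) - W
        tr_b2 = float((b_diag_adjust * b_diag_adjust.T).sum())
        dfs[j] = tr_b ** 2 / tr_b2
    return dfs


class YieldModel:
    """OLS yield-function model over plots with precomputed exposures.

    ``plots`` needs columns ``location, group, origin, age, year,
    volume_m3ha``; ``exposures`` (aligned on index) the columns produced by
    :func:`forestsink.exposure.exposure_table`.
    """

    def __init__(self, plots: pd.DataFrame, exposures: pd.DataFrame, spec: ModelSpec = ModelSpec()):
        self.spec = spec
        df = plots.join(exposures, how="inner")
        if spec.origin_filter is not None:
            df = df[df["origin"] == spec.origin_filter]
        if spec.groups is not None:
            df = df[df["group"].isin(spec.groups)]
        lo, hi = spec.age_range
        df = df[(df["age"] >= lo) & (df["age"] <= hi)]
        n_zero = int((df["volume_m3ha"] <= 0).sum())
        if n_zero:
            df = df[df["volume_m3ha"] > 0]
        self.n_dropped_zero_volume = n_zero
        if df.empty:
            raise ValueError("no observations left after filtering")
        self._df = df.copy()
        self.groups = tuple(sorted(df["group"].unique()))

        if spec.climate_centers == "sample_mean":
            self.centers = {
                f"{v}_{s}": float(df[f"{v}_{s}"].mean()) for s in SEASONS for v in ("T", "P")
            }
        else:
            self.centers = dict(spec.climate_centers)

        self.exog, self.endog, self.cluster_groups = self._build_design(df)
        self._check_rank()

    @classmethod
    def from_tables(
        cls,
        plots: pd.DataFrame,
        climate: pd.DataFrame | ClimateIndex,
        co2: pd.DataFrame | CO2Index,
        spec: ModelSpec = ModelSpec(),
    ) -> "YieldModel":
        """Build the model directly from plot, climate and CO2 tables."""
        expo = exposure_table(plots, climate, co2)
        return cls(plots, expo, spec)

    def _build_design(self, df: pd.DataFrame):
        spec = self.spec
        n = len(df)
        cols: dict[str, np.ndarray] = {}
        age = df["age"].to_numpy(dtype=float)
        age_terms = _age_columns(age, spec.age_form)
        for g in self.groups:
            mask = (df["group"] == g).to_numpy(dtype=float)
            cols[f"alpha[{g}]"] = mask
            for name, vals in age_terms.items():
                cols[f"{name}[{g}]"] = vals * mask
        t_means = {s: df[f"T_{s}"].to_numpy() for s in SEASONS}
        p_means = {s: df[f"P_{s}"].to_numpy() for s in SEASONS}
        cols.update(_climate_basis(t_means, p_means, self.centers))
        cols["log_co2"] = np.log(df["co2_mean"].to_numpy())
        if spec.fixed_effects == "year":
            levels = sorted(df["year"].unique())[1:]
            for lv in levels:
                cols[f"fe[{lv}]"] = (df["year"] == lv).to_numpy(dtype=float)
        elif spec.fixed_effects == "period":
            period = np.digitize(df["year"].to_numpy(), spec.period_breaks)
            for lv in sorted(set(period))[1:]:
                cols[f"fe[period{lv}]"] = (period == lv).astype(float)
        X = pd.DataFrame(cols, index=df.index)
        y = np.log(df["volume_m3ha"].to_numpy())
        return X, pd.Series(y, index=df.index, name="log_volume"), df["location"]

    def _check_rank(self):
        X = self.exog.to_numpy()
        if len(X) < X.shape[1]:
            raise ValueError(
                f"{len(X)} observations cannot identify {X.shape[1]} coefficients"
            )
        _, _, pivots = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(scipy.linalg.qr(X[:, pivots], mode="economic")[1]))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            bad = [self.exog.columns[i] for i in pivots[rank:]]
            raise ValueError(f"design matrix is rank deficient; collinear terms: {bad}")

    def fit(self, cov_type: str = "cluster") -> "YieldResults":
        """Estimate by OLS; default covariance is cluster-robust by location.

        ``cov_type='cluster'`` uses the bias-reduced CR2 estimator: the
        plain CR1 sandwich is biased downward when regressors (here the
        seasonal climate polynomials) vary mostly between clusters, which
        inflates Wald tests; CR2's leverage adjustment is exactly unbiased
        under homoskedasticity.  ``'cluster-cr1'`` gives the plain
        sandwich; any other value is passed through to statsmodels.
        """
        ols = sm.OLS(self.endog, self.exog)
        n_clusters = self.cluster_groups.nunique()
        if cov_type in ("cluster", "cluster-cr1") and n_clusters < 2:
            warnings.warn("only one cluster; falling back to HC1 covariance")
            cov_type = "HC1"
        df_bm = None
        if cov_type == "cluster":
            res = ols.fit()
            X = self.exog.to_numpy()
            pieces = _cr2_pieces(X, self.cluster_groups)
            cov_arr = _cr2_covariance(X, res.resid.to_numpy(),
                                      self.cluster_groups, pieces=pieces)
            df_inference = n_clusters - 1
            # effective dfs for the coefficients used in inference
            targets = [c for c in climate_columns() if c in self.exog.columns]
            targets.append("log_co2")
            idx = np.array([self.exog.columns.get_loc(c) for c in targets])
            df_bm = pd.Series(
                _satterthwaite_dfs(X, self.cluster_groups, idx, pieces=pieces),
                index=targets,
            )
        elif cov_type == "cluster-cr1":
            res = ols.fit(cov_type="cluster", cov_kwds={"groups": self.cluster_groups})
            cov_arr = res.cov_params()
            df_inference = n_clusters - 1
        else:
            res = ols.fit(cov_type=cov_type)
            cov_arr = res.cov_params()
            df_inference = res.df_resid
        return YieldResults(
            params=res.params,
            cov=pd.DataFrame(cov_arr, index=self.exog.columns, columns=self.exog.columns),
            spec=self.spec,
            centers=self.centers,
            groups=self.groups,
            nobs=int(res.nobs),
            df_inference=float(df_inference),
            n_clusters=int(self.cluster_groups.nunique()),
            n_dropped_zero_volume=self.n_dropped_zero_volume,
            cov_type=cov_type,
            rsquared=float(res.rsquared),
            df_bm=df_bm,
        )


class YieldResults:
    """Fitted yield function: coefficients, covariance, scope and predictions."""

    def __init__(
        self,
        params: pd.Series,
        cov: pd.DataFrame,
        spec: ModelSpec,
        centers: Mapping[str, float],
        groups: Sequence[str],
        nobs: int,
        df_inference: float,
        n_clusters: int = 0,
        n_dropped_zero_volume: int = 0,
        cov_type: str = "cluster",
        rsquared: float = float("nan"),
        df_bm: pd.Series | None = None,
    ):
        self.params = pd.Series(params)
        self.cov = pd.DataFrame(cov)
        if not np.allclose(self.cov.to_numpy(), self.cov.to_numpy().T, atol=1e-8):
            raise ValueError("coefficient covariance must be symmetric")
        self.spec = spec
        self.centers = dict(centers)
        self.groups = tuple(groups)
        self.nobs = nobs
        self.df_inference = df_inference
        self.n_clusters = n_clusters
        self.n_dropped_zero_volume = n_dropped_zero_volume
        self.cov_type = cov_type
        self.rsquared = rsquared
        self.df_bm = df_bm

    # -- inference ---------------------------------------------------------

    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def _df_for(self, names) -> float:
        """Reference df: Bell-McCaffrey effective df (minimum over the
        involved coefficients) when available, else the cluster df."""
        if self.df_bm is None:
            return self.df_inference
        dfs = [float(self.df_bm[nm]) for nm in names if nm in self.df_bm.index]
        return min(dfs) if dfs else self.df_inference

    def conf_int(self, name: str, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided confidence interval using the t reference distribution
        with the coefficient's effective degrees of freedom."""
        se = float(self.bse()[name])
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self._df_for([name]))
        b = float(self.params[name])
        return b - tcrit * se, b + tcrit * se

    @property
    def co2_elasticity(self) -> float:
        return float(self.params["log_co2"])

    def f_test_seasonal_poly(self, season: str, variable: str) -> tuple[float, float]:
        """Wald F-test that the cubic polynomial of one seasonal variable is zero.

        ``variable`` is ``'temperature'`` or ``'precipitation'``.  The
        statistic is the quadratic form ``b' S^-1 b / 3`` in the three
        polynomial coefficients with their (cluster-robust) covariance
        block ``S``; the reference distribution is F(3, df).
        """
        v = {"temperature": "T", "precipitation": "P"}.get(variable, variable)
        if v not in ("T", "P"):
            raise KeyError(f"unknown variable {variable!r}")
        if season not in SEASONS:
            raise KeyError(f"unknown season {season!r}")
        names = [f"{v}_{season}^{k}" for k in (1, 2, 3)]
        missing = [nm for nm in names if nm not in self.params.index]
        if missing:
            raise KeyError(f"model does not contain terms {missing}")
        b = self.params[names].to_numpy()
        S = self.cov.loc[names, names].to_numpy()
        F = float(b @ np.linalg.solve(S, b) / len(names))
        p = float(scipy.stats.f.sf(F, len(names), self._df_for(names)))
        return F, p

    # -- prediction --------------------------------------------------------

    def _check_scope(self, age: int, group: str, origin: str | None):
        lo, hi = self.spec.age_range
        if not (lo <= age <= hi):
            warnings.warn(
                f"age {age} outside fitted range [{lo}, {hi}]; extrapolating",
                ScopeWarning, stacklevel=3,
            )
        if self.spec.origin_filter is not None and origin is not None \
                and origin != self.spec.origin_filter:
            warnings.warn(
                f"prediction for origin {origin!r} from a model fitted on "
                f"{self.spec.origin_filter!r} stands", ScopeWarning, stacklevel=3,
            )

    def linear_predictor(
        self,
        tmean: Mapping[str, float],
        prcp: Mapping[str, float],
        co2: float,
        age: int,
        group: str,
    ) -> float:
        if group not in self.groups:
            raise KeyError(f"group {group!r} not in fitted model (has {list(self.groups)})")
        p = self.params
        lp = float(p[f"alpha[{group}]"])
        for name, vals in _age_columns(np.array([float(age)]), self.spec.age_form).items():
            lp += float(p[f"{name}[{group}]"]) * float(vals[0])
        basis = _climate_basis(
            {s: np.array([tmean[s]]) for s in SEASONS},
            {s: np.array([prcp[s]]) for s in SEASONS},
            self.centers,
        )
        for name, vals in basis.items():
            lp += float(p[name]) * float(vals[0])
        lp += float(p["log_co2"]) * np.log(co2)
        return lp

    def predict_volume(
        self,
        exposure: ExposureCovariates,
        age: int | None = None,
        group: str = "",
        origin: str | None = None,
    ) -> float:
        """Expected volume density (m^3 ha^-1) for a stand with the given exposure.

        Fixed effects, when present in the fit, are evaluated at the
        baseline level.  Warns (``ScopeWarning``) outside the fitted age
        range or origin filter.
        """
        if age is None:
            age = exposure.age
        if age <= 0:
            raise ValueError("age must be positive")
        self._check_scope(age, group, origin)
        lp = self.linear_predictor(exposure.tmean, exposure.prcp, exposure.co2, age, group)
        return float(np.exp(lp))

    # -- presentation / serialization --------------------------------------

    def summary(self) -> str:
        se = self.bse()
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = self.params / se
        pvals = 2 * scipy.stats.t.sf(np.abs(tvals), self.df_inference)
        lines = [
            "Yield function (OLS, ln volume)",
            f"  observations: {self.nobs}   clusters: {self.n_clusters}   "
            f"R^2: {self.rsquared:.4f}   cov: {self.cov_type}",
            f"  groups: {len(self.groups)}   age form: {self.spec.age_form}   "
            f"ages {self.spec.age_range[0]}-{self.spec.age_range[1]}   "
            f"origin: {self.spec.origin_filter or 'all'}",
            f"  zero-volume plots dropped: {self.n_dropped_zero_volume}",
            f"  {'term':<24}{'coef':>12}{'se':>11}{'t':>9}{'P>|t|':>9}",
        ]
        for i, name in enumerate(self.params.index):
            lines.append(
                f"  {name:<24}{self.params.iloc[i]:>12.4f}{se.iloc[i]:>11.4f}"
                f"{tvals.iloc[i]:>9.2f}{pvals[i]:>9.3f}"
            )
        return "\n".join(lines)

    def to_json(self, path) -> None:
        payload = {
            "params": {k: float(v) for k, v in self.params.items()},
            "cov_names": list(self.cov.columns),
            "cov": self.cov.to_numpy().tolist(),
            "spec": asdict(self.spec),
            "centers": self.centers,
            "groups": list(self.groups),
            "nobs": self.nobs,
            "df_inference": self.df_inference,
            "n_clusters": self.n_clusters,
            "n_dropped_zero_volume": self.n_dropped_zero_volume,
            "cov_type": self.cov_type,
            "rsquared": self.rsquared,
            "df_bm": None if self.df_bm is None else
                     {k: float(v) for k, v in self.df_bm.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "YieldResults":
        with open(path) as fh:
            d = json.load(fh)
        spec_d = d["spec"]
        for key in ("groups", "age_range", "period_breaks"):
            if spec_d.get(key) is not None:
                spec_d[key] = tuple(spec_d[key])
        if isinstance(spec_d.get("climate_centers"), dict):
            spec_d["climate_centers"] = dict(spec_d["climate_centers"])
        return cls(
            params=pd.Series(d["params"]),
            cov=pd.DataFrame(d["cov"], index=d["cov_names"], columns=d["cov_names"]),
            spec=ModelSpec(**spec_d),
            centers=d["centers"],
            groups=d["groups"],
            nobs=d["nobs"],
            df_inference=d["df_inference"],
            n_clusters=d["n_clusters"],
            n_dropped_zero_volume=d["n_dropped_zero_volume"],
            cov_type=d["cov_type"],
            rsquared=d["rsquared"],
            df_bm=None if d.get("df_bm") is None else pd.Series(d["df_bm"]),
        )

    @classmethod
    def from_coefficients(
        cls,
        params: Mapping[str, float],
        centers: Mapping[str, float],
        groups: Sequence[str],
        spec: ModelSpec = ModelSpec(),
        cov: pd.DataFrame | None = None,
        df_inference: float = 1e9,
    ) -> "YieldResults":
        """Results object from known coefficients (oracle/simulation use)."""
        p = pd.Series(dict(params))
        if cov is None:
            cov = pd.DataFrame(np.eye(len(p)), index=p.index, columns=p.index)
        return cls(
            params=p, cov=cov, spec=spec, centers=centers, groups=groups,
            nobs=0, df_inference=df_inference, cov_type="assumed",
        )
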