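"""Strata-absorbed spline regression.

The identification strategy is within-person, within-year: every
(participant, year) cell gets its own intercept, so only night-to-night
variation inside a participant-year informs the seasonal and environmental
coefficients.  For the Gaussian family the strata intercepts are absorbed by
within-cell demeaning of the outcome and every design column (the
Frisch-Waugh-Lovell partition), which is exact and scales to tens of
thousands of strata.  For binary outcomes the strata intercepts are
eliminated by conditional (strata-matched) logistic likelihood instead —
explicit dummies would suffer incidental-parameter bias in short strata.

The design is: natural spline of day-of-year (boundary knots pinned at days
1 and 365), six day-of-week indicators (Monday reference), plus optional
confounder splines.  No global intercept — the strata absorb it.  Columns
that are constant within every stratum (e.g. participant-year-level
covariates) are exactly collinear with the absorbed intercepts; they are
detected after demeaning and dropped, with bookkeeping kept on the fit.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg
from statsmodels.discrete.conditional_models import ConditionalLogit

from .splines import NaturalSplineBasis, natural_spline_basis

logger = logging.getLogger(__name__)

SEASONAL_BOUNDARY = (1.0, 365.0)
_ZERO_TOL = 1e-9


@dataclass
class FixedEffectsSpec:
    """What to regress on what, within subject/year strata.

    outcome: ``"c_ahi"`` (relative AHI change, %), ``"ahi"`` (absolute,
    events/h) or ``"binary"`` with ``binary_threshold`` 15 or 30.
    ``confounders`` is a list of ``(variable, df)`` pairs; df 1 means a plain
    linear term.
    """

    outcome: str = "c_ahi"
    binary_threshold: float | None = None
    seasonal_df: int = 8
    seasonal_boundary: tuple[float, float] = SEASONAL_BOUNDARY
    dow: bool = True
    confounders: list[tuple[str, int]] = field(default_factory=list)

    def required_columns(self) -> list[str]:
        cols = ["day_of_year"]
        if self.dow:
            cols.append("day_of_week")
        cols += [v for v, _ in self.confounders]
        if self.outcome == "binary":
            cols.append("ahi")
        else:
            cols.append(self.outcome)
        return cols


@dataclass
class TermInfo:
    """Where a model term lives in the design matrix."""

    name: str
    kind: str                      # "spline" | "dow"
    columns: list[int]
    basis: NaturalSplineBasis | None = None

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "columns": self.columns,
            "basis": self.basis.to_dict() if self.basis else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TermInfo":
        basis = NaturalSplineBasis.from_dict(d["basis"]) if d["basis"] else None
        return cls(d["name"], d["kind"], list(d["columns"]), basis)


@dataclass
class ModelFit:
    """A fitted strata-absorbed model, sufficient to recompute any marginal mean.

    ``params``/``cov`` span the full design; entries for columns dropped as
    strata-collinear or rank-deficient are exactly zero and their names are in
    ``dropped``.  ``df_resid`` already accounts for the absorbed strata
    (n - rank - n_strata).
    """

    params: np.ndarray
    cov: np.ndarray
    column_names: list[str]
    terms: list[TermInfo]
    family: str                    # "gaussian" | "binomial"
    n_obs: int
    n_strata: int
    df_resid: int
    resid_var: float | None
    dropped: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def term(self, name: str) -> TermInfo:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"term {name!r} not in fit (have {[t.name for t in self.terms]})")

    def to_dict(self) -> dict:
        return {
            "params": self.params.tolist(),
            "cov": self.cov.tolist(),
            "column_names": self.column_names,
            "terms": [t.to_dict() for t in self.terms],
            "family": self.family,
            "n_obs": self.n_obs,
            "n_strata": self.n_strata,
            "df_resid": self.df_resid,
            "resid_var": self.resid_var,
            "dropped": self.dropped,
            "n_dropped_rows": self.n_dropped_rows,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "ModelFit":
        return cls(
            params=np.asarray(d["params"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            column_names=list(d["column_names"]),
            terms=[TermInfo.from_dict(t) for t in d["terms"]],
            family=d["family"],
            n_obs=int(d["n_obs"]),
            n_strata=int(d["n_strata"]),
            df_resid=int(d["df_resid"]),
            resid_var=d["resid_var"],
            dropped=list(d["dropped"]),
            n_dropped_rows=int(d.get("n_dropped_rows", 0)),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelFit":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_design(nights: pd.DataFrame, spec: FixedEffectsSpec):
    """Assemble outcome, design matrix, strata labels and term metadata.

    Nights with a missing value in any required column are dropped and
    counted.  Returns ``(y, X, strata_codes, terms, column_names, info)``
    where ``info`` carries row bookkeeping and the participant labels used
    for optional cluster-robust inference.
    """
    cols = spec.required_columns()
    missing_cols = [c for c in cols if c not in nights.columns]
    if missing_cols:
        raise ValueError(f"design variables missing from nightly table: {missing_cols}")
    if "year" not in nights.columns:
        nights = nights.copy()
        nights["year"] = pd.DatetimeIndex(nights["date"]).year
    mask = np.ones(len(nights), dtype=bool)
    for c in cols:
        mask &= pd.notna(nights[c]).to_numpy()
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("build_design: dropped %d night(s) with missing values", n_dropped)
    d = nights[mask]
    if not len(d):
        raise ValueError("empty design: every night was dropped for missing values")

    if spec.outcome == "binary":
        if spec.binary_threshold not in (15.0, 30.0, 15, 30):
            raise ValueError("binary_threshold must be 15 or 30")
        y = (d["ahi"].to_numpy(dtype=float) >= float(spec.binary_threshold)).astype(float)
    else:
        y = d[spec.outcome].to_numpy(dtype=float)

    blocks, names, terms = [], [], []

    sb, basis = natural_spline_basis(
        d["day_of_year"].to_numpy(dtype=float),
        spec.seasonal_df,
        boundary=spec.seasonal_boundary,
        variable="day_of_year",
    )
    terms.append(TermInfo("day_of_year", "spline",
                          list(range(spec.seasonal_df)), basis))
    blocks.append(sb)
    names += [f"doy_ns{i+1}" for i in range(spec.seasonal_df)]

    if spec.dow:
        dow = d["day_of_week"].to_numpy(dtype=int)
        ind = np.column_stack([(dow == k).astype(float) for k in range(2, 8)])
        start = len(names)
        terms.append(TermInfo("day_of_week", "dow", list(range(start, start + 6))))
        blocks.append(ind)
        names += [f"dow_{k}" for k in range(2, 8)]

    for var, df_c in spec.confounders:
        x = d[var].to_numpy(dtype=float)
        cb, cbasis = natural_spline_basis(x, df_c, variable=var)
        start = len(names)
        terms.append(TermInfo(var, "spline", list(range(start, start + df_c)), cbasis))
        blocks.append(cb)
        names += [f"{var}_ns{i+1}" for i in range(df_c)]

    X = np.column_stack(blocks)
    strata_labels = (
        d["participant_id"].astype(str) + "/" + d["year"].astype(str)
    )
    strata_codes, _ = pd.factorize(strata_labels, sort=True)
    info = {
        "n_dropped_rows": n_dropped,
        "participant": d["participant_id"].to_numpy(),
        "row_index": d.index.to_numpy(),
    }
    return y, X, strata_codes, terms, names, info


def absorb_strata(y: np.ndarray, X: np.ndarray, strata: np.ndarray):
    """Subtract within-stratum means from the outcome and every design column.

    Returns ``(y_dm, X_dm, sizes, zero_cols)``.  Rows in single-observation
    strata become exactly zero (they carry no within information) and columns
    constant within every stratum come out as (numerical) zero columns,
    flagged in ``zero_cols`` for dropping — they are collinear with the
    absorbed intercepts.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(strata), sort=True)  # dense renumbering
    n_strata = int(codes.max()) + 1 if len(codes) else 0
    sizes = np.bincount(codes, minlength=n_strata)

    def demean(v):
        sums = np.zeros((n_strata,) + v.shape[1:])
        np.add.at(sums, codes, v)
        means = sums / sizes.reshape((-1,) + (1,) * (v.ndim - 1))
        return v - means[codes]

    y_dm = demean(y)
    X_dm = demean(X)
    col_scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    zero_cols = np.abs(X_dm).max(axis=0) <= _ZERO_TOL * col_scale
    if zero_cols.any():
        X_dm = X_dm.copy()
        X_dm[:, zero_cols] = 0.0
    return y_dm, X_dm, sizes, zero_cols


class StrataAbsorbedOLS:
    """Least squares after strata absorption, sklearn-estimator style.

    ``fit(X, y, strata)`` demeans within strata, drops strata-collinear and
    rank-deficient columns, and solves the within regression.  The residual
    degrees of freedom subtract the number of absorbed strata, so the
    model-based covariance matches an explicit dummy-intercept OLS exactly.

    Parameters
    ----------
    cluster_robust : bool
        If True and ``cluster`` labels are passed to ``fit``, report a
        cluster-robust (CR1) sandwich covariance instead of the model-based one.
    """

    def __init__(self, cluster_robust: bool = False):
        self.cluster_robust = cluster_robust

    def get_params(self, deep: bool = True) -> dict:
        return {"cluster_robust": self.cluster_robust}

    def set_params(self, **params) -> "StrataAbsorbedOLS":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, strata, cluster=None) -> "StrataAbsorbedOLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        y_dm, X_dm, sizes, zero_cols = absorb_strata(y, X, strata)
        keep = ~zero_cols

        kept_idx = np.flatnonzero(keep)
        Xk = X_dm[:, kept_idx]
        # rank check via pivoted QR; drop minimal trailing pivots if deficient
        if Xk.shape[1]:
            _, R, piv = scipy.linalg.qr(Xk, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = diag.max() * max(Xk.shape) * np.finfo(float).eps if diag.size else 0.0
            rank = int((diag > tol).sum())
            if rank < Xk.shape[1]:
                dropped_rd = kept_idx[piv[rank:]]
                warnings.warn(
                    f"design is rank deficient after absorption; dropping "
                    f"{Xk.shape[1] - rank} column(s)", stacklevel=2,
                )
                keep = keep.copy()
                keep[dropped_rd] = False
                kept_idx = np.flatnonzero(keep)
                Xk = X_dm[:, kept_idx]
        rank = Xk.shape[1]

        if rank == 0:
            raise ValueError("no identifiable design columns after strata absorption")
        XtX = Xk.T @ Xk
        beta_k = scipy.linalg.solve(XtX, Xk.T @ y_dm, assume_a="pos")
        resid = y_dm - Xk @ beta_k
        n_strata = len(sizes)
        df_resid = n - rank - n_strata
        if df_resid <= 0:
            raise ValueError("no residual degrees of freedom after absorbing strata")
        s2 = float(resid @ resid) / df_resid
        XtX_inv = scipy.linalg.inv(XtX)

        if self.cluster_robust:
            if cluster is None:
                raise ValueError("cluster labels required for cluster-robust covariance")
            ccodes, _ = pd.factorize(np.asarray(cluster), sort=True)
            G = int(ccodes.max()) + 1
            Xe = Xk * resid[:, None]
            S = np.zeros((G, rank))
            np.add.at(S, ccodes, Xe)
            meat = S.T @ S
            cov_k = XtX_inv @ meat @ XtX_inv * (G / (G - 1))
        else:
            cov_k = s2 * XtX_inv

        self.coef_ = np.zeros(p)
        self.coef_[kept_idx] = beta_k
        self.cov_ = np.zeros((p, p))
        self.cov_[np.ix_(kept_idx, kept_idx)] = cov_k
        self.kept_mask_ = keep
        self.rank_ = rank
        self.n_obs_ = n
        self.n_strata_ = n_strata
        self.strata_sizes_ = sizes
        self.df_resid_ = df_resid
        self.resid_var_ = s2
        return self

    @property
    def bse_(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_))

    def predict(self, X) -> np.ndarray:
        """Within-stratum linear predictor (strata intercepts excluded)."""
        return np.asarray(X, dtype=float) @ self.coef_


class ConditionalLogisticRegression:
    """Conditional (strata-matched) logistic regression.

    Eliminates the per-stratum intercepts by conditioning on the number of
    events in each stratum; strata where the outcome does not vary are
    uninformative and dropped before fitting.  Columns constant within every
    informative stratum are unidentified and dropped the same way as in the
    Gaussian path.

    The conditional likelihood's combinatorial denominator makes exact fits
    impractical for long strata (hundreds of nights with many events), so
    ``max_per_stratum`` optionally thins each stratum to a random subset of
    nights before fitting — the within-stratum design stays valid because the
    conditioning argument applies to any subset of a stratum.  Thinning is
    deterministic given ``random_state``.
    """

    def __init__(self, max_per_stratum: int | None = None, random_state: int = 0):
        self.max_per_stratum = max_per_stratum
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"max_per_stratum": self.max_per_stratum,
                "random_state": self.random_state}

    def set_params(self, **params) -> "ConditionalLogisticRegression":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y, strata) -> "ConditionalLogisticRegression":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        codes, _ = pd.factorize(np.asarray(strata), sort=True)
        if self.max_per_stratum is not None:
            rng = np.random.default_rng(self.random_state)
            order = rng.permutation(n)
            pos_in_stratum = pd.Series(np.arange(n)).groupby(
                codes[order]).cumcount().to_numpy()
            keep_rows = np.zeros(n, dtype=bool)
            keep_rows[order[pos_in_stratum < self.max_per_stratum]] = True
            X, y, codes = X[keep_rows], y[keep_rows], codes[keep_rows]
            n = len(y)
        df = pd.DataFrame({"y": y, "g": codes})
        gmean = df.groupby("g")["y"].transform("mean")
        informative = (gmean > 0) & (gmean < 1)
        self.n_strata_total_ = int(codes.max()) + 1
        if not informative.any():
            raise ValueError("no informative strata: outcome constant within "
                             "every participant-year")
        yi = y[informative.to_numpy()]
        Xi = X[informative.to_numpy()]
        gi, _ = pd.factorize(codes[informative.to_numpy()], sort=True)
        _, Xi_dm, sizes, zero_cols = absorb_strata(yi, Xi, gi)
        keep = np.flatnonzero(~zero_cols)
        if keep.size == 0:
            raise ValueError("no identifiable design columns within informative strata")
        model = ConditionalLogit(yi, Xi[:, keep], groups=gi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", tol=1e-10, disp=0, maxiter=200)
            except np.linalg.LinAlgError:
                res = model.fit(method="bfgs", gtol=1e-8, disp=0, maxiter=500)
        self.coef_ = np.zeros(p)
        self.coef_[keep] = res.params
        self.cov_ = np.zeros((p, p))
        self.cov_[np.ix_(keep, keep)] = np.asarray(res.cov_params())
        self.kept_mask_ = np.zeros(p, dtype=bool)
        self.kept_mask_[keep] = True
        self.n_obs_ = int(informative.sum())
        self.n_strata_ = len(sizes)
        self.result_ = res
        return self


def fit_gaussian(y, X, strata, *, terms=None, column_names=None,
                 cluster=None, cluster_robust=False, n_dropped_rows=0) -> ModelFit:
    """Strata-absorbed Gaussian (identity link) fit -> :class:`ModelFit`."""
    est = StrataAbsorbedOLS(cluster_robust=cluster_robust)
    est.fit(X, y, strata, cluster=cluster)
    p = X.shape[1]
    names = column_names or [f"x{i}" for i in range(p)]
    dropped = [names[i] for i in np.flatnonzero(~est.kept_mask_)]
    if dropped:
        logger.info("fit_gaussian: dropped columns %s", dropped)
    return ModelFit(
        params=est.coef_, cov=est.cov_, column_names=names,
        terms=terms or [], family="gaussian",
        n_obs=est.n_obs_, n_strata=est.n_strata_, df_resid=est.df_resid_,
        resid_var=est.resid_var_, dropped=dropped, n_dropped_rows=n_dropped_rows,
    )


def fit_binary(y, X, strata, *, terms=None, column_names=None,
               n_dropped_rows=0, max_per_stratum=None, random_state=0) -> ModelFit:
    """Conditional-logistic fit of a binary outcome -> :class:`ModelFit`."""
    est = ConditionalLogisticRegression(max_per_stratum=max_per_stratum,
                                        random_state=random_state)
    est.fit(X, y, strata)
    p = X.shape[1]
    names = column_names or [f"x{i}" for i in range(p)]
    dropped = [names[i] for i in np.flatnonzero(~est.kept_mask_)]
    return ModelFit(
        params=est.coef_, cov=est.cov_, column_names=names,
        terms=terms or [], family="binomial",
        n_obs=est.n_obs_, n_strata=est.n_strata_,
        df_resid=est.n_obs_ - int(est.kept_mask_.sum()) - est.n_strata_,
        resid_var=None, dropped=dropped, n_dropped_rows=n_dropped_rows,
    )


class FixedEffectsSplineModel:
    """High-level estimator: derived-nights table in, :class:`ModelFit` out.

    Builds the seasonal-spline + day-of-week (+ confounder-spline) design from
    a derived nightly table and fits it with subject/year strata absorbed
    (Gaussian) or conditioned out (binary).  sklearn-style: configuration in
    ``__init__``, data in ``fit``, results in trailing-underscore attributes.
    """

    def __init__(self, outcome: str = "c_ahi", binary_threshold: float | None = None,
                 seasonal_df: int = 8,
                 seasonal_boundary: tuple[float, float] = SEASONAL_BOUNDARY,
                 dow: bool = True, confounders: list[tuple[str, int]] | None = None,
                 cluster_robust: bool = False, max_per_stratum: int | None = None,
                 random_state: int = 0):
        self.outcome = outcome
        self.binary_threshold = binary_threshold
        self.seasonal_df = seasonal_df
        self.seasonal_boundary = seasonal_boundary
        self.dow = dow
        self.confounders = confounders
        self.cluster_robust = cluster_robust
        self.max_per_stratum = max_per_stratum
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "outcome": self.outcome, "binary_threshold": self.binary_threshold,
            "seasonal_df": self.seasonal_df, "seasonal_boundary": self.seasonal_boundary,
            "dow": self.dow, "confounders": self.confounders,
            "cluster_robust": self.cluster_robust,
            "max_per_stratum": self.max_per_stratum,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "FixedEffectsSplineModel":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def spec(self) -> FixedEffectsSpec:
        return FixedEffectsSpec(
            outcome=self.outcome, binary_threshold=self.binary_threshold,
            seasonal_df=self.seasonal_df, seasonal_boundary=self.seasonal_boundary,
            dow=self.dow, confounders=list(self.confounders or []),
        )

    def fit(self, nights: pd.DataFrame, y=None) -> "FixedEffectsSplineModel":
        spec = self.spec()
        yv, X, strata, terms, names, info = build_design(nights, spec)
        if spec.outcome == "binary":
            self.result_ = fit_binary(
                yv, X, strata, terms=terms, column_names=names,
                n_dropped_rows=info["n_dropped_rows"],
                max_per_stratum=self.max_per_stratum,
                random_state=self.random_state,
            )
        else:
            self.result_ = fit_gaussian(
                yv, X, strata, terms=terms, column_names=names,
                cluster=info["participant"], cluster_robust=self.cluster_robust,
                n_dropped_rows=info["n_dropped_rows"],
            )
        self.n_obs_ = self.result_.n_obs
        self.n_strata_ = self.result_.n_strata
        self.coef_ = self.result_.params
        return self
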