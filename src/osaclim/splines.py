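"""Natural cubic spline bases for exposure-response and seasonal terms.

A natural cubic spline is a piecewise cubic that is constrained to be linear
beyond its boundary knots.  With ``df`` basis columns (no intercept) the basis
spans all natural cubics on ``df + 1`` knots: two boundary knots plus
``df - 1`` interior knots placed at equally spaced quantiles of the training
values.  Evaluation outside the boundary knots continues on the tangent line
(the natural linear extension), which is what makes the basis safe for
prediction grids that slightly exceed the observed range.

The construction is the classic truncated-power one: with knots
``k_1 < ... < k_K`` define

    d_j(x) = [ (x - k_j)_+^3 - (x - k_K)_+^3 ] / (k_K - k_j)

and take ``N_1(x) = x`` and ``N_{j+1}(x) = d_j(x) - d_{K-1}(x)`` for
``j = 1 .. K-2``.  Cubic and quadratic terms cancel beyond ``k_K``, so every
basis function is exactly linear outside the boundary — no special-casing of
extrapolation is needed.  Inputs are affinely rescaled to the unit interval
before cubing to keep the columns well conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["NaturalSplineBasis", "natural_spline_basis", "NaturalSplineFeatures"]


@dataclass(frozen=True)
class NaturalSplineBasis:
    """Frozen definition of a fitted natural cubic spline basis.

    Carries everything needed to re-evaluate the basis on new values
    (serialisable to plain JSON), so downstream marginal-mean code can work
    from a stored model fit without refitting.
    """

    variable: str
    df: int
    interior_knots: tuple[float, ...]
    boundary_knots: tuple[float, float]

    @property
    def knots(self) -> np.ndarray:
        """All knots, boundary included, ascending."""
        return np.asarray(
            [self.boundary_knots[0], *self.interior_knots, self.boundary_knots[1]],
            dtype=float,
        )

    def design(self, x) -> np.ndarray:
        """Evaluate the basis at ``x`` -> array of shape ``(len(x), df)``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.boundary_knots
        scale = hi - lo
        t = (x - lo) / scale
        knots = (self.knots - lo) / scale
        K = len(knots)

        def trunc3(v, k):
            d = v - k
            return np.where(d > 0, d**3, 0.0)

        def d_j(j):
            return (trunc3(t, knots[j]) - trunc3(t, knots[K - 1])) / (
                knots[K - 1] - knots[j]
            )

        cols = [t]
        d_last = d_j(K - 2)
        for j in range(K - 2):
            cols.append(d_j(j) - d_last)
        return np.column_stack(cols)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "df": self.df,
            "interior_knots": list(self.interior_knots),
            "boundary_knots": list(self.boundary_knots),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaturalSplineBasis":
        return cls(
            variable=d["variable"],
            df=int(d["df"]),
            interior_knots=tuple(d["interior_knots"]),
            boundary_knots=(d["boundary_knots"][0], d["boundary_knots"][1]),
        )


def natural_spline_basis(
    x,
    df: int,
    boundary: tuple[float, float] | None = None,
    variable: str = "x",
) -> tuple[np.ndarray, NaturalSplineBasis]:
    """Build a natural cubic spline basis from data.

    Parameters
    ----------
    x : array-like
        Observed values of the variable.  Interior knots are placed at the
        quantiles ``i/df`` for ``i = 1 .. df-1``.
    df : int
        Number of basis columns (>= 1).  ``df = 1`` is the plain linear term.
    boundary : (low, high), optional
        Boundary knots.  Defaults to ``(min(x), max(x))``.  The seasonal term
        pins these at days 1 and 365 so fits from different subsets share a
        common domain.
    variable : str
        Name recorded in the returned :class:`NaturalSplineBasis`.

    Returns
    -------
    (design, basis) : the ``(n, df)`` design matrix and the frozen basis.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("df must be >= 1")
    n_distinct = len(np.unique(x[np.isfinite(x)]))
    if n_distinct <= df:
        raise ValueError(
            f"natural spline for {variable!r} needs more than {df} distinct "
            f"values, got {n_distinct}"
        )
    if boundary is None:
        boundary = (float(np.nanmin(x)), float(np.nanmax(x)))
    lo, hi = float(boundary[0]), float(boundary[1])
    if not hi > lo:
        raise ValueError("upper boundary knot must exceed lower boundary knot")
    if df == 1:
        interior: tuple[float, ...] = ()
    else:
        probs = np.arange(1, df) / df
        interior_arr = np.quantile(x[np.isfinite(x)], probs)
        # knots must be strictly inside the boundary and strictly increasing
        interior_arr = np.clip(interior_arr, lo, hi)
        interior_arr = np.unique(interior_arr)
        interior_arr = interior_arr[(interior_arr > lo) & (interior_arr < hi)]
        if len(interior_arr) != df - 1:
            raise ValueError(
                f"could not place {df - 1} distinct interior knots for "
                f"{variable!r}; values too discrete for df={df}"
            )
        interior = tuple(float(k) for k in interior_arr)
    basis = NaturalSplineBasis(
        variable=variable, df=df, interior_knots=interior, boundary_knots=(lo, hi)
    )
    return basis.design(x), basis


class NaturalSplineFeatures:
    """sklearn-style transformer wrapping :func:`natural_spline_basis`.

    ``fit`` learns knots from the training column; ``transform`` evaluates the
    frozen basis, extending linearly beyond the boundary knots.
    """

    def __init__(self, df: int = 4, boundary: tuple[float, float] | None = None,
                 variable: str = "x"):
        self.df = df
        self.boundary = boundary
        self.variable = variable

    def get_params(self, deep: bool = True) -> dict:
        return {"df": self.df, "boundary": self.boundary, "variable": self.variable}

    def set_params(self, **params) -> "NaturalSplineFeatures":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "NaturalSplineFeatures":
        x = np.asarray(X, dtype=float).reshape(-1)
        _, self.basis_ = natural_spline_basis(
            x, self.df, boundary=self.boundary, variable=self.variable
        )
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "basis_"):
            raise AttributeError("NaturalSplineFeatures is not fitted")
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.basis_.design(x)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
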