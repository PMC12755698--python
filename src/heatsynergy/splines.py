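"""Natural cubic spline bases and the exposure design matrix.

The fitted model's linear predictor is built from a natural cubic spline for
windowed temperature, a natural cubic spline for windowed PM2.5 and an
interaction: either the raw product term ``tmax_w * pm25_w`` (the primary
model) or a tensor-product spline surface (sensitivity model). No intercept
column is emitted — the matched-set conditional likelihood absorbs it.

The natural basis is the standard truncated-power construction: with knots
``k_1 < … < k_K`` (interior plus the two boundary knots) the ``K - 1``
columns are ``N_1(x) = x`` and ``N_{j+1}(x) = d_j(x) - d_{K-1}(x)`` where
``d_j(x) = [(x - k_j)_+^3 - (x - k_K)_+^3] / (k_K - k_j)``. Every column is
exactly linear beyond the boundary knots (second derivative zero at and past
them), so the span contains all linear functions and extrapolation is linear
by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SplineSpec",
    "ModelSpec",
    "ExtrapolationWarning",
    "DegenerateDesignError",
    "natural_cubic_basis",
    "NaturalSplineFeatures",
    "ExposureDesign",
    "LinearExposureDesign",
    "build_design",
]


class ExtrapolationWarning(UserWarning):
    """Evaluation outside the boundary knots; the basis extends linearly."""


class DegenerateDesignError(ValueError):
    """The design matrix cannot be built (e.g. a constant exposure column)."""


@dataclass(frozen=True)
class SplineSpec:
    """Degrees of freedom and (optional) explicit knots for one exposure.

    ``df`` is the number of basis columns. When knots are not supplied,
    ``df - 1`` interior knots are placed at equally spaced quantiles of the
    case-day exposure values and the boundary knots at the min/max of the
    analysis values.
    """

    df: int = 4
    interior_knots: tuple[float, ...] | None = None
    boundary_knots: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.df < 2:
            raise ValueError("a natural cubic spline needs df >= 2")


@dataclass(frozen=True)
class ModelSpec:
    """Exposure-response model: marginal splines plus an interaction term."""

    temp_spline: SplineSpec = field(default_factory=SplineSpec)
    pm_spline: SplineSpec = field(default_factory=SplineSpec)
    interaction: str = "linear_product"
    tensor_df: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        if self.interaction not in ("linear_product", "tensor_product"):
            raise ValueError("interaction must be 'linear_product' or 'tensor_product'")


def _natural_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k_last = knots[-1]
    k_penult = knots[-2]

    def d(kj):
        return (
            np.clip(x - kj, 0.0, None) ** 3 - np.clip(x - k_last, 0.0, None) ** 3
        ) / (k_last - kj)

    cols = [x] + [d(kj) - d(k_penult) for kj in knots[:-2]]
    return np.column_stack(cols)


def natural_cubic_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate a natural cubic spline basis (``spec.df`` columns) at ``x``.

    Requires explicit knots on the :class:`SplineSpec` (use :class:`NaturalSplineFeatures`
    for data-driven placement). Warns when any ``x`` lies outside the
    boundary knots; the basis continues linearly there.
    """
    if spec.interior_knots is None or spec.boundary_knots is None:
        raise ValueError("natural_cubic_basis needs explicit interior and boundary knots")
    lo, hi = spec.boundary_knots
    if not lo < hi:
        raise ValueError("boundary knots must satisfy lo < hi")
    interior = np.asarray(spec.interior_knots, dtype=float)
    if interior.size != spec.df - 1:
        raise ValueError(f"df={spec.df} requires {spec.df - 1} interior knots")
    if np.any(interior <= lo) or np.any(interior >= hi):
        raise ValueError("interior knots must lie strictly inside the boundary knots")
    x = np.asarray(x, dtype=float)
    if np.any(x < lo) or np.any(x > hi):
        warnings.warn(
            "evaluating spline basis outside its boundary knots; extending linearly",
            ExtrapolationWarning,
            stacklevel=2,
        )
    knots = np.concatenate([[lo], np.sort(interior), [hi]])
    return _natural_basis(np.atleast_1d(x), knots)


class NaturalSplineFeatures(TransformerMixin, BaseEstimator):
    """Natural cubic spline transformer with quantile knot placement.

    ``fit(X)`` records the knots: ``df - 1`` interior knots at equally spaced
    quantiles of ``knot_values`` (case-day exposures, when given; otherwise
    the training values) and boundary knots at the min/max of the training
    values. ``transform`` then evaluates the frozen basis anywhere, extending
    linearly (with a warning) outside the boundary knots.
    """

    def __init__(self, df: int = 4, interior_knots=None, boundary_knots=None):
        self.df = df
        self.interior_knots = interior_knots
        self.boundary_knots = boundary_knots

    def fit(self, X, y=None, knot_values=None):
        x = np.asarray(X, dtype=float).ravel()
        if x.size == 0:
            raise ValueError("cannot fit spline knots on empty data")
        if np.ptp(x) == 0:
            raise DegenerateDesignError("exposure is constant; spline basis is degenerate")
        if self.boundary_knots is not None:
            lo, hi = map(float, self.boundary_knots)
        else:
            lo, hi = float(x.min()), float(x.max())
        if self.interior_knots is not None:
            interior = np.asarray(self.interior_knots, dtype=float)
        else:
            ref = x if knot_values is None else np.asarray(knot_values, dtype=float)
            m = self.df - 1
            probs = np.arange(1, m + 1) / (m + 1)
            interior = np.quantile(ref, probs)
            interior = np.clip(interior, np.nextafter(lo, hi), np.nextafter(hi, lo))
        if np.unique(interior).size != interior.size:
            raise DegenerateDesignError("duplicate interior knots; reduce df")
        self.spec_ = SplineSpec(
            df=self.df,
            interior_knots=tuple(np.sort(interior)),
            boundary_knots=(lo, hi),
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "spec_"):
            raise ValueError("NaturalSplineFeatures is not fitted")
        return natural_cubic_basis(np.asarray(X, dtype=float).ravel(), self.spec_)

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        name = (input_features or ["x"])[0]
        return np.array([f"ns({name})[{j}]" for j in range(self.df)])


class ExposureDesign(TransformerMixin, BaseEstimator):
    """Two-exposure design matrix builder (splines + interaction).

    Fit on the long-format analysis table (columns ``tmax_w``, ``pm25_w``
    and, when present, ``is_case`` — case-day values drive interior-knot
    placement). ``transform`` accepts either the same kind of table or a
    ``(t, p)`` pair of arrays, and returns the design matrix with columns

    * ``linear_product``: ``[NCS(T) | NCS(P) | T*P]`` — ``df_T + df_P + 1``,
    * ``tensor_product``: ``[NCS(T) | NCS(P) | tensor(T, P)]`` where the
      interaction block is the row-wise outer product of marginal natural
      bases of the configured tensor degrees of freedom.
    """

    def __init__(self, model: ModelSpec | None = None):
        self.model = model

    @property
    def model_(self) -> ModelSpec:
        return self.model or ModelSpec()

    def fit(self, table: pd.DataFrame, y=None):
        t, p = _extract_tp(table)
        case_mask = (
            table["is_case"].to_numpy().astype(bool)
            if isinstance(table, pd.DataFrame) and "is_case" in table
            else np.ones(t.shape, dtype=bool)
        )
        model = self.model_
        self.temp_basis_ = NaturalSplineFeatures(
            df=model.temp_spline.df,
            interior_knots=model.temp_spline.interior_knots,
            boundary_knots=model.temp_spline.boundary_knots,
        ).fit(t, knot_values=t[case_mask])
        self.pm_basis_ = NaturalSplineFeatures(
            df=model.pm_spline.df,
            interior_knots=model.pm_spline.interior_knots,
            boundary_knots=model.pm_spline.boundary_knots,
        ).fit(p, knot_values=p[case_mask])
        labels = [f"ns(tmax)[{j}]" for j in range(model.temp_spline.df)]
        labels += [f"ns(pm25)[{j}]" for j in range(model.pm_spline.df)]
        if model.interaction == "linear_product":
            labels.append("tmax:pm25")
        else:
            dt, dp = model.tensor_df
            self.tensor_temp_basis_ = NaturalSplineFeatures(df=dt).fit(
                t, knot_values=t[case_mask]
            )
            self.tensor_pm_basis_ = NaturalSplineFeatures(df=dp).fit(
                p, knot_values=p[case_mask]
            )
            labels += [f"te(tmax,pm25)[{i},{j}]" for i in range(dt) for j in range(dp)]
        self.column_labels_ = labels
        return self

    def transform(self, table) -> np.ndarray:
        if not hasattr(self, "temp_basis_"):
            raise ValueError("ExposureDesign is not fitted")
        t, p = _extract_tp(table)
        blocks = [self.temp_basis_.transform(t), self.pm_basis_.transform(p)]
        if self.model_.interaction == "linear_product":
            blocks.append((t * p)[:, None])
        else:
            bt = self.tensor_temp_basis_.transform(t)
            bp = self.tensor_pm_basis_.transform(p)
            blocks.append(bt[:, :, None] * bp[:, None, :])
            blocks[-1] = blocks[-1].reshape(len(t), -1)
        X = np.hstack(blocks)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in the design matrix")
        return X

    @property
    def knots_(self) -> dict:
        """Knot locations of every fitted basis, for the run manifest."""
        out = {
            "tmax": {
                "interior": list(self.temp_basis_.spec_.interior_knots),
                "boundary": list(self.temp_basis_.spec_.boundary_knots),
            },
            "pm25": {
                "interior": list(self.pm_basis_.spec_.interior_knots),
                "boundary": list(self.pm_basis_.spec_.boundary_knots),
            },
        }
        if hasattr(self, "tensor_temp_basis_"):
            out["tensor_tmax"] = {
                "interior": list(self.tensor_temp_basis_.spec_.interior_knots),
                "boundary": list(self.tensor_temp_basis_.spec_.boundary_knots),
            }
            out["tensor_pm25"] = {
                "interior": list(self.tensor_pm_basis_.spec_.interior_knots),
                "boundary": list(self.tensor_pm_basis_.spec_.boundary_knots),
            }
        return out


class LinearExposureDesign(TransformerMixin, BaseEstimator):
    """Purely linear design ``[T | P | T*P]``.

    The correctly specified design when the data come from the linear hazard
    DGP; used for exact parameter-recovery and calibration analyses. Shares
    the :class:`ExposureDesign` interface so effect summaries work unchanged.
    """

    column_labels_ = ["tmax", "pm25", "tmax:pm25"]

    @property
    def model_(self) -> ModelSpec:
        return ModelSpec(interaction="linear_product")

    def fit(self, table=None, y=None):
        return self

    def transform(self, table) -> np.ndarray:
        t, p = _extract_tp(table)
        return np.column_stack([t, p, t * p])


def _extract_tp(table) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(table, pd.DataFrame):
        t = table["tmax_w"].to_numpy(dtype=float)
        p = table["pm25_w"].to_numpy(dtype=float)
    else:
        t, p = table
        t = np.asarray(t, dtype=float).ravel()
        p = np.asarray(p, dtype=float).ravel()
        if t.shape != p.shape:
            raise ValueError("temperature and PM2.5 arrays must have equal length")
    return t, p


def build_design(
    analysis_table: pd.DataFrame, model: ModelSpec | None = None
) -> tuple[np.ndarray, list[str], ExposureDesign]:
    """Fit an :class:`ExposureDesign` on the analysis table and evaluate it.

    Returns ``(design matrix, column labels, fitted design)``; the fitted
    design re-evaluates the identical basis at arbitrary ``(t, p)`` for
    effect estimation.
    """
    design = ExposureDesign(model=model).fit(analysis_table)
    return design.transform(analysis_table), design.column_labels_, design
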