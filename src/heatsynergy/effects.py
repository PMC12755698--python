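"""Posterior effect summaries: OR curves, contrasts, RERI and the OR grid.

All quantities are functions of the posterior draws and the fitted exposure
design. For a contrast moving temperature from ``t0`` to ``t1`` and PM2.5
from ``p0`` to ``p1`` (defaults: case-day medians to case-day 95th
percentiles), each posterior draw yields three odds ratios against the joint
reference ``(t0, p0)``:

    OR10 = OR(t1, p0), OR01 = OR(t0, p1), OR11 = OR(t1, p1)

and the additive-scale relative excess risk due to interaction

    RERI = OR11 - OR10 - OR01 + 1,

positive under synergism. Because the outcome is rare, the OR-based RERI
approximates the risk-ratio form. Summaries are posterior means with 95%
equal-tailed credible intervals; the RERI is reported both per-draw
(mean/CI of per-draw RERIs) and as the plug-in of the posterior-mean ORs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .splines import ExposureDesign

__all__ = [
    "ContrastSpec",
    "EffectSummary",
    "RERIResult",
    "log_odds_surface",
    "odds_ratio",
    "or_draws",
    "reri",
    "reri_plugin",
    "multiplicative_interaction",
    "or_grid",
    "or_curve",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Reference (t0, p0) and comparison (t1, p1) exposure levels."""

    t0: float
    t1: float
    p0: float
    p1: float

    @classmethod
    def from_case_days(
        cls, analysis_table: pd.DataFrame, q_ref: float = 0.5, q_cmp: float = 0.95
    ) -> "ContrastSpec":
        """Contrast levels from case-day exposure distributions.

        Default: medians as reference, 95th percentiles as comparison —
        computed on case days only.
        """
        cases = analysis_table[analysis_table["is_case"] == 1]
        if cases.empty:
            raise ValueError("no case days in the analysis table")
        t = cases["tmax_w"].to_numpy(dtype=float)
        p = cases["pm25_w"].to_numpy(dtype=float)
        return cls(
            t0=float(np.quantile(t, q_ref)),
            t1=float(np.quantile(t, q_cmp)),
            p0=float(np.quantile(p, q_ref)),
            p1=float(np.quantile(p, q_cmp)),
        )


@dataclass(frozen=True)
class EffectSummary:
    """Posterior mean and 95% equal-tailed credible interval."""

    mean: float
    ci_low: float
    ci_high: float
    n_draws: int

    @classmethod
    def from_draws(cls, values: np.ndarray) -> "EffectSummary":
        values = np.asarray(values, dtype=float)
        lo, hi = np.percentile(values, [2.5, 97.5])
        return cls(
            mean=float(values.mean()),
            ci_low=float(lo),
            ci_high=float(hi),
            n_draws=int(values.size),
        )

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_draws": self.n_draws,
        }


@dataclass(frozen=True)
class RERIResult:
    """Additive interaction: per-draw summary plus the plug-in variant."""

    per_draw: EffectSummary
    plugin: float
    or10: EffectSummary
    or01: EffectSummary
    or11: EffectSummary


def _draws_matrix(draws) -> np.ndarray:
    d = np.asarray(getattr(draws, "draws_", draws), dtype=float)
    return np.atleast_2d(d)


def log_odds_surface(draws, design: ExposureDesign, t, p) -> np.ndarray:
    """Linear predictor (relative to the implicit stratum baseline).

    Evaluates the fitted design at exposure points ``(t, p)`` and contracts
    with the draws: returns shape ``(n_points, n_draws)`` (squeezed to
    ``(n_points,)`` for a single coefficient vector).
    """
    d = _draws_matrix(draws)
    t = np.atleast_1d(np.asarray(t, dtype=float))
    p = np.atleast_1d(np.asarray(p, dtype=float))
    rows = design.transform((t, p))
    if rows.shape[1] != d.shape[1]:
        raise ValueError(
            f"design has {rows.shape[1]} columns but draws have {d.shape[1]}"
        )
    eta = rows @ d.T
    return eta[:, 0] if np.asarray(getattr(draws, "draws_", draws)).ndim == 1 else eta


def or_draws(draws, design: ExposureDesign, point, reference) -> np.ndarray:
    """Per-draw odds ratios of exposure ``point`` versus ``reference``."""
    d = _draws_matrix(draws)
    ta, pa = point
    t0, p0 = reference
    rows = design.transform((np.array([ta, t0]), np.array([pa, p0])))
    eta = rows @ d.T
    return np.exp(eta[0] - eta[1])


def odds_ratio(draws, design: ExposureDesign, point, reference) -> EffectSummary:
    """Posterior OR summary for one exposure contrast."""
    return EffectSummary.from_draws(or_draws(draws, design, point, reference))


def reri_plugin(or11: float, or10: float, or01: float) -> float:
    """RERI from three already-summarized odds ratios: OR11 - OR10 - OR01 + 1."""
    return or11 - or10 - or01 + 1.0


def reri(draws, design: ExposureDesign, contrast: ContrastSpec) -> RERIResult:
    """Relative excess risk due to interaction at the given contrast."""
    r10 = or_draws(draws, design, (contrast.t1, contrast.p0), (contrast.t0, contrast.p0))
    r01 = or_draws(draws, design, (contrast.t0, contrast.p1), (contrast.t0, contrast.p0))
    r11 = or_draws(draws, design, (contrast.t1, contrast.p1), (contrast.t0, contrast.p0))
    per_draw = EffectSummary.from_draws(r11 - r10 - r01 + 1.0)
    plugin = reri_plugin(
        float(r11.mean()), float(r10.mean()), float(r01.mean())
    )
    return RERIResult(
        per_draw=per_draw,
        plugin=plugin,
        or10=EffectSummary.from_draws(r10),
        or01=EffectSummary.from_draws(r01),
        or11=EffectSummary.from_draws(r11),
    )


def multiplicative_interaction(draws, design: ExposureDesign) -> EffectSummary:
    """OR per 1 °C·µg/m³ from the linear product term.

    Only defined for the ``linear_product`` model; the tensor sensitivity
    model has no single interaction coefficient.
    """
    if design.model_.interaction != "linear_product":
        raise ValueError(
            "multiplicative interaction is only defined for the linear_product model"
        )
    idx = design.column_labels_.index("tmax:pm25")
    d = _draws_matrix(draws)
    return EffectSummary.from_draws(np.exp(d[:, idx]))


def or_grid(
    draws,
    design: ExposureDesign,
    t_grid,
    p_grid,
    reference: tuple[float, float],
) -> pd.DataFrame:
    """Posterior-mean OR over a (temperature x PM2.5) grid vs the reference.

    Rows indexed by temperature, columns by PM2.5; the cell at the reference
    exposure equals 1 exactly.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)
    d = _draws_matrix(draws)
    tt, pp = np.meshgrid(t_grid, p_grid, indexing="ij")
    rows = design.transform((tt.ravel(), pp.ravel()))
    ref_row = design.transform((np.array([reference[0]]), np.array([reference[1]])))
    eta = (rows - ref_row) @ d.T
    means = np.exp(eta).mean(axis=1).reshape(len(t_grid), len(p_grid))
    return pd.DataFrame(means, index=pd.Index(t_grid, name="tmax"), columns=pd.Index(p_grid, name="pm25"))


def or_curve(
    draws,
    design: ExposureDesign,
    grid,
    axis: str,
    fixed: float,
    reference: tuple[float, float],
) -> pd.DataFrame:
    """Exposure-response OR curve along one exposure, the other held fixed.

    ``axis`` is ``"tmax"`` or ``"pm25"``; ``fixed`` is the level of the other
    exposure; every point on the curve is referenced to ``reference``.
    Returns a frame with the grid, posterior-mean OR and 95% CI bounds.
    """
    grid = np.asarray(grid, dtype=float)
    if axis == "tmax":
        t, p = grid, np.full_like(grid, fixed)
    elif axis == "pm25":
        t, p = np.full_like(grid, fixed), grid
    else:
        raise ValueError("axis must be 'tmax' or 'pm25'")
    d = _draws_matrix(draws)
    rows = design.transform((t, p))
    ref_row = design.transform((np.array([reference[0]]), np.array([reference[1]])))
    ors = np.exp((rows - ref_row) @ d.T)
    lo, hi = np.percentile(ors, [2.5, 97.5], axis=1)
    return pd.DataFrame(
        {axis: grid, "or_mean": ors.mean(axis=1), "ci_low": lo, "ci_high": hi}
    )
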