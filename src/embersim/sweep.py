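"""Parameter-space exploration: retention-probability grids over
(theta, nu), loss/retention cell classification, per-panel tallies over
(tau, eta_max), retention/loss boundary extraction, and cross-validation of
the Monte-Carlo engine against the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .analytical import discontinuity_probability, retention_probability_analytic
from .core import ModelParams, ParameterError, delta_t_max
from .numerical import estimate_retention

__all__ = [
    "GridSpec",
    "RetentionGrid",
    "PanelSummary",
    "default_theta_axis",
    "default_nu_axis",
    "PANEL_TAU_VALUES",
    "PANEL_ETA_VALUES",
    "sweep_grid",
    "classify_cells",
    "panel_summaries",
    "count_loss_majority_panels",
    "find_boundary",
    "cross_validate",
    "CrossValidationReport",
    "grid_to_dataframe",
    "plot_grid",
]

#: Forgetting times (years) and expert-pool sizes spanning the canonical
#: 5 x 6 multiplot of retention panels.
PANEL_TAU_VALUES: tuple[float, ...] = (1, 2, 4, 8, 16)
PANEL_ETA_VALUES: tuple[float, ...] = (3, 6, 12, 24, 48, 60)


def _child_seeds(seed: int | None, n: int) -> list[int]:
    """Derive ``n`` distinct 31-bit integer seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def default_theta_axis(n: int = 50) -> np.ndarray:
    """Uniform mean-use-interval axis, 1 to 20 years."""
    return np.linspace(1.0, 20.0, n)


def default_nu_axis(n: int = 50) -> np.ndarray:
    """Uniform variability axis, 0.1 to 2.0 (the canonical sweep range)."""
    return np.linspace(0.1, 2.0, n)


@dataclass(frozen=True)
class GridSpec:
    """Axes and fixed parameters for one retention-probability grid."""

    theta_values: np.ndarray
    nu_values: np.ndarray
    tau: float
    eta_max: float
    horizon_L: float = 1000.0
    n_sequences_K: int = 111
    engine: Literal["analytical", "numerical"] = "analytical"
    seed: int | None = None
    truncation_corrected: bool = False

    def __post_init__(self) -> None:
        for name in ("theta_values", "nu_values"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if vals.size == 0:
                raise ParameterError(f"{name} must be non-empty")
            if vals.size > 1 and not (np.diff(vals) > 0).all():
                raise ParameterError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, vals)
        if self.engine not in ("analytical", "numerical"):
            raise ParameterError(f"unknown engine {self.engine!r}")
        if self.engine == "numerical" and self.seed is None:
            raise ParameterError("numerical grids require a seed")


@dataclass(frozen=True)
class RetentionGrid:
    """P_r evaluated on a (nu, theta) grid; rows index nu, columns theta."""

    grid_spec: GridSpec
    p_r: np.ndarray
    delta_t_max: float

    def __post_init__(self) -> None:
        expected = (self.grid_spec.nu_values.size, self.grid_spec.theta_values.size)
        if self.p_r.shape != expected:
            raise ParameterError(
                f"p_r shape {self.p_r.shape} != |nu| x |theta| {expected}"
            )


@dataclass(frozen=True)
class PanelSummary:
    """Loss/retention cell tally for one (tau, eta_max) panel."""

    tau: float
    eta_max: float
    n_loss_cells: int
    n_retention_cells: int
    n_transition_cells: int
    loss_majority: bool


def _analytical_grid(spec: GridSpec) -> np.ndarray:
    TH, NU = np.meshgrid(spec.theta_values, spec.nu_values)
    p_d = discontinuity_probability(
        TH, NU, spec.tau, spec.eta_max,
        truncation_corrected=spec.truncation_corrected,
    )
    with np.errstate(divide="ignore"):
        log_pr = (spec.horizon_L / TH) * np.log1p(-np.minimum(p_d, 1.0))
    return np.where(p_d >= 1.0, 0.0, np.exp(log_pr))


def _numerical_grid(spec: GridSpec) -> np.ndarray:
    # one derived seed per cell, deterministic in the grid seed
    n_cells = spec.nu_values.size * spec.theta_values.size
    cell_seeds = _child_seeds(spec.seed, n_cells)
    out = np.empty((spec.nu_values.size, spec.theta_values.size))
    idx = 0
    for i, nu in enumerate(spec.nu_values):
        for j, theta in enumerate(spec.theta_values):
            params = ModelParams(
                theta=theta, nu=nu, eta_max=spec.eta_max, tau=spec.tau,
                horizon_L=spec.horizon_L, n_sequences_K=spec.n_sequences_K,
            )
            out[i, j] = estimate_retention(params, cell_seeds[idx]).p_r
            idx += 1
    return out


def sweep_grid(grid_spec: GridSpec) -> RetentionGrid:
    """Evaluate P_r on every (nu, theta) cell with the chosen engine."""
    if grid_spec.engine == "analytical":
        p_r = _analytical_grid(grid_spec)
    else:
        p_r = _numerical_grid(grid_spec)
    return RetentionGrid(
        grid_spec=grid_spec,
        p_r=p_r,
        delta_t_max=delta_t_max(grid_spec.tau, grid_spec.eta_max),
    )


def classify_cells(
    grid: RetentionGrid,
    loss_cut: float = 0.5,
    transition_band: tuple[float, float] = (0.05, 0.95),
) -> PanelSummary:
    """Dichotomize cells at ``loss_cut`` and tally the panel.

    A cell is a loss cell when P_r < loss_cut, otherwise a retention cell.
    Cells with P_r strictly inside ``transition_band`` are additionally
    counted as transition cells (informational; they still belong to one of
    the two main classes).
    """
    lo, hi = transition_band
    if not (0.0 <= loss_cut <= 1.0 and 0.0 <= lo <= hi <= 1.0):
        raise ParameterError("classification cuts must lie in [0, 1]")
    p = grid.p_r
    n_loss = int((p < loss_cut).sum())
    n_ret = p.size - n_loss
    n_trans = int(((p > lo) & (p < hi)).sum())
    return PanelSummary(
        tau=grid.grid_spec.tau,
        eta_max=grid.grid_spec.eta_max,
        n_loss_cells=n_loss,
        n_retention_cells=n_ret,
        n_transition_cells=n_trans,
        loss_majority=n_loss > n_ret,
    )


def panel_summaries(
    tau_values: Sequence[float] = PANEL_TAU_VALUES,
    eta_values: Sequence[float] = PANEL_ETA_VALUES,
    theta_values: np.ndarray | None = None,
    nu_values: np.ndarray | None = None,
    engine: Literal["analytical", "numerical"] = "analytical",
    horizon_L: float = 1000.0,
    n_sequences_K: int = 111,
    seed: int | None = None,
    loss_cut: float = 0.5,
) -> list[PanelSummary]:
    """One classified retention grid per (tau, eta_max) pair."""
    if len(tau_values) == 0 or len(eta_values) == 0:
        raise ParameterError("tau_values and eta_values must be non-empty")
    theta_values = default_theta_axis() if theta_values is None else theta_values
    nu_values = default_nu_axis() if nu_values is None else nu_values
    n_panels = len(tau_values) * len(eta_values)
    seeds: Iterable = (
        _child_seeds(seed, n_panels)
        if engine == "numerical"
        else [None] * n_panels
    )
    summaries = []
    for (tau, eta), panel_seed in zip(
        ((t, e) for t in tau_values for e in eta_values), seeds
    ):
        spec = GridSpec(
            theta_values=theta_values, nu_values=nu_values, tau=tau,
            eta_max=eta, horizon_L=horizon_L, n_sequences_K=n_sequences_K,
            engine=engine, seed=panel_seed,
        )
        summaries.append(classify_cells(sweep_grid(spec), loss_cut=loss_cut))
    return summaries


def count_loss_majority_panels(
    tau_values: Sequence[float] = PANEL_TAU_VALUES,
    eta_values: Sequence[float] = PANEL_ETA_VALUES,
    theta_values: np.ndarray | None = None,
    nu_values: np.ndarray | None = None,
    engine: Literal["analytical", "numerical"] = "analytical",
    **kwargs,
) -> int:
    """Number of (tau, eta_max) panels in which loss cells outnumber
    retention cells over the (theta, nu) plane."""
    summaries = panel_summaries(
        tau_values, eta_values, theta_values, nu_values, engine, **kwargs
    )
    return sum(s.loss_majority for s in summaries)


def find_boundary(grid: RetentionGrid, level: float = 0.5) -> pd.DataFrame:
    """Per-nu-row theta at which P_r crosses ``level``.

    Interpolates linearly in theta between the bracketing cells of the first
    downward crossing. Rows with no crossing inside the theta range get NaN;
    non-monotone rows (possible with the Monte-Carlo engine) use the first
    crossing and are flagged.
    """
    theta = grid.grid_spec.theta_values
    records = []
    for nu, row in zip(grid.grid_spec.nu_values, grid.p_r):
        below = row < level
        monotone = bool((np.diff(row) <= 1e-12).all())
        if not below.any() or below[0]:
            records.append((nu, np.nan, not monotone))
            continue
        j = int(np.argmax(below))  # first cell below level
        x0, x1, y0, y1 = theta[j - 1], theta[j], row[j - 1], row[j]
        cross = x0 + (level - y0) * (x1 - x0) / (y1 - y0)
        records.append((nu, float(cross), not monotone))
    return pd.DataFrame(
        records, columns=["nu", "boundary_theta", "non_monotone"]
    )


@dataclass(frozen=True)
class CrossValidationReport:
    """Per-point numerical-vs-analytical discrepancies and a pass summary."""

    table: pd.DataFrame
    pass_fraction: float
    tolerance_se_multiple: float = 3.0
    tolerance_floor: float = 0.02


def cross_validate(
    param_points: Sequence[ModelParams],
    K: int = 111,
    seed: int = 0,
    se_multiple: float = 3.0,
    floor: float = 0.02,
) -> CrossValidationReport:
    """Compare Monte-Carlo and closed-form P_r at each parameter point.

    A point is flagged when |P_r_num - P_r_ana| > se_multiple * SE + floor,
    with SE the binomial standard error of the Monte-Carlo estimate. At
    nu = 0 both engines are deterministic and must agree exactly.
    """
    point_seeds = _child_seeds(seed, len(param_points))
    rows = []
    for params, point_seed in zip(param_points, point_seeds):
        p = ModelParams(
            theta=params.theta, nu=params.nu, eta_max=params.eta_max,
            tau=params.tau, horizon_L=params.horizon_L, n_sequences_K=K,
            retention_threshold=params.retention_threshold,
        )
        num = estimate_retention(p, point_seed)
        ana = retention_probability_analytic(p)
        disc = abs(num.p_r - ana.p_r)
        tol = se_multiple * num.std_error + floor
        rows.append(
            (p.theta, p.nu, p.tau, p.eta_max, num.p_r, ana.p_r,
             num.std_error, disc, disc > tol)
        )
    table = pd.DataFrame(
        rows,
        columns=["theta", "nu", "tau", "eta_max", "p_r_numerical",
                 "p_r_analytical", "std_error", "discrepancy", "flagged"],
    )
    pass_fraction = float(1.0 - table["flagged"].mean())
    return CrossValidationReport(
        table=table, pass_fraction=pass_fraction,
        tolerance_se_multiple=se_multiple, tolerance_floor=floor,
    )


def grid_to_dataframe(grid: RetentionGrid) -> pd.DataFrame:
    """Tidy long-format view of a grid, one row per cell."""
    spec = grid.grid_spec
    TH, NU = np.meshgrid(spec.theta_values, spec.nu_values)
    return pd.DataFrame(
        {
            "engine": spec.engine,
            "tau": spec.tau,
            "eta_max": spec.eta_max,
            "theta": TH.ravel(),
            "nu": NU.ravel(),
            "p_r": grid.p_r.ravel(),
            "delta_t_max": grid.delta_t_max,
            "K": spec.n_sequences_K if spec.engine == "numerical" else pd.NA,
            "seed": spec.seed if spec.seed is not None else pd.NA,
        }
    )


def plot_grid(grid: RetentionGrid, path: str) -> None:
    """Save a heatmap of the grid (dark = retained, light = lost)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = grid.grid_spec
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(
        spec.theta_values, spec.nu_values, grid.p_r,
        cmap="OrRd", vmin=0.0, vmax=1.0, shading="nearest",
    )
    if spec.theta_values[0] <= grid.delta_t_max <= spec.theta_values[-1]:
        ax.axvline(grid.delta_t_max, color="tab:blue", lw=2)
    ax.set_xlabel("use interval θ (years)")
    ax.set_ylabel("variability ν")
    ax.set_title(
        f"P(retention), τ={spec.tau}, η_max={spec.eta_max} ({spec.engine})"
    )
    fig.colorbar(mesh, ax=ax, label="P_r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
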