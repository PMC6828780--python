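"""Experimental REDOR curve construction and chi-square grid fitting.

Experimental dephasing curves are assembled from S and S0 peak-volume tables:
reference points are recorded on a sparse schedule and linearly interpolated
to the recoupling time points, and the relaxation-compensated fraction
(S0 - S)/S0 cancels the common decay. Per-point errors use a floor of two
times the spectral noise standard deviation, propagated to the fraction by
first-order error propagation.

The two tensor parameters (|delta_aniso|, eta) are fitted by exhaustive
chi-square minimization over a precomputed simulation grid; Leu/Val methyl
pairs can be fitted jointly by summing their chi-square surfaces. Parameter
uncertainties come from a parametric Monte Carlo: the best-fit simulated
curve is perturbed by the per-point errors and refitted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .redor import DephasingCurve, RedorGrid
from .tensor import OrderParameters, order_from_fit, METHYL_CH_BOND_NMR

__all__ = [
    "PeakVolumeTable",
    "FitResult",
    "build_experimental_curve",
    "grid_fit",
    "monte_carlo_errors",
    "read_volume_tables",
    "write_volume_tables",
]


@dataclass
class PeakVolumeTable:
    """Peak volumes versus dephasing time for one site and experiment (S or S0)."""

    site_id: str
    times: np.ndarray  # s
    volumes: np.ndarray  # arbitrary units
    experiment: str  # "S" or "S0"
    noise_sd: float = 0.0  # standard deviation of the spectral noise amplitude

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.experiment not in ("S", "S0"):
            raise ValueError("experiment must be 'S' or 'S0'")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.times.shape != self.volumes.shape:
            raise ValueError("times and volumes must have equal shape")
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.volumes = self.volumes[order]


def read_volume_tables(path) -> dict[tuple[str, str], PeakVolumeTable]:
    """Read a volumes CSV (site_id, time_s, volume, experiment, noise_sd)."""
    df = pd.read_csv(path)
    tables = {}
    for (site, exp), sub in df.groupby(["site_id", "experiment"]):
        tables[(site, exp)] = PeakVolumeTable(
            site_id=site,
            times=sub["time_s"].to_numpy(),
            volumes=sub["volume"].to_numpy(),
            experiment=exp,
            noise_sd=float(sub["noise_sd"].iloc[0]),
        )
    return tables


def write_volume_tables(tables, path) -> None:
    rows = []
    for t in tables:
        for time, vol in zip(t.times, t.volumes):
            rows.append(
                {"site_id": t.site_id, "time_s": time, "volume": vol,
                 "experiment": t.experiment, "noise_sd": t.noise_sd}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def build_experimental_curve(
    S_table: PeakVolumeTable, S0_table: PeakVolumeTable
) -> DephasingCurve:
    """Relaxation-compensated dephasing curve (S0 - S)/S0 with propagated errors.

    S0 is linearly interpolated to the S time points; the S0 schedule must
    bracket every S time (no extrapolation). The volume-level error is
    2 * noise_sd for both experiments.
    """
    if S_table.experiment != "S" or S0_table.experiment != "S0":
        raise ValueError("expected an S table and an S0 table")
    t = S_table.times
    if t.min() < S0_table.times.min() - 1e-12 or t.max() > S0_table.times.max() + 1e-12:
        raise ValueError("S0 schedule does not bracket all S times (extrapolation)")
    s0 = np.interp(t, S0_table.times, S0_table.volumes)
    if np.any(s0 <= 0):
        raise ValueError("interpolated S0 is non-positive at a required time")
    s = S_table.volumes
    frac = (s0 - s) / s0
    sig_s = 2.0 * S_table.noise_sd
    sig_s0 = 2.0 * S0_table.noise_sd
    sigma = np.sqrt((sig_s / s0) ** 2 + (s * sig_s0 / s0**2) ** 2)
    return DephasingCurve(times=t, values=frac, sigma=sigma, kind="experimental",
                          site_id=S_table.site_id)


@dataclass
class FitResult:
    """Best grid node of a chi-square surface over (|delta_aniso|, eta).

    ``delta_aniso`` carries the negative sign of the heteronuclear 1H,13C
    coupling; its magnitude lies on the grid axis.
    """

    delta_aniso: float  # Hz (signed, negative by convention)
    eta: float
    chi2: float
    chi2_surface: np.ndarray  # (n_aniso, n_eta)
    grid: RedorGrid = field(repr=False)
    joint_members: list = field(default_factory=list)
    mc_sd_delta: float | None = None
    mc_sd_eta: float | None = None
    order: OrderParameters | None = None


def _interp_grid_to_times(grid: RedorGrid, times: np.ndarray) -> np.ndarray:
    """Grid curves linearly interpolated in time -> (n_aniso, n_eta, len(times))."""
    gt = np.concatenate([[0.0], grid.times]) if grid.times[0] > 0 else grid.times
    if times.min() < gt.min() - 1e-12 or times.max() > gt.max() + 1e-12:
        raise ValueError("curve times outside the simulated grid time range")
    gc = grid.curves
    if gt.size != grid.times.size:  # prepend the exact zero point
        gc = np.concatenate([np.zeros(gc.shape[:2] + (1,)), gc], axis=2)
    flat = gc.reshape(-1, gt.size)
    out = np.empty((flat.shape[0], times.size))
    for i in range(flat.shape[0]):
        out[i] = np.interp(times, gt, flat[i])
    return out.reshape(gc.shape[0], gc.shape[1], times.size)


def _argmin_tiebreak(chi2: np.ndarray, grid: RedorGrid) -> tuple[int, int]:
    """Index of the chi-square minimum; ties go to smaller |delta|, then eta."""
    flat = chi2.ravel()
    best = flat.min()
    cand = np.flatnonzero(np.isclose(flat, best, rtol=0.0, atol=best * 1e-12 + 1e-30))
    ii, jj = np.unravel_index(cand, chi2.shape)
    order = np.lexsort((grid.eta_axis[jj], grid.aniso_axis[ii]))
    return int(ii[order[0]]), int(jj[order[0]])


def grid_fit(
    curves: DephasingCurve | list[DephasingCurve],
    grid: RedorGrid,
    r: float = METHYL_CH_BOND_NMR,
    S_f_sq: float = 1.0 / 9.0,
) -> FitResult:
    """Fit one or more dephasing curves against the simulation grid.

    Multiple curves (e.g. the two methyls of a Val residue) share a single
    tensor: their chi-square surfaces are summed node-wise.
    """
    if isinstance(curves, DephasingCurve):
        curves = [curves]
    if not curves or any(len(c) == 0 for c in curves):
        raise ValueError("empty dephasing curve")
    chi2 = np.zeros((grid.aniso_axis.size, grid.eta_axis.size))
    for c in curves:
        sim = _interp_grid_to_times(grid, c.times)
        if c.sigma is None or np.all(c.sigma == 0):
            if c.sigma is not None:
                warnings.warn("all per-point errors are zero; unweighted fit")
            w = np.ones_like(c.values)
        else:
            w = c.sigma
        chi2 += np.sum(((c.values[None, None, :] - sim) / w) ** 2, axis=2)
    i, j = _argmin_tiebreak(chi2, grid)
    delta_mag = grid.aniso_axis[i]
    order = None
    try:
        order = order_from_fit(delta_mag, r=r, S_f_sq=S_f_sq)
    except ValueError:
        pass  # fitted coupling beyond the rigid limit: leave order undefined
    return FitResult(
        delta_aniso=-delta_mag,
        eta=float(grid.eta_axis[j]),
        chi2=float(chi2[i, j]),
        chi2_surface=chi2,
        grid=grid,
        joint_members=[c.site_id for c in curves if c.site_id],
        order=order,
    )


def monte_carlo_errors(
    fit: FitResult,
    curves: DephasingCurve | list[DephasingCurve],
    grid: RedorGrid,
    n_runs: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Parametric Monte Carlo parameter spreads (sd of refit delta, eta).

    Each run perturbs the best-fit simulated curve by Gaussian noise with the
    per-point sigma of the data and refits on the grid.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if isinstance(curves, DephasingCurve):
        curves = [curves]
    if any(c.sigma is None for c in curves):
        raise ValueError("per-point errors required for Monte Carlo")
    rng = np.random.default_rng(seed)
    i0 = int(np.argmin(np.abs(grid.aniso_axis - abs(fit.delta_aniso))))
    j0 = int(np.argmin(np.abs(grid.eta_axis - fit.eta)))

    sims, sigmas, bests = [], [], []
    for c in curves:
        sim = _interp_grid_to_times(grid, c.times)
        sims.append(sim.reshape(-1, c.times.size))
        sigmas.append(c.sigma)
        bests.append(sim[i0, j0])
    sim_nodes = np.concatenate(sims, axis=1)  # (n_nodes, nt_total)
    sigma = np.concatenate(sigmas)
    best = np.concatenate(bests)

    safe = np.where(sigma > 0, sigma, 1.0)
    deltas = np.empty(n_runs)
    etas = np.empty(n_runs)
    shape = (grid.aniso_axis.size, grid.eta_axis.size)
    for r_ in range(n_runs):
        data = best + rng.normal(0.0, sigma)
        chi2 = np.sum(((data[None, :] - sim_nodes) / safe[None, :]) ** 2, axis=1)
        i, j = _argmin_tiebreak(chi2.reshape(shape), grid)
        deltas[r_] = grid.aniso_axis[i]
        etas[r_] = grid.eta_axis[j]
    return float(np.std(deltas, ddof=1)), float(np.std(etas, ddof=1))
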