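"""Treatment planning: ablation metrics, power/time sweeps, calibration.

The planning layer answers the clinical questions the simulator exists for:

* how much of the tumor is necrosed, how much healthy tissue is damaged, and
  what is the minimal 3D safety margin (``coverage_metrics``);
* how long does a given input power take to necrose the whole tumor
  (``ablation_time``), and how does that time fall with power;
* what is the smallest power on a grid that achieves complete ablation within
  a time budget, and is its ablation zone acceptably shaped
  (``optimal_power``);
* the single scalar efficiency factor eta that anchors the reduced model to
  one known operating point — 10 W just ablating the smaller study tumor at
  600 s — after which every other predicted number is out-of-sample
  (``calibrate_efficiency``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.ndimage import distance_transform_edt, map_coordinates

from .bioheat import ThermalState, run_simulation
from .damage import DamageParams, damage_fraction, necrosis_mask
from .materials import PropertySet
from .phantoms import LabelGrid


@dataclass(frozen=True)
class CoverageMetrics:
    coverage: float            # necrosed tumor fraction, 0..1
    healthy_damage_cm3: float  # necrosed healthy-tissue volume
    margin_mm: float           # min signed distance tumor surface -> necrosis boundary


@dataclass
class PowerEvaluation:
    power: float
    ablation_time: Optional[float]   # s, None if not achieved within budget
    coverage: float
    healthy_damage_cm3: float
    margin_mm: float
    elongated: bool
    center_T_final: float


@dataclass
class PlanResult:
    """Outcome of a power sweep / optimal-power search."""

    evaluations: list
    optimal_power: Optional[float]
    efficiency: float
    criterion: str
    duration: float

    def table(self) -> np.ndarray:
        """(power, ablation_time-or-nan) rows, ascending in power."""
        return np.array([[e.power,
                          np.nan if e.ablation_time is None else e.ablation_time]
                         for e in self.evaluations])


@dataclass
class SimOptions:
    """Numerical settings shared by all planning runs."""

    dt: float = 0.25
    em_backend: str = "fdfd"
    em_options: dict = field(default_factory=dict)
    em_resolve_delta_T: float = 10.0


def _necrosis_field(state: ThermalState, criterion: str,
                    params: DamageParams, peak_T=None) -> np.ndarray:
    if criterion == "arrhenius":
        return necrosis_mask(damage_fraction(state.omega), params,
                             mode="arrhenius")
    if criterion == "isotherm":
        T = state.T if peak_T is None else peak_T
        return necrosis_mask(T, params, mode="isotherm")
    raise ValueError(f"unknown completeness criterion {criterion!r}")


def coverage_metrics(state: ThermalState, grid: LabelGrid,
                     params: Optional[DamageParams] = None,
                     criterion: str = "arrhenius",
                     peak_T=None) -> CoverageMetrics:
    """Coverage fraction, healthy damage and minimal safety margin.

    The margin is the minimum over tumor-surface mesh vertices of the signed
    distance to the necrosis boundary: positive when the whole surface lies
    inside the necrotic zone, negative as soon as any surface point is
    outside it.
    """
    params = params or DamageParams()
    tumor = grid.tumor_mask
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("grid contains no tumor voxels")
    necro = _necrosis_field(state, criterion, params, peak_T)
    coverage = float((necro & tumor).sum()) / n_tumor
    healthy_cm3 = float((necro & grid.healthy_mask).sum()) \
        * grid.voxel_volume * 1e6

    h = grid.spacing
    if necro.any() and not necro.all():
        signed = (distance_transform_edt(necro)
                  - distance_transform_edt(~necro)) * h
    elif necro.all():
        signed = np.full(grid.shape, np.inf)
    else:
        signed = np.full(grid.shape, -np.inf)
    verts = grid.mesh.vertices
    coords = (verts - grid.origin[None, :]).T / h
    if np.isfinite(signed).all():
        vertex_dist = map_coordinates(signed, coords, order=1, mode="nearest")
        margin_mm = float(vertex_dist.min()) * 1e3
    else:
        margin_mm = float(np.inf if necro.all() else -np.inf)
    return CoverageMetrics(coverage=coverage, healthy_damage_cm3=healthy_cm3,
                           margin_mm=margin_mm)


def _coverage_monitor(grid: LabelGrid, params: DamageParams, criterion: str):
    """Cheap per-step completeness check via the tumor-minimum damage/peak T."""
    tumor_idx = np.nonzero(grid.tumor_mask)
    omega_star = params.omega_threshold
    if criterion == "arrhenius":
        def complete(state: ThermalState) -> bool:
            return bool(state.omega[tumor_idx].min() >= omega_star)
        return complete, None
    if criterion == "isotherm":
        peak = {"T": None}

        def track(state, q_ext):
            if peak["T"] is None:
                peak["T"] = state.T.copy()
            else:
                np.maximum(peak["T"], state.T, out=peak["T"])

        def complete(state: ThermalState) -> bool:
            T = peak["T"] if peak["T"] is not None else state.T
            return bool(T[tumor_idx].min() >= params.isotherm_threshold)
        return complete, (track, peak)
    raise ValueError(f"unknown completeness criterion {criterion!r}")


def simulate_until(grid: LabelGrid, antenna, duration: float,
                   materials: PropertySet, params: DamageParams,
                   sim: SimOptions, criterion: str = "arrhenius",
                   stop_on_complete: bool = True,
                   snapshot_times: Iterable[float] = ()):
    """Run a planning simulation, tracking completeness each step.

    Returns ``(result, ablation_time_or_None, peak_T_or_None)`` where the
    ablation time is the earliest step time at which every tumor voxel meets
    the chosen necrosis criterion (resolution = one time step, well within
    +/-5 s).
    """
    complete, tracker = _coverage_monitor(grid, params, criterion)
    callbacks = []
    peak_store = None
    if tracker is not None:
        callbacks.append(tracker[0])
        peak_store = tracker[1]
    reached = {"t": None}

    def monitor(state: ThermalState) -> bool:
        if reached["t"] is None and complete(state):
            reached["t"] = state.time
        return stop_on_complete and reached["t"] is not None

    result = run_simulation(
        grid, antenna, duration, materials, params,
        dt=sim.dt, em_backend=sim.em_backend, em_options=sim.em_options,
        em_resolve_delta_T=sim.em_resolve_delta_T,
        snapshot_times=snapshot_times,
        stop_when=monitor, callbacks=callbacks)
    peak_T = peak_store["T"] if peak_store is not None else None
    return result, reached["t"], peak_T


def ablation_time(grid: LabelGrid, antenna, power: float, *,
                  t_max: float = 900.0, criterion: str = "arrhenius",
                  materials: Optional[PropertySet] = None,
                  params: Optional[DamageParams] = None,
                  sim: Optional[SimOptions] = None) -> Optional[float]:
    """Earliest time (s) of complete tumor necrosis at ``power`` W.

    Runs the coupled simulation up to ``t_max`` and monitors the completeness
    criterion every time step; returns ``None`` when the tumor is never fully
    necrosed within the budget.
    """
    if power <= 0:
        raise ValueError("power must be positive")
    materials = materials or PropertySet()
    params = params or DamageParams()
    sim = sim or SimOptions()
    _, t_abl, _ = simulate_until(grid, antenna.with_power(power), t_max,
                                 materials, params, sim, criterion)
    return t_abl


def _elongation_ratio(necro: np.ndarray, spacing: float) -> float:
    idx = np.nonzero(necro)
    if len(idx[0]) == 0:
        return 0.0
    axial = (idx[2].max() - idx[2].min() + 1) * spacing
    trans_x = (idx[0].max() - idx[0].min() + 1) * spacing
    trans_y = (idx[1].max() - idx[1].min() + 1) * spacing
    return axial / max(0.5 * (trans_x + trans_y), spacing)


def optimal_power(grid: LabelGrid, antenna, duration: float = 600.0,
                  powers: Sequence[float] = tuple(range(8, 26)), *,
                  criterion: str = "arrhenius",
                  materials: Optional[PropertySet] = None,
                  params: Optional[DamageParams] = None,
                  sim: Optional[SimOptions] = None,
                  elongation_limit: float = 1.6) -> PlanResult:
    """Smallest grid power that completely necroses the tumor within ``duration``.

    Evaluates the ascending power grid; for each power records the ablation
    time (if reached), coverage and healthy-damage metrics at the end of the
    run, and whether the necrosis zone is undesirably elongated (axial/
    transverse extent above ``elongation_limit``).  The optimum is the first
    power whose coverage reaches 1.0 within the duration.
    """
    powers = sorted(float(p) for p in powers)
    if not powers:
        raise ValueError("empty power grid")
    materials = materials or PropertySet()
    params = params or DamageParams()
    sim = sim or SimOptions()

    evaluations = []
    optimal = None
    for p in powers:
        result, t_abl, peak_T = simulate_until(
            grid, antenna.with_power(p), duration, materials, params, sim,
            criterion, stop_on_complete=False)
        state = result.final
        metrics = coverage_metrics(state, grid, params, criterion, peak_T)
        necro = _necrosis_field(state, criterion, params, peak_T)
        ev = PowerEvaluation(
            power=p, ablation_time=t_abl, coverage=metrics.coverage,
            healthy_damage_cm3=metrics.healthy_damage_cm3,
            margin_mm=metrics.margin_mm,
            elongated=_elongation_ratio(necro, grid.spacing) > elongation_limit,
            center_T_final=float(result.center_series[-1, 1]))
        evaluations.append(ev)
        if optimal is None and t_abl is not None:
            optimal = p
    return PlanResult(evaluations=evaluations, optimal_power=optimal,
                      efficiency=antenna.efficiency, criterion=criterion,
                      duration=duration)


@dataclass
class CalibrationResult:
    efficiency: float
    achieved_time: float
    history: list   # (eta, ablation_time or None)


def calibrate_efficiency(grid: LabelGrid, antenna, *,
                         anchor_power: float = 10.0,
                         anchor_time: float = 600.0,
                         tolerance: float = 5.0,
                         eta_range: tuple = (0.05, 1.5),
                         criterion: str = "arrhenius",
                         materials: Optional[PropertySet] = None,
                         params: Optional[DamageParams] = None,
                         sim: Optional[SimOptions] = None,
                         max_iter: int = 12) -> CalibrationResult:
    """Bisection on the efficiency factor eta to hit the calibration anchor.

    Finds eta such that the ablation time at ``anchor_power`` equals
    ``anchor_time`` within ``tolerance`` seconds.  The ablation time is
    monotone decreasing in eta, so plain bisection on the sign of
    (t_abl − anchor_time) converges; runs are capped just above the anchor
    time because "not yet complete at anchor_time + tolerance" already
    determines the sign.  Deterministic.
    """
    materials = materials or PropertySet()
    params = params or DamageParams()
    sim = sim or SimOptions()
    t_cap = anchor_time + 4 * tolerance
    history = []

    def eval_eta(eta: float):
        ant = antenna.with_efficiency(eta).with_power(anchor_power)
        _, t_abl, _ = simulate_until(grid, ant, t_cap, materials, params,
                                     sim, criterion)
        history.append((eta, t_abl))
        return t_abl

    lo, hi = eta_range
    t_hi = eval_eta(hi)
    if t_hi is None or t_hi > anchor_time + tolerance:
        raise RuntimeError(
            f"even eta={hi} cannot ablate the anchor tumor by "
            f"{anchor_time + tolerance} s; the anchor is unreachable")
    if abs(t_hi - anchor_time) <= tolerance:
        return CalibrationResult(hi, t_hi, history)
    t_lo = eval_eta(lo)
    if t_lo is not None and t_lo < anchor_time - tolerance:
        raise RuntimeError(
            f"eta={lo} already over-ablates the anchor tumor "
            f"({t_lo:.0f} s < {anchor_time} s)")

    best = (hi, t_hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        t_mid = eval_eta(mid)
        if t_mid is not None and abs(t_mid - anchor_time) <= tolerance:
            return CalibrationResult(mid, t_mid, history)
        if t_mid is None or t_mid > anchor_time:
            lo = mid
        else:
            hi = mid
            best = (mid, t_mid)
    return CalibrationResult(best[0], best[1], history)
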