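"""Leukocyte concentration transport and shear-thresholded adhesion.

The normalized concentration rho (1 at the inlet) is advected by the flow
with a positivity-preserving donor-cell scheme and depleted at the wall by
a sink whose rate coefficient k(WSS) vanishes above a species-specific
threshold.  The realized sink is k(WSS) * rho in *tracked* mode (so
upstream depletion reduces downstream adhesion); *uniform* mode accrues the
pure-WSS rate with rho frozen at 1 and leaves the field untouched.  Adhered
amounts are ledgered in (s, theta) wall bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .hemodynamics import MM, ProjectionSolver
from .wall_shear import WallSampleSet

__all__ = [
    "LeukocyteSpecies",
    "NEUTROPHIL",
    "MONOCYTE",
    "LYMPHOCYTE",
    "rate_coefficient",
    "ConcentrationState",
    "AdhesionLedger",
    "ScalarTransport",
    "TransportCoupler",
    "apply_sink",
    "adhesion_profile",
]


@dataclass(frozen=True)
class LeukocyteSpecies:
    """Adhesion parameters for one species.

    The rate law k(WSS) is pluggable: 'linear' ramps from k_max at WSS = 0
    to zero at the threshold; 'step' is k_max throughout the adhesive
    window.  WSS equal to the threshold is inside the adhesive regime.
    """

    name: str
    rho_ref: float             # reference blood concentration [cells/l]
    wss_th: float              # adhesion threshold [Pa]
    k_max: float = 1.0         # maximal rate coefficient [1/s]
    law: str = "linear"

    def __post_init__(self):
        if self.rho_ref <= 0 or self.wss_th <= 0 or self.k_max < 0:
            raise ValueError("rho_ref, wss_th must be > 0 and k_max >= 0")
        if self.law not in _RATE_LAWS:
            raise ValueError(f"unknown rate law {self.law!r}; "
                             f"available: {sorted(_RATE_LAWS)}")


def _law_linear(wss, th, k_max):
    return k_max * (1.0 - wss / th)


def _law_step(wss, th, k_max):
    return np.full_like(np.asarray(wss, float), k_max)


_RATE_LAWS = {"linear": _law_linear, "step": _law_step}


# Neutrophil values are clinically anchored (reference 4.34e9 cells/l,
# threshold 1.2 Pa).  Monocyte and lymphocyte thresholds/references are
# provisional placeholders, NOT taken from any study; configure per run.
NEUTROPHIL = LeukocyteSpecies("neutrophil", rho_ref=4.34e9, wss_th=1.2)
MONOCYTE = LeukocyteSpecies("monocyte", rho_ref=0.5e9, wss_th=0.9)
LYMPHOCYTE = LeukocyteSpecies("lymphocyte", rho_ref=2.0e9, wss_th=0.6)


def rate_coefficient(wss, species: LeukocyteSpecies):
    """k(WSS) [1/s]: zero above the threshold, nonincreasing below it,
    k(0) = k_max.  NaN input (invalid wall probe) yields 0."""
    arr = np.asarray(wss, float)
    if np.any(arr[np.isfinite(arr)] < 0):
        raise ValueError("WSS magnitude cannot be negative")
    with np.errstate(invalid="ignore"):
        k = np.where(arr <= species.wss_th,
                     _RATE_LAWS[species.law](arr, species.wss_th, species.k_max),
                     0.0)
    k = np.where(np.isfinite(arr), k, 0.0)
    k = np.clip(k, 0.0, species.k_max)
    return float(k) if np.isscalar(wss) else k


@dataclass
class ConcentrationState:
    """Non-negative normalized concentration on the flow grid cells."""

    rho: np.ndarray
    t: float = 0.0


@dataclass
class AdhesionLedger:
    """Accumulated adhered amount per (s, theta) wall bin plus the running
    instantaneous-sink bookkeeping for one retained period."""

    s_mm: np.ndarray
    theta: np.ndarray
    bin_area_mm2: np.ndarray           # (Ns, Mt)
    accumulated: np.ndarray = None     # (Ns, Mt) [m^3 * normalized conc]
    elapsed: float = 0.0

    def __post_init__(self):
        if self.accumulated is None:
            self.accumulated = np.zeros_like(self.bin_area_mm2)

    def add_flat(self, flat_bins: np.ndarray, amounts: np.ndarray):
        if np.any(amounts < -1e-30):
            raise ValueError("ledger increments must be nonnegative")
        np.add.at(self.accumulated.ravel(), flat_bins, amounts)

    def reset(self):
        self.accumulated[:] = 0.0
        self.elapsed = 0.0

    def total(self) -> float:
        return float(np.sum(self.accumulated))

    def downstream_total(self, s_from_mm: float) -> float:
        sel = self.s_mm >= s_from_mm
        return float(np.sum(self.accumulated[sel]))


def adhesion_profile(ledger: AdhesionLedger, period: float) -> tuple[np.ndarray, np.ndarray]:
    """Section profile Rbar(s)*T [mm]: adhered volume per unit wall area per
    period.  The ledger must span exactly one retained cardiac period."""
    if not np.isclose(ledger.elapsed, period, rtol=1e-6, atol=1e-12):
        raise ValueError(
            f"ledger spans {ledger.elapsed:.6g} s, expected one period "
            f"({period:.6g} s)")
    acc_mm3 = np.sum(ledger.accumulated, axis=1) / MM ** 3
    area = np.sum(ledger.bin_area_mm2, axis=1)
    return ledger.s_mm, acc_mm3 / area


def apply_sink(rho, k, dt: float, mode: str = "tracked"):
    """Pointwise wall-sink update over one step.

    Tracked mode depletes rho by exact exponential decay and returns the
    removed (adhered) amount; uniform mode leaves rho untouched and accrues
    the pure-rate amount k*1*dt.  Returns (rho_new, adhered_increment).
    """
    rho = np.asarray(rho, float)
    k = np.asarray(k, float)
    if mode == "tracked":
        removed = rho * (1.0 - np.exp(-k * dt))
        return rho - removed, removed
    if mode == "uniform":
        return rho.copy(), k * dt * np.ones_like(rho)
    raise ValueError(f"unknown sink mode {mode!r}")


class ScalarTransport:
    """Donor-cell advection of a passive scalar on the solver's grid.

    The projected velocity field is discretely divergence-free in *every*
    cell (solid cells included), so the fluxes use the full staggered face
    velocities and the scalar is evolved in all cells: the scheme then
    preserves constants exactly, is positivity-preserving, and conserves
    mass exactly against the inlet/outlet flux bookkeeping it returns.
    (Faces deep inside the solid carry zero velocity, so the solid region
    beyond the forced boundary layer stays inert.)
    """

    def __init__(self, solver: ProjectionSolver):
        if solver.periodic_x:
            raise ValueError("scalar transport requires the inlet/outlet mode")
        self.solver = solver
        self.h = solver.h
        self.fluid_cell = solver.fluid_cell

    def fresh_state(self) -> ConcentrationState:
        return ConcentrationState(rho=np.ones(self.solver.grid.shape),
                                  t=self.solver.t)

    def advect(self, conc: ConcentrationState, dt: float,
               rho_inlet: float = 1.0):
        """One explicit upwind step; returns (influx, outflux) in
        m^3 * normalized concentration for this step."""
        s = self.solver
        h = self.h
        rho = conc.rho
        speed = (np.max(np.abs(s.u)) + np.max(np.abs(s.v)) + np.max(np.abs(s.w)))
        if speed * dt / h > 1.0:
            raise ValueError(
                f"scalar CFL violation: (|u|+|v|+|w|) dt/h = {speed * dt / h:.3f}")
        h2 = h * h
        fx = np.empty_like(s.u)
        ui = s.u[1:-1]
        fx[1:-1] = ui * h2 * np.where(ui > 0, rho[:-1], rho[1:])
        u0 = s.u[0]
        fx[0] = u0 * h2 * np.where(u0 > 0, rho_inlet, rho[0])
        un = s.u[-1]
        fx[-1] = un * h2 * rho[-1]
        fy = np.zeros_like(s.v)
        vi = s.v[:, 1:-1]
        fy[:, 1:-1] = vi * h2 * np.where(vi > 0, rho[:, :-1], rho[:, 1:])
        fz = np.zeros_like(s.w)
        if rho.shape[2] > 1:
            wi = s.w[:, :, 1:-1]
            fz[:, :, 1:-1] = wi * h2 * np.where(wi > 0, rho[:, :, :-1],
                                                rho[:, :, 1:])
        div = (fx[1:] - fx[:-1]) + (fy[:, 1:] - fy[:, :-1])
        if rho.shape[2] > 1:
            div = div + (fz[:, :, 1:] - fz[:, :, :-1])
        conc.rho = rho - dt / h ** 3 * div
        conc.t += dt
        influx = float(np.sum(fx[0])) * dt
        outflux = float(np.sum(fx[-1])) * dt
        return influx, outflux

    def storage(self, conc: ConcentrationState) -> float:
        return float(np.sum(conc.rho)) * self.h ** 3


class TransportCoupler:
    """Couples scalar transport + wall adhesion to a running flow solve.

    Runs every species simultaneously in both modes: *tracked* (own
    depleted concentration field) and *uniform* (rho frozen at 1).  Driven
    by the callbacks of :func:`lumenflow.hemodynamics.run_cycles`.
    """

    def __init__(self, species: list[LeukocyteSpecies], samples: WallSampleSet):
        self.species = species
        self.samples = samples
        self._wss_flat = None
        self._ready = False

    def _bind(self, solver: ProjectionSolver):
        self.transport = ScalarTransport(solver)
        # sink cells: fluid cells with at least one solid 6-neighbour
        fc = solver.fluid_cell
        pad = np.pad(fc, 1, mode="edge")
        nb_solid = np.zeros_like(fc, bool)
        for ax in range(3):
            if fc.shape[ax] == 1:
                continue
            for sl_nb in (slice(0, -2), slice(2, None)):
                sl = [slice(1, -1)] * 3
                sl[ax] = sl_nb
                nb_solid |= ~pad[tuple(sl)]
        sink = fc & nb_solid
        self.sink_idx = np.flatnonzero(sink.ravel())
        xc, yc, zc = solver.grid.cell_axes()
        X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])[self.sink_idx]
        tree = cKDTree(self.samples.flat_points())
        _, self.sink_bins = tree.query(pts)
        self.conc = {sp.name: self.transport.fresh_state() for sp in self.species}
        self.ledgers = {sp.name: AdhesionLedger(
            self.samples.s_mm, self.samples.theta,
            self.samples.bin_area_mm2.copy()) for sp in self.species}
        self.ledgers_uniform = {sp.name: AdhesionLedger(
            self.samples.s_mm, self.samples.theta,
            self.samples.bin_area_mm2.copy()) for sp in self.species}
        self.balance = {sp.name: dict(influx=0.0, outflux=0.0, adhered=0.0,
                                      storage0=self.transport.storage(
                                          self.conc[sp.name]))
                        for sp in self.species}
        self._k = {sp.name: np.zeros(len(self.sink_idx)) for sp in self.species}
        self._ready = True

    # -- run_cycles callbacks ---------------------------------------------

    def on_cycle_start(self, solver: ProjectionSolver, period: float):
        if not self._ready:
            self._bind(solver)
        for name in self.conc:
            self.ledgers[name].reset()
            self.ledgers_uniform[name].reset()
            self.balance[name] = dict(influx=0.0, outflux=0.0, adhered=0.0,
                                      storage0=self.transport.storage(
                                          self.conc[name]))

    def on_wss(self, wss: np.ndarray):
        self._wss_flat = np.asarray(wss).ravel()
        if self._ready:
            for sp in self.species:
                k_bin = rate_coefficient(self._wss_flat, sp)
                self._k[sp.name] = k_bin[self.sink_bins]

    def on_step(self, solver: ProjectionSolver, dt: float):
        if not self._ready:
            self._bind(solver)
        vol = self.transport.h ** 3
        # substep the scalar if the momentum dt crowds the scalar CFL bound
        h = self.transport.h
        speed = (np.max(np.abs(solver.u)) + np.max(np.abs(solver.v))
                 + np.max(np.abs(solver.w)))
        n_sub = max(1, int(np.ceil(speed * dt / (0.9 * h))))
        for sp in self.species:
            conc = self.conc[sp.name]
            influx = outflux = 0.0
            for _ in range(n_sub):
                fi, fo = self.transport.advect(conc, dt / n_sub)
                influx += fi
                outflux += fo
            bal = self.balance[sp.name]
            bal["influx"] += influx
            bal["outflux"] += outflux
            k = self._k[sp.name]
            decay = 1.0 - np.exp(-k * dt)
            flat = conc.rho.ravel()
            removed = flat[self.sink_idx] * decay
            flat[self.sink_idx] -= removed
            self.ledgers[sp.name].add_flat(self.sink_bins, removed * vol)
            self.ledgers[sp.name].elapsed += dt
            bal["adhered"] += float(np.sum(removed)) * vol
            # uniform-concentration comparison mode: rho == 1 everywhere
            self.ledgers_uniform[sp.name].add_flat(self.sink_bins, k * dt * vol)
            self.ledgers_uniform[sp.name].elapsed += dt

    # -- reporting ---------------------------------------------------------

    def balance_error(self, name: str) -> float:
        """|influx - outflux - d(storage) - adhered| / influx for the last
        retained cycle (tracked mode)."""
        bal = self.balance[name]
        storage = self.transport.storage(self.conc[name]) - bal["storage0"]
        resid = bal["influx"] - bal["outflux"] - storage - bal["adhered"]
        return abs(resid) / max(bal["influx"], 1e-300)

    def profiles(self, period: float, mode: str = "tracked"):
        src = self.ledgers if mode == "tracked" else self.ledgers_uniform
        return {name: adhesion_profile(led, period) for name, led in src.items()}
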