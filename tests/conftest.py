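"""Shared fixtures.  The expensive flow solves are session-scoped and
reused across the unit, property, and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from lumenflow import geometry as geo
from lumenflow import hemodynamics as hemo
from lumenflow import leukocyte as leuko
from lumenflow import wall_shear as ws
from lumenflow.synthetic_study import SyntheticStudySpec, synth_baseline


# ---------------------------------------------------------------------------
# steady plane Poiseuille (2D mode)
# ---------------------------------------------------------------------------

def _poiseuille2d(ncells: int):
    h_gap = 2e-3
    h = h_gap / ncells
    dom = hemo.ChannelDomain(0.0, h_gap)
    grid = hemo.CartesianGrid.from_bounds(
        [0.0, -2 * h, 0.0], [8e-3, h_gap + 2 * h, h], h)
    fluid = hemo.FluidProperties(rho=1000.0, mu=1e-3)
    u_bulk = 0.01
    sol = hemo.run_steady(dom, fluid, grid, u_bulk, tol=1e-6)
    return dict(solver=sol, domain=dom, grid=grid, fluid=fluid,
                u_bulk=u_bulk, h_gap=h_gap, h=h)


@pytest.fixture(scope="session")
def poiseuille2d_32():
    return _poiseuille2d(32)


@pytest.fixture(scope="session")
def poiseuille2d_16():
    return _poiseuille2d(16)


# ---------------------------------------------------------------------------
# steady pipe Poiseuille (3D IBM)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def pipe3d():
    radius = 1e-3
    ncpd = 24
    h = 2 * radius / ncpd
    dom = hemo.PipeDomain(radius)
    grid = hemo.CartesianGrid.from_bounds(
        [0.0, -radius - 2 * h, -radius - 2 * h],
        [5e-3, radius + 2 * h, radius + 2 * h], h)
    fluid = hemo.FluidProperties(rho=1000.0, mu=1e-3)
    u_bulk = 0.01
    sol = hemo.run_steady(dom, fluid, grid, u_bulk, tol=1e-6)
    # measured flow rate -> honest bulk velocity
    i_mid = grid.shape[0] // 2
    q = float(np.sum(sol.u[i_mid][sol.fluid_face[0][i_mid]])) * h * h
    u_meas = q / (np.pi * radius ** 2)
    samples = _pipe_wall_samples(dom, radius,
                                 np.linspace(1.5e-3, 3.5e-3, 7), 32)
    return dict(solver=sol, domain=dom, grid=grid, fluid=fluid,
                radius=radius, u_bulk=u_bulk, u_meas=u_meas, h=h,
                samples=samples)


def _pipe_wall_samples(dom, radius, xs, n_theta):
    th = 2 * np.pi * np.arange(n_theta) / n_theta
    pts = np.zeros((len(xs), n_theta, 3))
    nrm = np.zeros_like(pts)
    pts[:, :, 0] = xs[:, None]
    pts[:, :, 1] = radius * np.cos(th)
    pts[:, :, 2] = radius * np.sin(th)
    nrm[:, :, 1] = -np.cos(th)
    nrm[:, :, 2] = -np.sin(th)
    return ws.WallSampleSet(
        points_m=pts, normals_in=nrm, s_mm=xs / 1e-3, theta=th,
        r_mm=np.full((len(xs), n_theta), radius / 1e-3),
        bin_area_mm2=np.ones((len(xs), n_theta)), sdf_m=dom.sdf)


# ---------------------------------------------------------------------------
# pulsatile Womersley validation (periodic driven mode)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def womersley_run():
    radius = 1e-3
    ncpd = 24
    h = 2 * radius / ncpd
    rho, mu = 1060.0, 3.5e-3
    nu = mu / rho
    alpha = 2.5
    omega = alpha ** 2 * nu / radius ** 2
    period = 2 * np.pi / omega
    dom = hemo.PipeDomain(radius)
    grid = hemo.CartesianGrid.from_bounds(
        [0.0, -radius - 2 * h, -radius - 2 * h],
        [4 * h, radius + 2 * h, radius + 2 * h], h)
    sol = hemo.ProjectionSolver(dom, hemo.FluidProperties(rho=rho, mu=mu),
                                grid, hemo.SolverConfig(), periodic_x=True)
    sol.bulk_area_m2 = np.pi * radius ** 2
    u0, u1 = 0.01, 0.005
    dt = 0.4 * h ** 2 / (6 * nu)
    n = int(np.ceil(period / dt))
    dt = period / n
    probe = np.array([[2 * h, 0.0, 0.0]])
    t_hist, u_hist = [], []
    n_cycles = 4
    for cycle in range(n_cycles):
        for _ in range(n):
            t_next = sol.t + dt
            sol.step(dt)
            sol.enforce_bulk(u0 + u1 * np.cos(omega * t_next))
            if cycle == n_cycles - 1:
                t_hist.append(sol.t)
                u_hist.append(sol.state().interp_velocity(probe)[0, 0])
    t_hist = np.asarray(t_hist)
    u_hist = np.asarray(u_hist)
    design = np.column_stack([np.ones_like(t_hist),
                              np.cos(omega * t_hist), np.sin(omega * t_hist)])
    coef, *_ = np.linalg.lstsq(design, u_hist, rcond=None)
    c_meas = coef[1] - 1j * coef[2]
    return dict(alpha=alpha, u0=u0, u1=u1, steady_centerline=coef[0],
                c_meas=c_meas, omega=omega, period=period)


# ---------------------------------------------------------------------------
# pulsatile 2D stenosis analog with coupled leukocyte transport
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def stenosis2d():
    gap0 = 2e-3          # healthy gap (2D analog of D = 2 mm)
    severity = 0.5
    half_width = 2e-3
    ncells = 16
    h = gap0 / ncells

    def gap(x):
        u = x / half_width
        g = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
        return gap0 * (1.0 - severity * g)

    dom = hemo.ChannelDomain(lambda x: -0.5 * gap(x), lambda x: 0.5 * gap(x))
    x_lo, x_hi = -6e-3, 18e-3
    grid = hemo.CartesianGrid.from_bounds(
        [x_lo, -0.5 * gap0 - 2 * h, 0.0], [x_hi, 0.5 * gap0 + 2 * h, h], h)
    fluid = hemo.FluidProperties(rho=1060.0, mu=3.5e-3)
    # clinically anchored mean bulk velocity; period shortened (scaled-down
    # run) to keep the suite within budget -- Womersley number ~ 2.2
    waveform = hemo.PulsatileWaveform.default_triphasic(u_mean=0.384, period=0.4)
    cfg = hemo.SolverConfig(n_cycles=3, n_transient=1, wss_stride=5)
    x_mm = np.arange(x_lo * 1e3 + 0.25, x_hi * 1e3 - 0.25, 0.25)
    samples = ws.samples_for_channel(dom, x_mm, dz_mm=h * 1e3)
    species = [
        leuko.NEUTROPHIL,
        leuko.LeukocyteSpecies("lymphocyte", rho_ref=2.0e9, wss_th=0.6),
        # threshold far below every realized WSS: must accrue exactly zero
        leuko.LeukocyteSpecies("subthreshold", rho_ref=1e9, wss_th=1e-12),
    ]
    coupler = leuko.TransportCoupler(species, samples)

    def sampler(state):
        return ws.instantaneous_wss(state, samples, fluid.mu)

    hist = hemo.run_cycles(dom, fluid, waveform, grid, cfg,
                           wall_sampler=sampler, coupler=coupler,
                           u_peak_scale=1.6 / (1.0 - severity))
    return dict(hist=hist, coupler=coupler, samples=samples, waveform=waveform,
                fluid=fluid, domain=dom, grid=grid, species=species,
                x_mm=x_mm, h=h, u_mean=0.384)


# ---------------------------------------------------------------------------
# tortuous vs straight centerline (3D, steady inflow)
# ---------------------------------------------------------------------------

def _steady_artery_case(surface, u_bulk=0.05, rho=1000.0, mu=1.25e-3,
                        cells_per_diameter=12):
    d_m = surface.mean_diameter * hemo.MM
    h = d_m / cells_per_diameter
    dom = hemo.ArteryDomain(surface)
    lo, hi = dom.bounds_m()
    grid = hemo.CartesianGrid.from_bounds(lo, hi, h, margin=2 * h)
    fluid = hemo.FluidProperties(rho=rho, mu=mu)
    sol = hemo.run_steady(dom, fluid, grid, u_bulk, tol=2e-5)
    samples = ws.samples_from_surface(surface)
    wss = ws.instantaneous_wss(sol.state(), samples, fluid.mu)
    wbar = np.array([ws.azimuthal_average(wss[i], samples.r_mm[i],
                                          samples.theta)
                     for i in range(wss.shape[0])])
    return dict(solver=sol, surface=surface, samples=samples, wss=wss,
                wbar=wbar, fluid=fluid, grid=grid)


@pytest.fixture(scope="session")
def centerline_pair():
    spec = SyntheticStudySpec(diameter=2.0, n_frames=20, stenosis_severity=0.0,
                              tortuosity_amplitude=0.6,
                              tortuosity_wavelength=12.0, contour_noise=0.0,
                              n_theta=48, seed=3)
    frames, centerline = synth_baseline(spec)
    d = 2.0
    surf_t = geo.add_extensions(geo.stack_frames(frames, centerline),
                                inlet_length=2 * d, outlet_length=3 * d)
    surf_s = geo.add_extensions(geo.straighten(frames),
                                inlet_length=2 * d, outlet_length=3 * d)
    case_t = _steady_artery_case(surf_t)
    case_s = _steady_artery_case(surf_s)
    return dict(tortuous=case_t, straight=case_s, frames=frames,
                centerline=centerline, spec=spec)


# ---------------------------------------------------------------------------
# slowly tapered tube (WSS ~ R^-3 scaling)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def tapered3d():
    n_frames = 24
    s = 0.5 * np.arange(n_frames)
    radii = np.linspace(1.0, 0.68, n_frames)
    frames = [geo.ContourFrame(index=i, s=float(s[i]),
                               radii=np.full(48, radii[i]))
              for i in range(n_frames)]
    surf = geo.add_extensions(geo.straighten(frames),
                              inlet_length=3.0, outlet_length=4.0)
    case = _steady_artery_case(surf, u_bulk=0.05, rho=1000.0, mu=3.33e-3,
                               cells_per_diameter=16)
    case["frame_radii"] = radii
    case["frame_s"] = s
    return case
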