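"""Independent numerical verification of the closed-form solution.

Two cross-checks, deliberately sharing no code with the series
evaluation:

* a Crank-Nicolson finite-difference solver for the heat equation with
  the same initial/boundary conditions, and
* a classical fixed-step RK4 integrator for the mode ODE

      dC_n/dt + alpha (n pi / L)^2 C_n = (dT A_n)/(L t0) exp(-t/t0),
      C_n(0) = -dT A_n / L,

  whose trajectory must match the closed form C_n = (2 dT/pi) D_n.

Crank-Nicolson is unconditionally stable, which matters here because
titanium's large diffusivity would make explicit time steps
impractically small.  The t = 0, y = L corner is discontinuous (the
interior starts at T2 while the boundary jumps to T1); plain CN only
damps the resulting high-frequency error slowly, so the march opens
with two backward-Euler half-steps (Rannacher start) which suppress the
oscillation without costing second-order accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .thermal_model import (
    ImplantModel,
    TemperatureField,
    ThermalLoad,
    fourier_coefficient,
    load_temperature,
)

__all__ = ["FdGridSpec", "FieldErrorReport", "fd_solve", "integrate_mode_ode", "field_error"]


@dataclass(frozen=True)
class FdGridSpec:
    """Finite-difference resolution: interior nodes, time step, final time.

    ``dt = None`` defaults to tau/2000 for the implant being solved.
    """

    n_space: int = 200
    dt: float | None = None
    t_end: float = 10.0

    def __post_init__(self) -> None:
        if int(self.n_space) != self.n_space or self.n_space < 10:
            raise ValueError(f"n_space must be an integer >= 10, got {self.n_space}")
        if self.dt is not None and not self.dt > 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if not self.t_end > 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")


@dataclass(frozen=True)
class FieldErrorReport:
    """Discrepancy between two temperature fields on a common grid."""

    max_abs: float
    rms: float
    location_of_max: tuple[float, float]
    interpolated: bool = False

    def __post_init__(self) -> None:
        if not (self.max_abs >= self.rms >= 0.0):
            raise ValueError("expected max_abs >= rms >= 0")


def fd_solve(
    model: ImplantModel, load: ThermalLoad, spec: FdGridSpec = FdGridSpec()
) -> TemperatureField:
    """Crank-Nicolson solution of dT/dt = alpha d2T/dy2 on a uniform grid.

    Dirichlet ends: y = 0 pinned at T2, y = L follows the load, with the
    time-dependent boundary value taken at the half-step t + dt/2 so the
    scheme stays second order in time.  Returns the full (times x
    positions) field including both boundary columns and the t = 0 row.
    """
    dt = spec.dt if spec.dt is not None else model.intrinsic_time / 2000.0
    n = spec.n_space
    dy = model.length / (n + 1)
    r = model.diffusivity * dt / dy**2
    n_steps = int(math.ceil(spec.t_end / dt))

    times = np.empty(n_steps + 1)
    values = np.empty((n_steps + 1, n + 2))
    y_interior = np.arange(1, n + 1) * dy

    u = np.full(n, load.t_body)  # interior starts at body temperature
    times[0] = 0.0
    values[0, :] = load.t_body
    values[0, -1] = load_temperature(load, 0.0)

    def banded(theta_r: float) -> np.ndarray:
        """Tridiagonal (I + theta_r * A) in solve_banded's (3, n) layout,
        A being the negated interior second-difference operator."""
        ab = np.zeros((3, n))
        ab[0, 1:] = -theta_r
        ab[1, :] = 1.0 + 2.0 * theta_r
        ab[2, :-1] = -theta_r
        return ab

    ab_cn = banded(r / 2.0)
    # backward Euler with step dt/2 has mesh ratio r/2 and implicit weight 1
    ab_be_half = banded(r / 2.0)

    def interior_laplacian(v: np.ndarray) -> np.ndarray:
        """Second difference of the interior vector with zero boundary
        entries; boundary contributions are added separately."""
        out = -2.0 * v
        out[1:] += v[:-1]
        out[:-1] += v[1:]
        return out

    t = 0.0
    for step in range(n_steps):
        if step == 0:
            # Rannacher start: two backward-Euler half-steps damp the
            # high-frequency error from the t=0, y=L corner jump.
            for _ in range(2):
                rhs = u.copy()
                rhs[0] += (r / 2.0) * load.t_body
                rhs[-1] += (r / 2.0) * load_temperature(load, t + dt / 2.0)
                u = solve_banded((1, 1), ab_be_half, rhs)
                t += dt / 2.0
        else:
            # boundary values of both half-operators taken at t + dt/2
            b_half = load_temperature(load, t + dt / 2.0)
            rhs = u + (r / 2.0) * interior_laplacian(u)
            rhs[0] += r * load.t_body
            rhs[-1] += r * b_half
            u = solve_banded((1, 1), ab_cn, rhs)
            t += dt

        times[step + 1] = t
        values[step + 1, 0] = load.t_body
        values[step + 1, 1:-1] = u
        values[step + 1, -1] = load_temperature(load, t)

    positions = np.concatenate(([0.0], y_interior, [model.length]))
    return TemperatureField(
        times=times, positions=positions, values=values,
        method="finite_difference", model=model, load=load, config=spec,
    )


def integrate_mode_ode(
    n: int,
    model: ImplantModel,
    load: ThermalLoad,
    times,
    steps_per_tau: float = 1000.0,
) -> np.ndarray:
    """Classical RK4 trajectory of the mode coefficient C_n(t).

    Fixed step ``<= tau / (steps_per_tau * n^2)`` — shrinking with n^2
    keeps the integrator inside its stability region for stiff high
    modes.  Returns C_n at each requested time; the closed form is
    ``C_n = (2 dT / pi) D_n`` and the two must agree to ~1e-6 |dT|.
    """
    if int(n) != n or n < 1:
        raise ValueError("mode index n must be a positive integer")
    times = np.asarray(times, dtype=float)
    if times.size == 0 or times[0] != 0.0 or np.any(np.diff(times) < 0):
        raise ValueError("times must be non-decreasing and start at 0")

    tau = model.intrinsic_time
    lam = n**2 / tau  # decay rate alpha (n pi / L)^2
    a_n = fourier_coefficient(int(n), model.length)
    drive = load.delta_t * a_n / (model.length * load.exposure_time)
    t0 = load.exposure_time

    def f(t: float, c: float) -> float:
        return -lam * c + drive * math.exp(-t / t0)

    h_max = tau / (steps_per_tau * n**2)
    c = -load.delta_t * a_n / model.length
    t = 0.0
    out = np.empty(times.size)
    out[0] = c if times[0] == 0.0 else math.nan
    idx = 1 if times[0] == 0.0 else 0
    for idx in range(idx, times.size):
        target = times[idx]
        while t < target - 1e-15:
            h = min(h_max, target - t)
            k1 = f(t, c)
            k2 = f(t + h / 2.0, c + h / 2.0 * k1)
            k3 = f(t + h / 2.0, c + h / 2.0 * k2)
            k4 = f(t + h, c + h * k3)
            c += h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[idx] = c
    return out


def field_error(a: TemperatureField, b: TemperatureField) -> FieldErrorReport:
    """Max-abs and RMS discrepancy between two fields of the same problem.

    ``b`` is interpolated bilinearly onto ``a``'s grid when the node
    sets differ (the report flags this).  Fields produced from different
    implant models or loads are rejected.
    """
    if a.model != b.model or a.load != b.load:
        raise ValueError("fields come from different models or loads")

    interpolated = not (
        np.array_equal(a.times, b.times) and np.array_equal(a.positions, b.positions)
    )
    if interpolated:
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (b.times, b.positions), b.values, method="linear",
            bounds_error=False, fill_value=None,
        )
        tt, yy = np.meshgrid(a.times, a.positions, indexing="ij")
        b_vals = interp(np.stack([tt.ravel(), yy.ravel()], axis=1)).reshape(
            a.values.shape
        )
    else:
        b_vals = b.values

    diff = np.abs(a.values - b_vals)
    i, j = np.unravel_index(int(np.argmax(diff)), diff.shape)
    return FieldErrorReport(
        max_abs=float(diff[i, j]),
        rms=float(np.sqrt(np.mean(diff**2))),
        location_of_max=(float(a.times[i]), float(a.positions[j])),
        interpolated=interpolated,
    )
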