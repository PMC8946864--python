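import numpy as np
import pytest

import implant_heat as ih


@pytest.fixture(scope="session")
def implant_a() -> ih.ImplantModel:
    return ih.preset_model("implant_A")


@pytest.fixture(scope="session")
def implant_b() -> ih.ImplantModel:
    return ih.preset_model("implant_B")


@pytest.fixture(scope="session")
def hot_load() -> ih.ThermalLoad:
    return ih.ThermalLoad(t_hot=60.0, t_body=37.0, exposure_time=2.0)


def fd_error_report(model, load, n_space=200, dt=None, t_end=10.0, t_min=None,
                    max_rows=1500):
    """Analytic-vs-CN discrepancy, comparing FD rows at t >= t_min.

    The default start of the comparison window, max(0.05 s, 10 dt),
    excludes the region where neither side is trustworthy: the
    truncated series carries Gibbs error from the t=0, y=L corner jump
    below ~0.05 s, and the CN march needs a few steps to damp the same
    corner discontinuity.  Row count is capped by striding so large FD
    grids stay cheap to compare.
    """
    spec = ih.FdGridSpec(n_space=n_space, dt=dt, t_end=t_end)
    dt_eff = dt if dt is not None else model.intrinsic_time / 2000.0
    if t_min is None:
        t_min = max(0.05, 10.0 * dt_eff)
    fd = ih.fd_solve(model, load, spec)
    keep = np.flatnonzero(fd.times >= t_min)
    stride = max(1, len(keep) // max_rows)
    keep = keep[::stride]
    fd_sub = ih.TemperatureField(
        times=fd.times[keep], positions=fd.positions, values=fd.values[keep],
        method=fd.method, model=fd.model, load=fd.load, config=fd.config,
    )
    analytic = ih.evaluate_field(
        model, load, ih.EvaluationGrid(fd_sub.times, fd_sub.positions)
    )
    return ih.field_error(analytic, fd_sub), fd_sub


@pytest.fixture(scope="session")
def fd_comparison_a(implant_a, hot_load):
    """Default-resolution and 2x-refined CN errors for implant A, t0 = 2 s."""
    coarse, _ = fd_error_report(implant_a, hot_load)
    fine, _ = fd_error_report(
        implant_a, hot_load, n_space=401, dt=implant_a.intrinsic_time / 4000.0
    )
    return coarse, fine
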