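import dataclasses

import numpy as np
import pytest

import coarctflow as cf
from coarctflow.boundary import BoundaryConditions, build_sink_band, developed_inlet
from coarctflow.solver import SolverParams, solve_steady_flow


@pytest.fixture(scope="session")
def reference_cohort():
    return cf.load_reference_cohort()


@pytest.fixture(scope="session")
def straight_tube():
    """R = 10 mm straight tube, 5 cm long (no stenosis)."""
    return cf.build_vessel(r_ref=0.010, degree=0.0, length=0.05,
                           stenosis_center=0.025, stenosis_length=0.01,
                           branch_band=(0.01, 0.02))


@pytest.fixture(scope="session")
def straight_mesh(straight_tube):
    return cf.generate_mesh(straight_tube, cf.MeshSpec())


@pytest.fixture(scope="session")
def poiseuille_field(straight_tube, straight_mesh):
    """Newtonian (3.5 mPa s) run at Q = 100 ml/s with a discrete
    fully-developed inlet, at the default 0.4 mm mesh."""
    inlet = developed_inlet(straight_mesh, 100.0)
    sink = build_sink_band(straight_tube, 100.0, 100.0)
    bcs = BoundaryConditions(inlet=inlet, sink=sink, q_in=1e-4, q_out=1e-4)
    field = solve_steady_flow(straight_mesh, bcs, cf.NewtonianParams(0.0035),
                              SolverParams())
    assert field.converged
    return field


@pytest.fixture(scope="session")
def zero_sd_spec():
    """Degenerate cohort distribution: every draw equals its mean."""
    spec = cf.CohortDistributionSpec()
    kw = {f.name: 0.0 for f in dataclasses.fields(spec) if f.name.endswith("_sd")}
    kw["noise_sd_rest"] = 0.0
    kw["noise_sd_ex"] = 0.0
    kw["flow_scale_log_sd"] = 0.0
    kw["male_fraction"] = 1.0
    return dataclasses.replace(spec, **kw)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
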