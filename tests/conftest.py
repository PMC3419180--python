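import numpy as np
import pytest

import tortuflow as tf

# Printed steady pressure-drop table (Pa), rows by tortuosity angle (deg),
# columns by tortuosity count 0..5.
TABLE1 = {
    30.0: (81.5, 115.0, 159.0, 205.0, 244.0, 285.0),
    60.0: (81.5, 107.0, 137.0, 166.0, 196.0, 228.0),
    90.0: (81.5, 101.0, 121.0, 145.0, 167.0, 187.0),
    120.0: (81.5, 92.7, 104.0, 116.0, 127.0, 139.0),
}

# Printed pulsatile drops (Pa) for the 30-degree, two-unit model at the
# cardiac landmarks t1, t2, t3.
TABLE2_30_2 = (1000.0, 400.0, 300.0)
ANCHOR_TIMES = (0.26, 0.36, 0.80)


@pytest.fixture(scope="session")
def fluid():
    return tf.FluidProperties()          # blood: mu = 3.5 mPa s, rho = 1050 kg/m^3


@pytest.fixture(scope="session")
def steady_bc():
    return tf.BoundaryConditionSet()     # 0.156 m/s plug inlet, zero outlet gauge


def solve_design_point(theta_deg, n, interval_mm=1.0, bc=None, cfg=None):
    """Build, mesh and steadily solve one design point at paper conditions."""
    geom = tf.VesselGeometry(theta_deg=theta_deg, n=n)
    path = tf.build_centerline(geom)
    mesh = tf.sweep_mesh(tf.offset_lumen(path, geom.d), path, interval_mm)
    fields = tf.solve_steady(mesh, tf.FluidProperties(),
                             bc or tf.BoundaryConditionSet(),
                             cfg or tf.SolverConfig())
    return geom, path, mesh, fields


@pytest.fixture(scope="session")
def coarse_straight():
    """Steady solution of the straight vessel on the nominal 1 mm mesh."""
    return solve_design_point(30.0, 0)


@pytest.fixture(scope="session")
def steady_sweep():
    """Full 4 angles x 6 counts steady design sweep at paper conditions."""
    return tf.run_design_sweep()
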