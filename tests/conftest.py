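import numpy as np
import pytest

import elbamd
from elbamd.units import GCM3_PER_AMUNM3, WATER_MOLAR_MASS


@pytest.fixture(scope="session")
def ff():
    return elbamd.load_default()


@pytest.fixture(scope="session")
def dopc(ff):
    return elbamd.make_template("DOPC", ff)


@pytest.fixture(scope="session")
def small_bilayer(ff):
    """32-lipid DOPC bilayer with a thin water layer (oracle-sized)."""
    spec = elbamd.BuildSpec(species="DOPC", n_lipids=32, hydration=4,
                            temperature=303.0)
    return elbamd.build_bilayer(spec, seed=2, ff=ff)


@pytest.fixture(scope="session")
def water_npt(ff):
    """Equilibrated 512-site water NPT run at 303 K / 1 atm with a density
    time series; shared by the equation-of-state and diffusion checks."""
    st = elbamd.build_water_box(512, T=303.0, seed=7, ff=ff)
    sim = elbamd.Simulation(st, ff,
                            elbamd.SimConfig(thermostat=True, barostat="iso",
                                             seed=7))
    sim.relax(1000)
    sim.run(4000)                      # 60 ps settling toward 1 atm
    log = sim.run(11000, log_stride=100)   # 165 ps production
    rho = np.array([512 * WATER_MOLAR_MASS / row["volume"] * GCM3_PER_AMUNM3
                    for row in log])
    return {"sim": sim, "log": log, "rho": rho}


@pytest.fixture(scope="session")
def water_msd(water_npt):
    """Continued NVT run of the equilibrated water box recording unwrapped
    positions for the self-diffusion estimate."""
    sim = water_npt["sim"]
    sim.cfg.barostat = "none"
    rec = []

    def grab(s):
        rec.append((s.state.time, s.state.unwrapped().copy()))

    sim.run(20200, observers=[(100, grab)])   # > 300 ps sampled
    times = np.array([t for t, _ in rec])
    pos = np.array([p for _, p in rec])
    return times, pos
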