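import numpy as np
import pytest

from vibronic_dimer import (
    BathSpec,
    DisorderSpec,
    averaged_dimer_signals,
    averaged_monomer_signal,
    fixtures,
)

OMEGA1 = np.arange(11900.0, 12650.0, 3.0)
T2 = np.arange(0.0, 2001.0, 10.0)
T1 = np.arange(0.0, 2000.0 + 1e-9, 4.0)


@pytest.fixture(scope="session")
def reference():
    return fixtures()["reference"]


@pytest.fixture(scope="session")
def ref_dimer(reference):
    return reference.dimer


@pytest.fixture(scope="session")
def ref_bath() -> BathSpec:
    return BathSpec()


@pytest.fixture(scope="session")
def ref_ensemble(reference):
    """Disorder-averaged R1/R4 signals of the reference dimer (n = 2000)."""
    s1, s4, beta = averaged_dimer_signals(
        reference.dimer, reference.bath, reference.disorder, OMEGA1, T2, T1
    )
    return s1, s4, beta


@pytest.fixture(scope="session")
def ref_monomer_signal(reference):
    """Disorder-broadened monomer vibrational reference (n = 2000)."""
    return averaged_monomer_signal(
        reference.dimer, reference.bath, reference.disorder, OMEGA1, T2, T1
    )


@pytest.fixture(scope="session")
def small_disorder():
    return DisorderSpec(n_samples=400, seed=711 + 20130619)
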