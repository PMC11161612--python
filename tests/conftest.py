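import pytest

from quorumsim import ColonyParameters, calibrate_threshold


@pytest.fixture(scope="session")
def reference_colony() -> ColonyParameters:
    """The packaged diffusion-study conditions: P = 5000 molecules/cell-s,
    n = 1e6 cells/mL, Ws = 1 um, R = 0.45 mm, D = 1e-6 cm^2/s."""
    return ColonyParameters.from_lab_units(
        production_rate=5000.0,
        cell_density_per_ml=1.0e6,
        colony_radius_mm=0.45,
        diffusion_coefficient=1.0e-6,
        cell_width_um=1.0,
    )


@pytest.fixture(scope="session")
def calibrated_threshold(reference_colony):
    """Threshold making the reference colony exactly critical (~8.4 nM)."""
    return calibrate_threshold(reference_colony)
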