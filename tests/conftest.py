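"""Shared synthetic fixtures: axes and simulation plans used across modules."""

import pytest

from spinproc import AxisSpec, PeakSpec, SimulationPlan


@pytest.fixture
def axis():
    """Small fast axis: 500 MHz, 12 ppm window, 4096 points."""
    return AxisSpec(sfo_mhz=500.0, sw_ppm=12.0, n_points=4096, ppm_max=10.0)


@pytest.fixture
def fine_axis():
    """Higher-resolution axis for width/integral measurements."""
    return AxisSpec(sfo_mhz=500.0, sw_ppm=12.0, n_points=16384, ppm_max=10.0)


@pytest.fixture
def single_peak_plan():
    return SimulationPlan(
        n_samples=3, peaks=(PeakSpec(5.0, 100.0, 4.0),), seed=11)


@pytest.fixture
def mixture_plan():
    """Two factor levels, jitter and noise: the generic study-condition plan."""
    assignment = {f"S{i:02d}": ("A" if i < 3 else "B") for i in range(6)}
    return SimulationPlan(
        n_samples=6,
        peaks=(
            PeakSpec(0.0, 120.0, 3.0),
            PeakSpec(1.33, 80.0, 3.0, multiplicity=2, j_hz=7.0),
            PeakSpec(2.55, 60.0, 3.0, multiplicity=3, j_hz=7.0),
            PeakSpec(5.23, 50.0, 4.0),
            PeakSpec(8.45, 40.0, 3.0),
        ),
        ppm_jitter_sd=0.002,
        noise_sd=0.5,
        factor_assignment=assignment,
        group_effects={("B", 3): 2.0},
        seed=7,
    )
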