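import pytest

from fadtools.family_io import GroupedAlignment
from fadtools.synthetic_data import (
    default_family_spec,
    fm1_demo_truth,
    simulate_family,
    simulate_peaks,
    simulate_structure_model,
)


@pytest.fixture(scope="session")
def planted_family():
    """Default 2×4-sequence family with 12 planted sites (seed 42)."""
    spec = default_family_spec(42)
    ga, truth = simulate_family(spec)
    return spec, ga, truth


@pytest.fixture()
def tiny_alignment():
    return GroupedAlignment(
        rows=[("a", "ACD-"), ("b", "AC-E"), ("c", "ACDE"), ("d", "ACDE"), ("q", "ACDE")],
        groups={"a": "delta12", "b": "delta12", "c": "omega3", "d": "omega3", "q": "query"},
    )


@pytest.fixture(scope="session")
def toy_shell_model():
    layout = [
        ("HIS", 105, 2.2),
        ("HIS", 141, 2.3),
        ("PHE", 157, 4.5),
        ("ILE", 290, 4.8),
        ("TRP", 308, 4.9),
        ("LEU", 200, 8.0),
    ]
    return layout, simulate_structure_model(layout, seed=7)


@pytest.fixture(scope="session")
def demo_peak_tables():
    """Noise-free demo assay: quantification must invert it exactly."""
    return simulate_peaks(fm1_demo_truth(), noise_sigma=0.0, seed=0)
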