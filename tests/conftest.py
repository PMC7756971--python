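import numpy as np
import pytest

from formulanet.io import FeatureRecord, FeatureTable, SpectrumRecord
from formulanet.manifest import SampleEntry, SampleManifest
from formulanet.simulate import SynthConfig, generate_dataset


def make_spectrum(feature_id, precursor, peaks, charge=1):
    """Build a SpectrumRecord from a list of (mz, intensity)."""
    return SpectrumRecord(feature_id, precursor, charge, np.array(peaks, dtype=float))


@pytest.fixture(scope="session")
def small_manifest():
    """Formula + three herbs (equal w/w) + one blank."""
    return SampleManifest(
        [
            SampleEntry("F", "formula"),
            SampleEntry("hA", "herb", herb_code="A", herb_color="#ff0000", ww_proportion=0.5),
            SampleEntry("hB", "herb", herb_code="B", herb_color="#00ff00", ww_proportion=0.25),
            SampleEntry("hC", "herb", herb_code="C", herb_color="#0000ff", ww_proportion=0.25),
            SampleEntry("BK", "blank"),
        ]
    )


def make_feature(fid, mz, rt, heights):
    return FeatureRecord(fid, mz, rt, dict(heights))


@pytest.fixture
def small_table(small_manifest):
    """Four features: single-herb, mixed, blank-derived, herb-only."""
    zeros = {s: 0.0 for s in small_manifest.sample_ids}
    return FeatureTable("PI", [
        make_feature(1, 300.1, 1.0, {**zeros, "F": 100.0, "hA": 1000.0}),
        make_feature(2, 400.2, 2.0, {**zeros, "F": 50.0, "hA": 300.0, "hB": 100.0, "hC": 600.0}),
        make_feature(3, 500.3, 3.0, {**zeros, "F": 20.0, "hA": 100.0, "BK": 90.0}),
        make_feature(4, 600.4, 4.0, {**zeros, "hB": 500.0}),
    ])


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study (10 herbs, 4 families x 5 members,
    6 ubiquitous metabolites, noise_cv 0.1, seed 42)."""
    return generate_dataset(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def default_networks(default_bundle):
    from formulanet.network import build_network

    return {
        mode: build_network(default_bundle.spectra[mode], mode=mode)
        for mode in ("PI", "NI")
    }
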