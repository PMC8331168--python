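import numpy as np
import pytest

from prmkit import pipeline
from prmkit.conservation import MultipleAlignment
from prmkit.peaks import Chromatogram


@pytest.fixture(scope="session")
def demo_run():
    """Noise-free 2x2x3 demo study, simulated and quantified once per session."""
    return pipeline.run_demo_pipeline(pipeline.demo_config(cv=0.0), seed=7)


@pytest.fixture()
def gaussian_xic():
    """Noise-free Gaussian peak (amplitude 100, sigma 0.05 min) on a zero baseline."""
    t = np.arange(19.0, 21.0 + 1e-9, 0.01)
    y = 100.0 * np.exp(-0.5 * ((t - 20.0) / 0.05) ** 2)
    return Chromatogram(sample_id="s", transition_id="tr", times=t, intensities=y)


@pytest.fixture()
def small_msa():
    return MultipleAlignment.from_pairs(
        [
            ("At", "MKRAGSVDEL"),
            ("Bo", "MKRAGSVDEI"),
            ("Os", "MKRAGAVNEL"),
            ("Pp", "MKKAGSVNEI"),
        ]
    )


@pytest.fixture(scope="session")
def covarying_msa():
    """Six taxa, 200 columns: 100 group-separating columns + 100 constant ones.

    Taxa T0-T2 and T3-T5 form two perfectly supported clades.
    """
    rows = [("A" if i < 3 else "L") * 100 + "G" * 100 for i in range(6)]
    return MultipleAlignment.from_pairs([(f"T{i}", rows[i]) for i in range(6)])
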