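import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ftirpath.bands import default_band_library, default_ratios
from ftirpath.roi import quantify_rois
from ftirpath.synthetic import default_study_specs, generate_cube

settings.register_profile(
    "suite", derandomize=True, max_examples=40, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

STUDY_SEED = 1  # fixed study seed used by the fixtures below


@pytest.fixture(scope="session")
def band_library():
    return default_band_library()


@pytest.fixture(scope="session")
def ratio_defs():
    return default_ratios()


@pytest.fixture(scope="session")
def default_study(band_library, ratio_defs):
    """One full synthetic study at the default conditions: per case the
    cube, ROI set, ground truth and quantified ROI table."""
    out = {}
    for spec in default_study_specs(seed=STUDY_SEED):
        cube, roiset, truth = generate_cube(spec)
        quant = quantify_rois(cube, roiset, band_library, ratio_defs)
        out[spec.case_id] = {
            "spec": spec, "cube": cube, "roiset": roiset,
            "truth": truth, "quant": quant,
        }
    return out


@pytest.fixture(scope="session")
def study_quant(default_study):
    import pandas as pd

    return pd.concat([c["quant"] for c in default_study.values()],
                     ignore_index=True)


def gaussian(x, center, sigma, amp=1.0):
    x = np.asarray(x, float)
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma ** 2))
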