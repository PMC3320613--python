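import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fecmap.genmap import GeneticMap, default_ril_map
from fecmap.simulate import triangular_coefficients

warnings.filterwarnings("ignore", message=".*convergence.*", category=UserWarning)

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def ril_map():
    return default_ril_map(102)


@pytest.fixture
def two_marker_map():
    return GeneticMap(
        pd.DataFrame(
            {"marker": ["m1", "m2"], "chrom": ["1", "1"], "cm": [0.0, 20.0]}
        )
    )


@pytest.fixture
def typed_genotypes(ril_map):
    from fecmap.simulate import simulate_ril_genotypes

    return simulate_ril_genotypes(ril_map, 12, seed=42)


def make_exact_records(coeffs_by_class, days=range(1, 15), n_flies=4,
                       environment="assay"):
    """Noise-free egg records lying exactly on given curves.

    ``coeffs_by_class``: {class label: (b0, b1, b2)}.  Egg 'counts' are the
    exact back-transformed curve values (real-valued), so curve fits must
    reproduce the coefficients to numerical precision.
    """
    rows = []
    for cls, (b0, b1, b2) in coeffs_by_class.items():
        for f in range(n_flies):
            fly = f"{cls}_f{f}"
            vial = f"{cls}_v{f % 2}"
            for d in days:
                mu = np.expm1(b0 + b1 * np.log(d) + b2 * d)
                rows.append((cls, cls, environment, vial, fly, d, max(mu, 0.0)))
    return pd.DataFrame(
        rows,
        columns=["line", "genotype_class", "environment", "vial", "fly", "day", "eggs"],
    )


@pytest.fixture
def exact_curve_records():
    b = triangular_coefficients(40.0, 4.0, -0.35)
    return make_exact_records({"ctrl": b})
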