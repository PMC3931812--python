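import numpy as np
import pytest

import camfret as cf

# Apparent Kd (µM) per construct, with the isotherm regime each sits in at
# 0.5 µM biosensor (hyperbolic only where Kd >> [BS]).
TABLE1_KD = {
    "BSGPER83-93": (136.62, "hyperbolic"),
    "BSGPER150-175": (0.44, "quadratic"),
    "BSGPER150-170": (3.41, "quadratic"),
    "BSGPER242-259": (8.01, "quadratic"),
    "BSGPER330-351": (1.40, "quadratic"),
    "BSGPER330-345": (1.60, "quadratic"),
}

# (EC50 µM, Hill n) per complex species.
TABLE2_HILL = {
    "CaM-GPER83-93-sp1": (0.13, 1.99),
    "CaM-GPER83-93-sp2": (3.71, 2.53),
    "CaM-GPER150-175": (2.38, 1.21),
    "CaM-GPER242-259": (5.15, 1.43),
    "CaM-GPER330-351": (0.75, 1.18),
}

BS_TOTAL = 0.5  # µM, biosensor concentration in every assay


def cam_roundtrip_fit(kd, model, **config_kwargs):
    """Generate a noiseless titration with true Kd and fit it back."""
    cfg = cf.GeneratorConfig(true_kd=kd, binding_model=model,
                             bs_total=BS_TOTAL, **config_kwargs)
    series = cf.simulate_cam_titration(cfg)
    response = cf.apply_dilution_correction(series)
    return cf.fit_binding(response, BS_TOTAL, model=model)


def ca_assay_roundtrip(ec50, n, **config_kwargs):
    """Generate a noiseless monophasic Ca2+ assay and analyze it end to end."""
    cfg = cf.GeneratorConfig(hill_species=[cf.HillSpecies(ec50, n)],
                             n_points=25, **config_kwargs)
    assay = cf.simulate_ca_assay(cfg)
    return cf.run_ca_assay(assay)


@pytest.fixture
def mixture_assay():
    """Noiseless two-species (0.25/0.75) biphasic Ca2+ assay."""
    cfg = cf.GeneratorConfig(
        hill_species=[cf.HillSpecies(0.13, 1.99, 0.25),
                      cf.HillSpecies(3.71, 2.53, 0.75)],
        n_points=25,
    )
    return cf.simulate_ca_assay(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20140221)
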