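import numpy as np
import pandas as pd
import pytest

from fetrad.features import all_feature_names
from fetrad.phantom import default_phantom_spec, simulate_patient

# Desk-scale phantom: same anatomy as the default spec, quarter-size grid.
SMALL_KW = dict(
    grid_shape=(24, 24, 16),
    midsagittal_index=11.5,
    tumor_center=(17.0, 12.0, 8.0),
    tumor_radii=(3.0, 3.0, 3.0),
    ventricle_center=(12.0, 12.0, 8.0),
    ventricle_radii=(1.8, 3.0, 2.0),
    crescent_center=(6.0, 17.0, 8.0),
    crescent_radius=4.0,
    crescent_notch_offset=(2.0, 0.0, 0.0),
)


def small_spec(seed=0, noise_scale=0.0, **overrides):
    kw = {**SMALL_KW, **overrides}
    return default_phantom_spec(seed=seed, noise_scale=noise_scale, **kw)


@pytest.fixture(scope="session")
def noisefree_patient():
    """Noise-free small-grid patient with the default isometabolic tumor."""
    return simulate_patient(small_spec(seed=7, noise_scale=0.0))


@pytest.fixture(scope="session")
def noisy_patient():
    return simulate_patient(small_spec(seed=11, noise_scale=0.05))


def make_feature_table(
    n_patients=10,
    rng=None,
    effect=None,
    phenotype="isometabolic",
):
    """Random long-format feature table; ``effect`` maps (kind, feature) -> shift
    added to tumor rows only."""
    rng = rng or np.random.default_rng(0)
    effect = effect or {}
    names = all_feature_names()
    rows = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        for kind in ("TBR_5_15", "TBR_20_40", "TTP"):
            base = rng.normal(size=len(names))
            for voi in ("tumor", "mirrored"):
                vals = base + rng.normal(scale=1.0, size=len(names))
                row = {
                    "patient_id": pid,
                    "phenotype": phenotype,
                    "voi": voi,
                    "kind": kind,
                }
                row.update(dict(zip(names, vals)))
                if voi == "tumor":
                    for (k, f), shift in effect.items():
                        if k == kind:
                            row[f] += shift
                rows.append(row)
    return pd.DataFrame(rows)
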