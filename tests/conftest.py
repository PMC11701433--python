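import numpy as np
import pandas as pd
import pytest

from tlscape.synth import MARKERS, SlideConfig, TLSSpec, simulate_slide

#: compositions that satisfy every inclusion rule (B majority, CD4/CD8 present)
COMP_EARLY = {"Bcell": 0.58, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04, "other": 0.04}
COMP_PRIMARY = {"Bcell": 0.57, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04,
                "other": 0.03, "FDC21": 0.02}
COMP_SECONDARY = {"Bcell": 0.57, "CD4T": 0.20, "CD8T": 0.14, "TFH": 0.04,
                  "other": 0.03, "FDC21_23": 0.02}
COMP_BY_MATURITY = {"early": COMP_EARLY, "mature_primary": COMP_PRIMARY,
                    "mature_secondary": COMP_SECONDARY}


def make_tls_spec(center, maturity="early", n_cells=200, radius=150.0, spacing=8.0):
    return TLSSpec(center=center, radius_um=radius, n_cells=n_cells,
                   composition=COMP_BY_MATURITY[maturity], maturity=maturity,
                   packing_spacing_um=spacing)


def random_slide_config(rng, n_tls=None, flip=0.0, field=1400.0):
    """A slide with background, a tumor nest and 0-4 well-separated planted
    aggregates of random maturity."""
    if n_tls is None:
        n_tls = int(rng.integers(0, 5))
    centers = [(280.0, 280.0), (280.0, 1120.0), (1120.0, 280.0), (1120.0, 1120.0)]
    maturities = ["early", "mature_primary", "mature_secondary"]
    specs = [make_tls_spec(centers[i], maturities[int(rng.integers(3))],
                           n_cells=int(rng.integers(120, 260)), radius=135.0)
             for i in range(n_tls)]
    bg = {"CD8T": 90.0, "CD4T": 90.0, "Bcell": 60.0, "TAM": 40.0,
          "TCF1_PD1_CD8T": 25.0, "TIM3_PD1_CD8T": 25.0, "TFH": 10.0}
    return SlideConfig(field_width_um=field, field_height_um=field,
                       background_rates=bg,
                       tumor_nests=[((700.0, 700.0), 160.0, 1200.0)],
                       tls_specs=specs, marker_flip_rate=flip,
                       seed=int(rng.integers(2**31 - 1)))


def random_cell_table(rng, n=300, field=1000.0):
    """Unstructured random cell table with random binary markers."""
    table = pd.DataFrame({
        "cell_id": [f"c{i:05d}" for i in range(n)],
        "x_um": rng.uniform(0, field, n),
        "y_um": rng.uniform(0, field, n),
    })
    for m in MARKERS:
        table[m] = rng.integers(0, 2, n)
    table.attrs["sample_id"] = "random"
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def planted_slide():
    """One mature-secondary aggregate on light background, no noise."""
    cfg = SlideConfig(
        field_width_um=1200.0, field_height_um=1200.0,
        background_rates={"CD8T": 80.0, "Bcell": 50.0, "CD4T": 80.0},
        tls_specs=[make_tls_spec((400.0, 400.0), "mature_secondary", n_cells=220)],
        seed=42)
    return simulate_slide(cfg)
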