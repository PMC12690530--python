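import numpy as np
import pandas as pd
import pytest

from ivdkit import synthetic as syn


@pytest.fixture
def two_group_design():
    return syn.GroupDesign(groups=("case", "ctrl"), n_per_group=(4, 4),
                           pseudoreplicates_per_animal=2)


@pytest.fixture
def two_block():
    return syn.two_block_structure(n_per_block=6)


@pytest.fixture
def small_panel():
    """Tiny hand-built collapsed panel: 2 cytokines, 2 groups of 3."""
    return pd.DataFrame(
        {
            "animal_id": [f"a{i}" for i in range(6)],
            "group": ["case"] * 3 + ["ctrl"] * 3,
            "replicate": [1] * 6,
            "CytA": [4.0, 5.0, 6.0, 1.0, 2.0, 3.0],
            "CytB": [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
        }
    )


@pytest.fixture
def default_phantom():
    spec = syn.DiscPhantomSpec()
    vol, masks = syn.generate_disc_volume(spec, seed=0)
    return spec, vol, masks


@pytest.fixture
def clean_trace():
    return syn.generate_loading_trace(syn.LoadingProtocol(), seed=0)


def make_trace(**kwargs):
    seed = kwargs.pop("seed", 0)
    return syn.generate_loading_trace(syn.LoadingProtocol(**kwargs), seed)


def np_scaled_phantom(np_scale: float, noise: float = 0.0) -> syn.DiscPhantomSpec:
    """Phantom whose NP is a scaled copy of the disc ellipsoid (NPVF ~ scale^3)."""
    disc = syn.Solid("ellipsoid", (31.5, 31.5, 31.5), (14.0, 26.0, 26.0))
    np_geom = syn.Solid(
        "ellipsoid", (31.5, 31.5, 31.5),
        tuple(r * np_scale for r in disc.radii),
    )
    return syn.DiscPhantomSpec(disc_geometry=disc, np_geometry=np_geom,
                               noise_sd=noise)
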