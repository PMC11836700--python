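import numpy as np
import pandas as pd
import pytest

from groupcot import energetics, trackio


@pytest.fixture(scope="session")
def flat_dem():
    """Constant-elevation grid: every slope 0, every band level."""
    dem = trackio.DemGrid(
        xll=-15000.0, yll=-15000.0, cell_size=30.0,
        elevation=np.full((1000, 1000), 500.0),
    )
    energetics.compute_slope_aspect(dem)
    return dem


@pytest.fixture
def make_straight_block():
    """Factory for a costed straight constant-speed 1 Hz block."""

    def _make(v=1.0, n=200, state=4, band=0, heading_deg=90.0):
        t = np.arange(n)
        rad = np.radians(heading_deg)
        x = v * t * np.sin(rad)
        y = v * t * np.cos(rad)
        cost = energetics.per_second_cost(
            np.full(n, state), np.full(n, float(v)), np.full(n, band)
        )
        return pd.DataFrame(
            {
                "t": t,
                "x": x,
                "y": y,
                "block": 0,
                "state": state,
                "v": float(v),
                "band": band,
                "cost": cost,
            }
        )

    return _make
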