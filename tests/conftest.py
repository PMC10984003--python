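import numpy as np
import pytest

import fibrilcg as fc


@pytest.fixture(scope="session")
def ff():
    return fc.default_forcefield()


@pytest.fixture(scope="session")
def mini7(ff):
    """7 molecules, 2 D-periods: the cheap structural fixture."""
    return fc.build_fibril(fc.FibrilLayout(n_molecules=7, n_periods=2),
                           forcefield=ff)


@pytest.fixture(scope="session")
def mini7x5(ff):
    """7 molecules, 5 D-periods: every lane has one interior gap."""
    return fc.build_fibril(fc.FibrilLayout(n_molecules=7, n_periods=5),
                           forcefield=ff)


@pytest.fixture(scope="session")
def single_mol(ff):
    return fc.build_fibril(fc.FibrilLayout(n_molecules=1, n_periods=5),
                           forcefield=ff)


@pytest.fixture(scope="session")
def reference_model(ff):
    """The nominal 200-nm-diameter fibril (155 molecules)."""
    return fc.build_fibril(fc.FibrilLayout(), forcefield=ff)


def axial_density_period(model, bin_width=2.0):
    """Independent banding-period estimate via density autocorrelation.

    Bins the collagen bead density along x, autocorrelates the
    mean-removed profile, and returns the lag of the first substantial
    local maximum.
    """
    x = model.positions[model.mol_id >= 0, 0]
    lo, hi = model.gauge_bounds()
    nbins = int((hi - lo) / bin_width)
    h, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    d = h - h.mean()
    ac = np.correlate(d, d, mode="full")[len(d) - 1:]
    ac = ac / ac[0]
    D = float(model.meta["D"])
    lag_lo = int(0.5 * D / bin_width)
    lag_hi = int(1.5 * D / bin_width)
    window = ac[lag_lo:lag_hi]
    return (lag_lo + int(np.argmax(window))) * bin_width
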