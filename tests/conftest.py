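import numpy as np
import pytest

from pi3knet.network import StimulusInput, equilibrate
from pi3knet.presets import build_parental_model, demo_ensemble, toy_pi3k_chain


@pytest.fixture(scope="session")
def parental():
    """Un-equilibrated builtin parental network model."""
    return build_parental_model()


@pytest.fixture(scope="session")
def parental_eq(parental):
    """Parental model at its growth-medium basal steady state."""
    return equilibrate(parental)


@pytest.fixture(scope="session")
def growth_medium():
    return StimulusInput("growth-medium", 1.0)


@pytest.fixture(scope="session")
def toy_chain():
    return toy_pi3k_chain()


@pytest.fixture(scope="session")
def small_ensemble(parental_eq):
    """Three-set illustrative ensemble around the demo parameterization."""
    return demo_ensemble(parental_eq, n=3, seed=0, sigma=0.03)


def rk4(f, y0, t_grid, dt):
    """Independent fixed-step RK4 oracle for small ODE systems."""
    y = np.asarray(y0, dtype=float).copy()
    t = t_grid[0]
    out = [y.copy()]
    for t_next in t_grid[1:]:
        while t < t_next - 1e-12:
            h = min(dt, t_next - t)
            k1 = np.asarray(f(t, y))
            k2 = np.asarray(f(t + h / 2, y + h / 2 * k1))
            k3 = np.asarray(f(t + h / 2, y + h / 2 * k2))
            k4 = np.asarray(f(t + h, y + h * k3))
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(y.copy())
        t = t_next
    return np.array(out).T
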