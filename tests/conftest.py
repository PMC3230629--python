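import math

import numpy as np
import pytest

from fluxcomp import CompetitionState


def round_sig(x: float, sig: int = 2) -> float:
    """Round to a number of significant figures (for printed-precision checks)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@pytest.fixture
def sigma_state() -> CompetitionState:
    """Measured exponential-phase sigma-factor competition state.

    700 RNAP molecules/cell with no free enzyme; bound/total amounts
    545/700 for the housekeeping factor, 100/370 and 55/110 for the
    flagellar and nitrogen factors.
    """
    return CompetitionState(
        T=700.0,
        C=[700.0, 370.0, 110.0],
        tc=[545.0, 100.0, 55.0],
        labels=("s70", "s28", "s54"),
    )


def random_states(rng: np.random.Generator, n_states: int, n_max: int = 5):
    """Random valid competition states (free target fraction varies)."""
    out = []
    for _ in range(n_states):
        n = int(rng.integers(1, n_max + 1))
        C = rng.uniform(0.5, 1000.0, n)
        s = rng.uniform(0.0, 0.98, n)
        tc = C * s
        T = tc.sum() * (1.0 + rng.uniform(0.0, 2.0)) + rng.uniform(1e-6, 10.0)
        out.append(CompetitionState(T=T, C=C, tc=tc))
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211205)
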