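import numpy as np
import pytest

from randlv import GenParams, generate_chen_cohen, solve_equilibrium


@pytest.fixture
def feasible_community():
    """Factory: rejection-sample one feasible Chen-Cohen community."""

    def make(
        n=8,
        P=0.5,
        C=0.7,
        sigma=0.02,
        background="exploitative",
        seed=0,
        max_draws=500,
    ):
        rng = np.random.default_rng(seed)
        for _ in range(max_draws):
            params = GenParams(
                n=n, P=P, C=C, sigma=sigma, background=background,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            im = generate_chen_cohen(params)
            eq = solve_equilibrium(im)
            if eq.feasible:
                return im, eq
        raise RuntimeError("no feasible draw found")

    return make
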