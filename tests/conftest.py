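import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from disct2.phantom import DiscSpec, GradeParams, PhantomSpec, build_phantom

#: grade table with sharp NP/AF boundaries (no blend zone) for exact-recovery tests
SHARP_GRADE_PARAMS = {
    g: GradeParams(np_t2=t2, af_t2=45.0, np_radius=0.6, blend=0.0)
    for g, t2 in {1: 120.0, 2: 100.0, 3: 80.0, 4: 60.0, 5: 50.0}.items()
}


def single_disc_spec(grade: int = 2, hiz: bool = False, noise_sigma: float = 0.0,
                     seed: int = 0, sharp: bool = True, **kwargs) -> PhantomSpec:
    params = dict(SHARP_GRADE_PARAMS) if sharp else None
    extra = {"grade_params": params} if params is not None else {}
    extra.update(kwargs)
    return PhantomSpec(
        shape=(3, 40, 56),
        discs=(DiscSpec("L4-L5", (20.0, 28.0), (5.5, 16.0), grade, hiz=hiz),),
        noise_sigma=noise_sigma,
        seed=seed,
        **extra,
    )


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free single-disc phantom with sharp compartments (grade 2)."""
    return build_phantom(single_disc_spec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """Single-disc phantom at Rician sigma 2."""
    return build_phantom(single_disc_spec(noise_sigma=2.0, seed=7))


@pytest.fixture(scope="session")
def hiz_phantom():
    """Noise-free grade-3 disc carrying an HIZ."""
    return build_phantom(single_disc_spec(grade=3, hiz=True))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
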