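import numpy as np
import pytest

from luvkit import GaussianShellProfile, HollowSphereModel
from luvkit.synth import LIP0_MALS, LIP0_SAXS, LIPCAS_MALS, LIPCAS_SAXS


@pytest.fixture
def lip0_profile() -> GaussianShellProfile:
    """Bare-vesicle SAXS geometry: R = 46 nm, d = 3.9 nm."""
    return LIP0_SAXS


@pytest.fixture
def lipcas_profile() -> GaussianShellProfile:
    """Protein-loaded vesicle SAXS geometry: R = 52 nm, d = 3.9 nm."""
    return LIPCAS_SAXS


@pytest.fixture
def lip0_shell() -> HollowSphereModel:
    return LIP0_MALS


@pytest.fixture
def lipcas_shell() -> HollowSphereModel:
    return LIPCAS_MALS


@pytest.fixture
def perturbed_init():
    """Factory: multiplicatively perturb a profile's parameters by
    +/-20% with a seeded generator (the standard hard-start for fits)."""

    def _make(profile: GaussianShellProfile, seed: int = 1) -> GaussianShellProfile:
        rng = np.random.default_rng(seed)

        def p(v: float) -> float:
            return v * (1.0 + rng.uniform(-0.2, 0.2))

        (_, _, s1), (r2, e2, s2), (r3, e3, s3) = profile.components
        return GaussianShellProfile(
            R=p(profile.R),
            components=(
                (1.0, 0.0, p(s1)),
                (p(r2), p(e2), p(s2)),
                (p(r3), p(e3), p(s3)),
            ),
        )

    return _make
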