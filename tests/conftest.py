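import numpy as np
import pytest

from rdcsampler.structure_io import (build_amide_protons, build_virtual_ha,
                                     extract_rdc_vectors)
from rdcsampler.synthetic import (default_tensor_components, make_helix,
                                  synth_targets)


@pytest.fixture(scope="session")
def helix30():
    """30-residue ideal alpha-helix with H and HA built."""
    return build_virtual_ha(build_amide_protons(make_helix(30)))


@pytest.fixture(scope="session")
def clean_targets(helix30):
    """Noise-free targets of all four bond classes from the default tensor."""
    return synth_targets(make_helix(30), default_tensor_components(), sigma=0.0)


@pytest.fixture(scope="session")
def clean_vectors(helix30, clean_targets):
    return extract_rdc_vectors(helix30, clean_targets)


@pytest.fixture()
def restrained_targets(clean_targets):
    """Copy of the clean targets with N-H and CA-HA restrained."""
    out = []
    for t in clean_targets:
        c = type(t)(t.residue, t.bond_class, t.d0,
                    restrained=t.bond_class in ("N-HN", "CA-HA"),
                    provenance=t.provenance)
        out.append(c)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
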