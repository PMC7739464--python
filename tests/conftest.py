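import numpy as np
import pytest
from random import Random

import medseal as ms


@pytest.fixture(scope="session")
def keypair():
    """One reproducible RSA pair for the whole run (keygen is the slow bit)."""
    return ms.generate_keypair(bits=1024, seed=11)


@pytest.fixture(scope="session")
def basic_info():
    return ms.BasicInfo(hospital="union hospital",
                        department="internal medicine",
                        doctor_number="526", patient_number="10,256",
                        shooting_time="9/6", contact_number="5628***",
                        image_type="brain CT")


@pytest.fixture(scope="session")
def phantom1():
    return ms.generate_phantom(ms.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def suite20():
    """Twenty varied phantoms, the standard evaluation population."""
    return ms.generate_suite(20, base_seed=1)


@pytest.fixture(scope="session")
def encrypted20(suite20, keypair, basic_info):
    """The suite encrypted with defaults, paired with the originals."""
    pub, _ = keypair
    out = []
    for i, img in enumerate(suite20):
        res = ms.encrypt(img, basic_info, pub, rng=Random(1000 + i))
        out.append((img, res))
    return out


def rng_image(seed: int, shape=(64, 64)) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 256, shape).astype(np.uint8)
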