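import numpy as np
import pytest
from hypothesis import settings

import phosphobind as pb

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def noiseless_fa_design():
    return pb.FAPlateDesign(noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def single_site_plate(noiseless_fa_design):
    """Noiseless single-site FA plate at the tight hDMX pSer367 affinity."""
    return pb.gen_fa_titration(noiseless_fa_design, pb.SingleSite(kd=98.8e-9))


@pytest.fixture(scope="session")
def two_event_plate(noiseless_fa_design):
    """Noiseless biphasic FA plate at tandem-peptide stepwise affinities."""
    return pb.gen_fa_titration(noiseless_fa_design, pb.TwoEvent(kd1=30e-9, kd2=10.7e-6))


@pytest.fixture(scope="session")
def pser367_peptide():
    return pb.parse_phosphopeptide("Ac-DCRRTIpSAPVVRPK-NH2", id="hDMX_361-374",
                                   protein_offset=361)


def relative_error(value, truth):
    return abs(value - truth) / abs(truth)


@pytest.fixture(scope="session")
def rel():
    return relative_error
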