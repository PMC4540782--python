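import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from auronekit import (  # noqa: E402
    Chain,
    ProteoformHypothesis,
    SYNTHETIC_AUS1_MATURE,
    CORE_END,
    PEPTIDE_SPAN,
    MATURE_END,
)


@pytest.fixture(scope="session")
def standin():
    """Chains of the synthetic stand-in sequence in mature numbering."""
    seq = SYNTHETIC_AUS1_MATURE
    return {
        "sequence": seq,
        "core": Chain("core", seq[:CORE_END], 1, CORE_END),
        "peptide": Chain("peptide", seq[PEPTIDE_SPAN[0] - 1:PEPTIDE_SPAN[1]],
                         PEPTIDE_SPAN[0], PEPTIDE_SPAN[1]),
        "latent": Chain("latent", seq, 1, MATURE_END),
        "latent_minus_ala": Chain("latent-A", seq[:MATURE_END - 1], 1,
                                  MATURE_END - 1),
    }


@pytest.fixture(scope="session")
def standin_species(standin):
    """The four intact proteoform hypotheses of the reference experiment."""
    return {
        "A": ProteoformHypothesis((standin["core"], standin["peptide"]),
                                  n_disulfide=3, n_thioether=1),
        "C": ProteoformHypothesis((standin["core"],), n_disulfide=2,
                                  n_thioether=1, condition="reducing"),
        "F": ProteoformHypothesis((standin["latent"],), n_disulfide=3,
                                  n_thioether=1),
        "G": ProteoformHypothesis((standin["latent_minus_ala"],),
                                  n_disulfide=3, n_thioether=1),
    }
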