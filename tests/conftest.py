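import numpy as np
import pytest

from combindex import AgentTruth, MedianEffectResults, MixtureDesign


@pytest.fixture
def ratio_design() -> MixtureDesign:
    """The 1:20 (w/w) extract-in-carrier loading used throughout."""
    return MixtureDesign.from_ratio("carrier", "extract", 20, 1)


@pytest.fixture
def carrier_truth() -> AgentTruth:
    return AgentTruth(m_true=1.5, ic50_true=50.0)


@pytest.fixture
def extract_truth() -> AgentTruth:
    return AgentTruth(m_true=1.5, ic50_true=0.45)


def median_effect_fit(m: float, ic50: float, agent_id: str = "agent") -> MedianEffectResults:
    """Exact median-effect results with slope m and the given IC50."""
    return MedianEffectResults(
        agent_id=agent_id, m=m, n=-m * np.log10(ic50), r_squared=1.0, n_used=8, n_excluded=0
    )
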