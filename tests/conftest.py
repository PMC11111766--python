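import numpy as np
import pytest

from netstates.types import ComponentTimecourses


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tc(data, tr=2.0, subject_id="sub01"):
    """Wrap a raw matrix in a ComponentTimecourses with generic labels."""
    data = np.asarray(data, float)
    C = data.shape[1]
    labels = [f"IC{i + 1:02d}" for i in range(C)]
    nets = ("DMN", "VN", "SMN", "LFPN", "RFPN", "DAN", "VAN", "AN")
    nmap = {lab: nets[i % len(nets)] for i, lab in enumerate(labels)}
    return ComponentTimecourses(subject_id=subject_id, data=data,
                                tr_seconds=tr, component_labels=labels,
                                network_map=nmap)


@pytest.fixture
def small_cohort():
    """A fast synthetic cohort: 10+10 subjects, C=6, T=120."""
    from netstates import synth
    spec = synth.CohortSpec(n_patients=10, n_controls=10, n_components=6,
                            n_timepoints=120, min_window_length=30, seed=42)
    return synth.simulate_cohort(spec) + (spec,)
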