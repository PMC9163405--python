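import numpy as np
import pytest

from dynfc import SynthSpec
from dynfc.simulate import ground_truth_window_labels, simulate_cohort
from dynfc.windows import GlassoConfig, TaperedWindowSpec, dynamic_fc


@pytest.fixture(scope="session")
def default_spec() -> SynthSpec:
    return SynthSpec()


@pytest.fixture(scope="session")
def small_cohort(default_spec):
    """24-subject cohort (8 per group) with unpenalized windowed FC and truth labels."""
    tcs, cov, gts = simulate_cohort(default_spec, {"HD": 8, "NonD": 8, "HC": 8},
                                    seed=3)
    wspec = TaperedWindowSpec()
    gcfg = GlassoConfig(penalty_grid=[0.0])
    stacks = [dynamic_fc(tc, wspec, gcfg, seed=0) for tc in tcs]
    truth = np.concatenate([ground_truth_window_labels(g, wspec.window_length_tr)
                            for g in gts])
    return {"timecourses": tcs, "covariates": cov, "ground_truths": gts,
            "stacks": stacks, "truth_labels": truth}
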