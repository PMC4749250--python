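import numpy as np
import pytest

from admixsel.model import ModelConfig, fit
from admixsel.simulate import SimConfig, simulate_study

# Desk-scale study shared by the inference tests: one simulation and one
# supervised fit are expensive, so they are computed once per session. The
# neutral cohort at the documented reduced scale (5,000-haplotype pool,
# 600 markers, 200 diplotypes) exercises the model under the same marker
# density the recovery checks use.


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(SimConfig.reduced(seed=11, selection_coefficient=0.0))


@pytest.fixture(scope="session")
def small_fit(small_study):
    cfg = ModelConfig(em_runs=3, em_steps=12, seed=5)
    return fit(small_study.training, small_study.cohort.panel(), cfg)


@pytest.fixture(scope="session")
def neutral_cohorts():
    """Twenty neutral replicates (truth dosages only; no inference needed)."""
    out = []
    for rep in range(20):
        cfg = SimConfig(n_pool=5000, snp_density=100.0, n_cohort_diplotypes=120,
                        n_panel_haps_per_pop=260, n_training_haps_per_pop=60,
                        selection_coefficient=0.0, seed=1000 + rep)
        out.append(simulate_study(cfg).cohort)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# End-to-end pipeline runs (shared: they are the expensive fixtures).

def _pipeline_report(tmp_path_factory, s):
    from admixsel.pipeline import PipelineConfig, run_pipeline
    out = tmp_path_factory.mktemp(f"pipe_s{s}")
    cfg = PipelineConfig(sim=SimConfig.reduced(selection_coefficient=s),
                         model=ModelConfig(em_runs=3, em_steps=15),
                         seed=0, outdir=str(out))
    return run_pipeline(cfg), out


@pytest.fixture(scope="session")
def pipeline_selected(tmp_path_factory):
    return _pipeline_report(tmp_path_factory, 0.05)


@pytest.fixture(scope="session")
def pipeline_neutral(tmp_path_factory):
    return _pipeline_report(tmp_path_factory, 0.0)
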