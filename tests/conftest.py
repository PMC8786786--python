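import pytest

from aglscan.pipeline import PipelineConfig, run_pipeline
from aglscan.synth import SynthSpec, make_cohort, truth_signal_annotations


@pytest.fixture(scope="session")
def cohort():
    """Noise-free synthetic cohort: 3 planted AGL genes + 7 decoys."""
    spec = SynthSpec(seed=11)
    genes, decoys = make_cohort(spec, n_agl=3)
    return spec, genes, decoys


@pytest.fixture(scope="session")
def cohort_reports(cohort):
    """Pipeline output on the cohort transcripts with truth signal imports."""
    _, genes, decoys = cohort
    cfg = PipelineConfig(
        records=[g.transcript for g in genes] + decoys,
        signals=truth_signal_annotations(genes),
        use_heuristic_signals=False,
    )
    return run_pipeline(cfg)
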