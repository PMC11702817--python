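"""Shared configuration for the numbered analysis scripts.

One synthetic study: a 50,000-pregnancy nulliparous cohort sampled from
the calibrated truth network, with EFW and visit-2 blood-pressure
missingness injected.  The cohort is larger than the real study's 9,558
because several planted effects (the sex-by-diabetes interaction at a
1.6% diabetes prevalence in particular) are only learnable from data at
that scale; the generator's marginals are unchanged.  All scripts write
under results/analysis/.
"""
from contextrisk.pipeline import PipelineConfig


def analysis_config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.output_dir = "results/analysis"
    cfg.n = 50_000
    cfg.bootstrap_b = 200
    cfg.folds = 5
    return cfg
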