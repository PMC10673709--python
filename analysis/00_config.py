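"""Shared run configuration for the numbered analysis drivers.

One seeded run directory under results/ so each driver can be re-run
independently from the persisted intermediates of the previous one.
"""

from droughtflux import pipeline

SEED = 1
OUTDIR = "results/run"


def config() -> pipeline.RunConfig:
    cfg = pipeline.RunConfig(seed=SEED, outdir=OUTDIR)
    cfg.effect.seed = SEED
    return cfg
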