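"""Shared run configuration for the numbered analysis scripts.

All scripts share one output directory (results/run) so each stage reuses
the previous scripts' products; delete the directory to start fresh.
"""

from pathlib import Path

from cropsuit.pipeline import PipelineConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def study_config(seed: int = 42) -> PipelineConfig:
    """The study conditions: 6 registry crops, 10 members, 0.5-degree grid."""
    return PipelineConfig(outdir=str(RESULTS / "run"), seed=seed)
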