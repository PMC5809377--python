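"""Shared configuration of the analysis runs.

All drivers regenerate the same deterministic input bundle (seed 42,
0.5-degree India grid, 1000 exposure-response draws) through the library,
so each script can be run independently and in any order.
"""

from pathlib import Path

from pm25burden.pipeline import RunConfig, generate_inputs

SEED = 42
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "analysis_run"


def run_config(**overrides) -> RunConfig:
    base = dict(seed=SEED, n_lat=60, n_lon=60, n_draws=1000)
    base.update(overrides)
    return RunConfig(**base)


def get_bundle(**overrides):
    return generate_inputs(run_config(**overrides))


def ensure_dirs() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)
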