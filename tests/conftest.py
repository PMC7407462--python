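import numpy as np
import pytest

from gapfill.study import default_config, run_study
from gapfill.synthetic_data import SimulationConfig, build_reference_and_donors


def rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=n)].astype(str))


def small_config(seed: int = 3) -> SimulationConfig:
    """A reduced cohort for unit tests: 12 gaps, 3 donors, 12 samples."""
    return SimulationConfig(
        seed=seed,
        n_chromosomes=2,
        chrom_length_bp=60_000,
        n_gaps={
            "within_scaffold": 6,
            "between_scaffolds": 2,
            "telomere": 2,
            "heterochromatin": 1,
            "short_arm": 1,
        },
        fill_length_max=4_000,
        n_assemblies=3,
        n_samples=12,
        populations={"POP1": 4, "POP2": 4, "POP3": 4},
    )


@pytest.fixture(scope="session")
def small_bundle():
    return build_reference_and_donors(small_config())


@pytest.fixture(scope="session")
def study_results():
    """The full pipeline on the default study conditions (40 gaps, 5 donors)."""
    return run_study(default_config(seed=1))
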