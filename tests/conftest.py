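import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pabscan import simulate as sim

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_arch() -> sim.ChromosomeArchitecture:
    """2 Mb chromosome: 0.8 Mb PAR, 1.0 Mb old stratum, 0.2 Mb recent stratum."""
    return sim.ChromosomeArchitecture(
        length=2_000_000,
        segments=[
            sim.ArchSegment(0, 800_000, sim.PAR),
            sim.ArchSegment(800_000, 1_800_000, sim.OLD_STRATUM),
            sim.ArchSegment(1_800_000, 2_000_000, sim.RECENT_STRATUM),
        ],
        reference_autosome_length=500_000,
    )


@pytest.fixture
def insert_arch() -> sim.ChromosomeArchitecture:
    """Architecture with an autosomal-contaminant island inside the X-specific zone."""
    return sim.ChromosomeArchitecture(
        length=3_000_000,
        segments=[
            sim.ArchSegment(0, 800_000, sim.PAR),
            sim.ArchSegment(800_000, 1_600_000, sim.OLD_STRATUM),
            sim.ArchSegment(1_600_000, 1_900_000, sim.AUTOSOMAL_INSERT),
            sim.ArchSegment(1_900_000, 3_000_000, sim.OLD_STRATUM),
        ],
        reference_autosome_length=500_000,
    )


@pytest.fixture
def sim_cfg() -> sim.SimulationConfig:
    return sim.SimulationConfig(seed=7)


def random_binary_newick(n_tips: int, rng: np.random.Generator) -> str:
    """Random rooted binary tree with uniform(0.5, 2.0) branch lengths."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(tips: list[str]) -> str:
        if len(tips) == 1:
            return tips[0]
        k = int(rng.integers(1, len(tips)))
        left, right = build(tips[:k]), build(tips[k:])
        bl_l, bl_r = rng.uniform(0.5, 2.0, size=2)
        return f"({left}:{bl_l:.6f},{right}:{bl_r:.6f})"

    return build(labels) + ";"
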