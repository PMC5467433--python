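import numpy as np
import pytest

from omicnet import BlockSpec, OmicsBlock, PlantedPair, SimConfig, generate_blocks


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def toy_block():
    """12 samples in 3 diet groups, 6 features, strictly positive values."""
    gen = np.random.default_rng(123)
    values = np.exp2(gen.normal(5, 1, size=(6, 12)))
    samples = [f"s{j}" for j in range(12)]
    groups = {s: ["soy", "casein", "whey"][j // 4] for j, s in enumerate(samples)}
    return OmicsBlock(
        values=values,
        feature_ids=[f"f{i}" for i in range(6)],
        sample_ids=samples,
        data_type="toy",
        groups=groups,
        reference_group="soy",
    )


@pytest.fixture
def planted_pair_config():
    """Two-block design with 10 planted cross-block edges at |r| = 0.85.

    The blocks emulate the *post-screen* stage of the analysis: features
    entering integration passed a differential screen, so most of them
    (80% here) respond to diet and carry the correlated group structure
    the integration expects.
    """

    def make(seed: int) -> SimConfig:
        return SimConfig(
            block_specs=[
                BlockSpec("metabolomics_serum", 24, 30, responsive_fraction=0.8),
                BlockSpec("transcriptomics", 30, 30, responsive_fraction=0.8),
            ],
            planted_pairs=[
                PlantedPair(
                    "metabolomics_serum",
                    i,
                    "transcriptomics",
                    i,
                    0.85 if i < 5 else -0.85,
                )
                for i in range(10)
            ],
            effect_size=2.0,
            seed=seed,
        )

    return make


@pytest.fixture
def planted_blocks(planted_pair_config):
    """Log-scale blocks plus the planted edge set for one fixed seed."""
    from omicnet import log_transform

    blocks, truth = generate_blocks(planted_pair_config(3))
    return [log_transform(b) for b in blocks], truth
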