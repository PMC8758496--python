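import numpy as np
import pandas as pd
import pytest

from mirconverge.synthetic import PlantedGene, SynthConfig


@pytest.fixture
def small_screen():
    """Tiny screen table with known ranks and no ties."""
    rng = np.random.default_rng(11)
    ids = [f"m{i:03d}" for i in range(100)]
    return pd.DataFrame({"entity_id": ids, "score": rng.standard_normal(100)})


@pytest.fixture
def planted_config():
    """Small universe with one strongly convergent planted gene."""
    return SynthConfig(
        n_mirna=300,
        n_gene=60,
        n_algorithms=6,
        base_call_prob=0.02,
        agreement=0.75,
        consensus_min=4,
        n_sirna_hits=20,
        planted_genes=(
            PlantedGene("GENE01", binder_count=8, candidate_overlap=6),
            PlantedGene("GENE02", binder_count=40, candidate_overlap=1),
            PlantedGene("GENE03", binder_count=25, candidate_overlap=2),
        ),
        n_planted_top=4,
        n_planted_bottom=4,
        planted_shift=10.0,
        rng_seed=17,
    )
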