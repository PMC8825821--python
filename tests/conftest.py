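import numpy as np
import pytest

from smapkit.io_formats import AA, AB, BB, GenotypeMatrix, PeptideRow, QuantBatch
from smapkit.simulation import IntensityParams, SimulationConfig, generate_genotype_matrix


@pytest.fixture
def small_panel() -> GenotypeMatrix:
    """5 samples x 6 SNPs with all three classes represented."""
    calls = np.array(
        [
            [AA, AB, BB, AA, AB, AA],
            [AB, AA, BB, AB, AA, AA],
            [BB, AB, AA, AA, BB, AB],
            [AA, BB, AB, BB, AB, AA],
            [AB, AA, AA, AB, BB, BB],
        ],
        dtype=np.int8,
    )
    snps = [f"chr1:{100 + i}:A:G" for i in range(6)]
    return GenotypeMatrix([f"S{i}" for i in range(1, 6)], snps, calls)


@pytest.fixture
def hwe_panel() -> GenotypeMatrix:
    return generate_genotype_matrix(
        SimulationConfig(n_samples=40, n_snps=300, seed=11)
    )


def make_noiseless_panel(n_samples=10, n_snps=60, seed=5) -> GenotypeMatrix:
    """Panel where every SNP carries exactly 3 AA, 5 AB and 2 BB calls.

    With these counts the empirical quartiles of noiseless scaled
    intensities fall strictly between the class levels 0 / 0.5 / 1, so
    quartile inference reproduces the generating genotypes exactly.
    """
    rng = np.random.default_rng(seed)
    base = np.array([AA] * 3 + [AB] * 5 + [BB] * 2, dtype=np.int8)
    calls = np.stack([rng.permutation(base) for _ in range(n_snps)], axis=1)
    snps = [f"chr2:{1000 + i}:C:T" for i in range(n_snps)]
    return GenotypeMatrix([f"N{i:02d}" for i in range(n_samples)], snps, calls)


@pytest.fixture
def noiseless_panel() -> GenotypeMatrix:
    return make_noiseless_panel()


NOISELESS_PARAMS = IntensityParams(sd_noise=0.0, sd_signal=0.0)


@pytest.fixture
def tiny_batch() -> QuantBatch:
    peptides = [
        PeptideRow("AAELK", "chr1:100:A:G", 2),
        PeptideRow("TTIR", "chr1:101:A:G", 1),
    ]
    intensities = np.array([[100.0, 200.0, 400.0], [50.0, np.nan, 150.0]])
    return QuantBatch(
        batch_id="b1",
        peptides=peptides,
        channels=["126", "127", "131"],
        intensities=intensities,
        manifest={"126": "S1", "127": "S2", "131": "CONTROL"},
        control_channels={"131"},
    )
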