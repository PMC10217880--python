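import numpy as np
import pytest

from mutscan import SyntheticCohortConfig, generate_synthetic_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """40 genes, no class signal beyond 2 point mutations each."""
    cfg = SyntheticCohortConfig(n_genes=40, seed=7)
    return generate_synthetic_cohort(cfg)


@pytest.fixture(scope="session")
def signal_cohort():
    """60 genes with a fully penetrant motif signal (separable classes)."""
    cfg = SyntheticCohortConfig(
        n_genes=60, signal_mode="motif", signal_strength=1.0, seed=7
    )
    return generate_synthetic_cohort(cfg)


@pytest.fixture
def fasta_file(tmp_path):
    def _write(records, name="test.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{h}\n{s}\n" for h, s in records))
        return path

    return _write
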