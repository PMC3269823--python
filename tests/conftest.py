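import numpy as np
import pytest

from chdrisk import GenotypeMatrix, SnpEffect, SnpPanel, default_panel


@pytest.fixture(scope="session")
def panel() -> SnpPanel:
    """The packaged 12-SNP CHD susceptibility panel (11 usable)."""
    return default_panel()


@pytest.fixture()
def toy_panel() -> SnpPanel:
    """Two-SNP panel with easy hand arithmetic (ORs 2 and 4, p=0.5)."""
    return SnpPanel(
        (
            SnpEffect("rsA", "1", "GENEA", "A", 2.0, 1.5, 2.5, 0.5, 0.5),
            SnpEffect("rsB", "2", "GENEB", "C", 4.0, 3.0, 5.0, 0.5, 0.5),
        )
    )


@pytest.fixture()
def toy_genotypes(toy_panel) -> GenotypeMatrix:
    return GenotypeMatrix(
        ["i1", "i2", "i3"],
        ["rsA", "rsB"],
        np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0]]),
    )
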