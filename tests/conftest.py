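import numpy as np
import pytest

from eqtlscan import CovariateMatrix, SimConfig, simulate_panel

TOY_GENO = """\
@type:riset
# toy two-chromosome panel
Chr\tLocus\tcM\tBXD1\tBXD2\tBXD3\tBXD4
1\tm1\t0\tB\tD\tB\tD
1\tm2\t10\tB\tD\tD\tD
2\tm3\t0\tD\tB\tB\tB
"""


@pytest.fixture
def toy_geno_path(tmp_path):
    path = tmp_path / "toy.geno"
    path.write_text(TOY_GENO)
    return path


@pytest.fixture(scope="session")
def small_panel():
    """80 strains, 2 chromosomes at 5 cM spacing, 30 traits (h2 = 0.4)."""
    cfg = SimConfig(
        n_strains=80, n_chromosomes=2, chr_length_cM=100.0,
        marker_spacing_cM=5.0, n_traits=30, prop_with_qtl=0.4, h2=0.4, seed=5,
    )
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def standard_panel():
    """The default simulated panel: 80 strains, 20 x 100 cM map at 2 cM,
    1000 traits, 30% with a planted eQTL at h2 = 0.4."""
    return simulate_panel(SimConfig())


@pytest.fixture(scope="session")
def two_covariates():
    """Intercept + two random covariates for an 80-strain panel."""
    rng = np.random.default_rng(99)

    def build(strain_ids):
        n = len(strain_ids)
        return CovariateMatrix(
            np.column_stack([np.ones(n), rng.standard_normal((n, 2))]),
            strain_ids,
            ["intercept", "cov_a", "cov_b"],
        )

    return build
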