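import numpy as np
import pytest

from sporevar.coverage import REPLICATES, STRAINS, CoverageBundle, CoverageProfile
from sporevar.simulate import SyntheticConfig, write_simulation


def make_bundle(gene_id="geneX", counts_by_sample=None, length=10, adjusted=False):
    """Bundle with explicit per-sample count vectors (default: constant 5s)."""
    profiles = []
    for strain in STRAINS:
        for rep in REPLICATES:
            key = f"{strain}_r{rep}"
            counts = (
                counts_by_sample[key]
                if counts_by_sample and key in counts_by_sample
                else np.full(length, 5.0)
            )
            profiles.append(
                CoverageProfile(gene_id, strain, rep, np.asarray(counts, float),
                                adjusted=adjusted)
            )
    return CoverageBundle(gene_id=gene_id, profiles=tuple(profiles))


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(seed=3, n_genes=12, gene_length_range=(400, 800))


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory, small_config):
    """A full synthetic input directory shared across tests."""
    d = tmp_path_factory.mktemp("sim") / "inputs"
    write_simulation(small_config, d)
    return d
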