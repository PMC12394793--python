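import numpy as np
import pytest

from lipopept.chem import Peptidoform, default_registry, registry_lookup


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def palmitoyl():
    return registry_lookup("palmitoyl")


@pytest.fixture(scope="session")
def stearoyl():
    return registry_lookup("stearoyl")


_AA = "ACDEFGHIKLMNPQRSTVWY"


def random_peptidoform(rng: np.random.Generator, min_len: int = 5,
                       max_len: int = 20, with_mod_probability: float = 0.5) -> Peptidoform:
    """A random peptide, optionally with one acyl modification on a Cys."""
    n = int(rng.integers(min_len, max_len + 1))
    sequence = "".join(rng.choice(list(_AA), size=n))
    mods = ()
    if rng.random() < with_mod_probability:
        cys = [i + 1 for i, aa in enumerate(sequence) if aa == "C"]
        if not cys:
            pos = int(rng.integers(1, n + 1))
            sequence = sequence[:pos - 1] + "C" + sequence[pos:]
            cys = [pos]
        mod_name = str(rng.choice(["palmitoyl", "myristoyl", "stearoyl",
                                   "farnesyl", "geranylgeranyl"]))
        mods = ((int(rng.choice(cys)), registry_lookup(mod_name)),)
    return Peptidoform(sequence, mods)


@pytest.fixture
def peptidoform_factory():
    return random_peptidoform


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The synthetic bundle (FASTA + planted/noise spectra + manifest)."""
    from lipopept.simulate import write_fixture_files

    out = tmp_path_factory.mktemp("bundle")
    manifest = write_fixture_files(out, seed=11)
    manifest["dir"] = out
    return manifest
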