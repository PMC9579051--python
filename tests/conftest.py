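from pathlib import Path

import pytest
from hypothesis import settings

from photosys.io import parse_structure
from photosys.synth import SyntheticSpec, generate_dimer, generate_monomer

settings.register_profile("suite", max_examples=25, derandomize=True,
                          deadline=None)
settings.load_profile("suite")

#: directory for optional reference depositions (7ZQD.cif etc.); the
#: download-dependent checks run only when these files have been fetched.
DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def monomer_fixture(tmp_path_factory):
    """(path, manifest, model) for the default synthetic monomer."""
    out = tmp_path_factory.mktemp("synth") / "monomer.cif"
    path, manifest = generate_monomer(SyntheticSpec(seed=11), out)
    return path, manifest, parse_structure(path)


@pytest.fixture(scope="session")
def dimer_fixture(tmp_path_factory):
    """(path, manifest, model) for the default synthetic C2 dimer."""
    out = tmp_path_factory.mktemp("synth") / "dimer.cif"
    path, manifest = generate_dimer(SyntheticSpec(seed=11), out)
    return path, manifest, parse_structure(path)


@pytest.fixture
def dimer_groups(dimer_fixture):
    _, manifest, model = dimer_fixture
    grouping = manifest["grouping"]
    res = {g: [r for c in model.chains if grouping[c.chain_id] == g
               for r in c.residues] for g in ("M1", "M2")}
    return model, grouping, res["M1"], res["M2"]


def site_str(residue) -> str:
    return f"{residue.chain_id}:{residue.comp_code}:{residue.auth_seq_id}"
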