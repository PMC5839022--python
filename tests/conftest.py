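import json
from pathlib import Path

import pytest
from hypothesis import settings

from trioseg import io as tio
from trioseg.reference_data import make_reference_fixtures

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    """Bundled reference fixtures, generated once per session."""
    outdir = tmp_path_factory.mktemp("reference_fixtures")
    make_reference_fixtures(outdir)
    return outdir


@pytest.fixture(scope="session")
def fixture_paths(fixture_dir):
    # regenerating is cheap and keeps paths consistent with fixture_dir
    return make_reference_fixtures(fixture_dir)


@pytest.fixture(scope="session")
def manifest(fixture_dir):
    return json.loads((fixture_dir / "manifest.json").read_text())


@pytest.fixture(scope="session")
def trios(fixture_dir):
    return tio.read_pedigree(fixture_dir / "trios.ped")


def load_fixture_records(paths, trios):
    """Read one fixture's VCF with its score side table applied."""
    table = tio.read_score_table(paths["scores"])
    return list(tio.read_trio_vcf(paths["vcf"], trios, score_table=table))
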