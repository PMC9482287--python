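import pytest

from organellekit import gene_content as gc
from organellekit import synthetic_data as syn
from organellekit import transfer_detection as td

SEED = 1


@pytest.fixture(scope="session")
def spec():
    return syn.FixtureSpec(seed=SEED)


@pytest.fixture(scope="session")
def reference(spec):
    return syn.make_reference_catalog(spec.seed, length_overrides=spec.gene_lengths)


@pytest.fixture(scope="session")
def plastome(spec):
    return syn.make_plastome_fixture(spec)


@pytest.fixture(scope="session")
def classified(plastome, reference):
    _, catalog = plastome
    return gc.classify_catalog(catalog, reference)


@pytest.fixture(scope="session")
def mitogenome(spec):
    return syn.make_mitogenome_fixture(spec)


@pytest.fixture(scope="session")
def transfer_fragments(spec, mitogenome, reference):
    sequences, _, _ = mitogenome
    hits = td.scan_homology(sequences, reference)
    return td.fragments_from_hits(
        hits, sequences, reference, replicon_order=[c[0] for c in spec.chromosomes]
    )
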