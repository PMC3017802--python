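import pytest

import organellarch as oa


@pytest.fixture(scope="session")
def mt_genome():
    """Mitochondrial-style synthetic genome (28.3 kb, 12 genes, 18 introns,
    18 palindrome clusters), fixed seed."""
    return oa.generate_genome(oa.mt_like_spec(seed=2))


@pytest.fixture(scope="session")
def pt_genome():
    """Plastid-style synthetic genome (269 kb, 102 genes, 14.4 kb IR)."""
    return oa.generate_genome(oa.pt_like_spec(seed=3))


@pytest.fixture()
def toy():
    return oa.toy_fixture()
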