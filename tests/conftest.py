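import pytest

from helpers import build_tax


@pytest.fixture
def ladder_tax():
    """root -> phylum -> genus -> species -> strain ladder."""
    return build_tax(
        [
            (1, 1, "root", "root"),
            (2, 1, "phylum", "P"),
            (3, 2, "genus", "G"),
            (4, 3, "species", "S"),
            (5, 4, "strain", "T"),
        ]
    )


@pytest.fixture
def forked_tax():
    """root -> (A -> {a1, a2}, B -> {b1}), genus/species ranks."""
    return build_tax(
        [
            (1, 1, "root", "root"),
            (2, 1, "genus", "A"),
            (3, 1, "genus", "B"),
            (4, 2, "species", "a1"),
            (5, 2, "species", "a2"),
            (6, 3, "species", "b1"),
        ]
    )
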