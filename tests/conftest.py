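"""Shared fixtures: small hand-built trees and seeded random generators."""

import pytest

from phyloconcord.treeio import parse_newick


@pytest.fixture
def quartet():
    return parse_newick("((A,B)95,(C,D)87);")


@pytest.fixture
def six_tip_binary():
    return parse_newick("(((A,B),(C,D)),(E,F));")


@pytest.fixture
def star6():
    return parse_newick("(A,B,C,D,E,F);")
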