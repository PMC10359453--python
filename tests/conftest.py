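"""Shared fixtures: toy alignments and the planted two-subfamily MSA."""

import io

import pytest
from Bio import Phylo
from hypothesis import HealthCheck, settings

from udgx.msa import Msa, build_reference_map
from udgx.simulate import MsaTruth, generate_msa

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_msa():
    """5 sequences x 12 columns; reference gapped at column 3.

    Reference positions: col 1->1, 2->2, 4->3, ... 12->11.  Three sequences
    carry R/H at reference positions 9/11 (columns 10/12); the other two
    carry P/N.
    """
    seqs = {
        "MsmUdgX": "AC-DEFGHIKRH",
        "u1":      "ACQDEFGHIKRH",
        "u2":      "ACQDEFGHIKRH",
        "f1":      "ACADEFGHIKPN",
        "f2":      "AC-DEFGHIKPN",
    }
    return Msa(tuple(seqs), tuple(seqs.values()))


@pytest.fixture
def toy_refmap(toy_msa):
    return build_reference_map(toy_msa, "MsmUdgX")


@pytest.fixture(scope="session")
def planted():
    """The study-condition synthetic MSA: n=2000, planted 53/107/109.

    Returns (msa, truth_record, refmap).  Generated once per session.
    """
    truth = MsaTruth(seed=11)
    msa, record = generate_msa(truth)
    refmap = build_reference_map(msa, truth.ref_id)
    return msa, record, refmap


def clade_size(newick: str, leaf_names: set[str]) -> int:
    """Number of leaves under the smallest clade containing *leaf_names*."""
    tree = Phylo.read(io.StringIO(newick), "newick")
    mrca = tree.common_ancestor([{"name": n} for n in leaf_names])
    return len(mrca.get_terminals())
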