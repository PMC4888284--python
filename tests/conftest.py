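"""Shared fixtures: toy annotations, tiny profiles, simulated genomes."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from regsig import (
    FilterConfig,
    GenomeRecord,
    Feature,
    Provenance,
    Site,
    SiteAlignment,
    build_profile,
)
from regsig.synthetic import SimConfig, simulate_genome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def toy_record():
    """1-kb record with a converging gene pair: CDS[100,400,+) / CDS[600,900,-)."""
    return GenomeRecord(
        "toy",
        "".join(np.random.default_rng(0).choice(list("ACGT"), size=1000)),
        [
            Feature("gene", 100, 400, "+", {"locus_tag": ["t1"]}),
            Feature("CDS", 100, 400, "+", {"locus_tag": ["t1"]}),
            Feature("gene", 600, 900, "-", {"locus_tag": ["t2"]}),
            Feature("CDS", 600, 900, "-", {"locus_tag": ["t2"]}),
        ],
    )


@pytest.fixture
def acgt_profile():
    """Single-sequence 'ACGT' profile at pseudocount 0 (log-odds 2 bits/col)."""
    aln = SiteAlignment("acgt", [Site("s1", "ACGT")])
    return build_profile(aln, pseudocount=0.0)


@pytest.fixture
def aa_at_profile():
    aln = SiteAlignment("aa_at", [Site("s1", "AA"), Site("s2", "AT")])
    return build_profile(aln, pseudocount=0.0)


@pytest.fixture(scope="session")
def sim_default():
    """One 50-kb simulated genome with its truth table (fixed seed)."""
    return simulate_genome(SimConfig(seed=11))


def random_profile(rng, length, pseudocount=0.5):
    """A random profile built from random multinomial counts."""
    counts = rng.integers(0, 20, size=(length, 4)).astype(float)
    matrix = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + 4 * pseudocount
    )
    from regsig.motifs import Profile

    return Profile(name=f"rand{length}", matrix=matrix, nsites=20)
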