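import numpy as np
import pytest

from postglacial.scenarios import DemographicScenario, PopulationSpec, Prior
from postglacial.seqdata import Alignment, encode_sequences


def single_population(ne: float, n: int, label: str = "A", age: int = 0) -> DemographicScenario:
    """One-population scenario with fixed haploid size (no events)."""
    return DemographicScenario(
        id=f"single_{label}",
        populations=[PopulationSpec(label=label, ne=Prior.of(ne), sample_size=n,
                                    sampling_age=age)],
        events=[],
    )


def alignment_from_strings(seq_strings, pops=None, ages=None, ids=None) -> Alignment:
    n = len(seq_strings)
    return Alignment(
        sample_ids=ids or [f"s{i}" for i in range(n)],
        pop_labels=pops or ["P"] * n,
        sample_ages=np.asarray(ages if ages is not None else [0] * n),
        seqs=encode_sequences(seq_strings),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def worked_alignment():
    """4 sequences x 8 bp with hand-checkable pairwise differences."""
    return alignment_from_strings(
        [
            "ACGTACGT",
            "ACGTACGA",  # differs from s0 at site 8
            "ACGAACGT",  # differs from s0 at site 4
            "TCGAACGA",  # differs from s0 at sites 1, 4, 8
        ],
        pops=["P1", "P1", "P2", "P2"],
    )
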