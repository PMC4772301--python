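import numpy as np
import pytest

from holocompare.io_formats import DomainRecord, ProteinDomainTable


@pytest.fixture
def rng():
    return np.random.default_rng(20160229)


def random_domain_table(rng, species_id, n_proteins=20, domains=("A", "B", "C", "D")):
    """A random but valid per-species domain table."""
    records = []
    for p in range(n_proteins):
        n_dom = rng.integers(0, 5)
        picks = rng.choice(len(domains), size=n_dom, replace=True)
        pos = 0
        for k in picks:
            start = pos
            end = start + int(rng.integers(20, 120))
            records.append(DomainRecord(f"p{p}", domains[int(k)], start, end))
            pos = end + int(rng.integers(1, 10))
    return ProteinDomainTable(species_id=species_id, records=records)
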