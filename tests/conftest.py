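import numpy as np
import pandas as pd
import pytest

from radpop import GenotypePanel, MISSING


def make_panel(genotypes, populations, locus_ids=None, positions=None):
    """Build a small panel from a genotype list-of-lists and pop labels."""
    geno = np.asarray(genotypes, dtype=np.int8)
    n, L = geno.shape
    samples = [f"s{i}" for i in range(n)]
    pops = pd.Series(list(populations), index=samples)
    if locus_ids is None:
        locus_ids = [f"L{j}" for j in range(L)]
    if positions is None:
        positions = list(range(1, L + 1))
    loci = pd.DataFrame(
        {
            "locus_id": locus_ids,
            "snp_id": [f"{lid}_{p}" for lid, p in zip(locus_ids, positions)],
            "chrom": "1",
            "pos": positions,
        }
    )
    return GenotypePanel(samples=samples, populations=pops, loci=loci, genotypes=geno)


@pytest.fixture
def toy_panel():
    """4 individuals, 2 populations, 3 SNPs with one missing call."""
    return make_panel(
        [[0, 1, 2], [1, 1, 0], [2, 0, MISSING], [0, 2, 1]],
        ["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def study_panel():
    """The default simulated 7x20 study panel plus truth (session-cached)."""
    from radpop import study_scenario, simulate_panel

    return simulate_panel(study_scenario())


@pytest.fixture(scope="session")
def study_filtered(study_panel):
    from radpop import filter_panel

    panel, _ = study_panel
    filtered, report = filter_panel(panel)
    return filtered, report
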