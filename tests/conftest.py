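import pytest

from placmatch.genotype_io import GenotypeTable, PairRecord, default_panel
from placmatch.popgen_qc import MCParams
from placmatch.synthetic_data import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture()
def toy_table(panel):
    """Two individuals fully typed at the nine default loci."""
    table = GenotypeTable(panel.names)
    calls_a = [(193, 209), (239, 241), (197, 201), (230, 232), (329, 331),
               (248, 250), (225, 227), (158, 160), (149, 151)]
    calls_b = [(193, 193), (241, 243), (197, 214), (230, 230), (331, 333),
               (250, 252), (227, 229), (160, 162), (151, 153)]
    for ind, calls in (("A", calls_a), ("B", calls_b)):
        table.add_individual(ind)
        for locus, (x, y) in zip(panel.names, calls):
            table.set_call(ind, locus, x, y)
    return table


@pytest.fixture(scope="session")
def clean_study():
    """43-pair study without null alleles or recombination (fully Mendelian)."""
    return simulate_study(
        SimulationConfig(
            seed=101, n_pairs=43, null_allele_freq={}, recombination_rates=[0.0] * 8
        )
    )


@pytest.fixture(scope="session")
def default_study():
    """43-pair study at the default (study-condition) settings; fittable realization."""
    return simulate_study(SimulationConfig(seed=2, n_pairs=43))


@pytest.fixture(scope="session")
def quick_mc():
    return MCParams(dememorization=100, batches=20, iterations=200)


def make_pairs(n, n_rfm):
    return [PairRecord(f"M{i}", f"F{i}", i < n_rfm) for i in range(n)]
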