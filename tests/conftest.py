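import pytest

from capssr.genotype_typing import NULL, MULTIBAND, GenotypeTable, make_call
from capssr.synthetic_data import PopulationDesign, simulate_population


def build_table(columns: dict[str, dict[str, object]]) -> GenotypeTable:
    """Build a GenotypeTable from marker -> {line -> cell} where a cell is an
    int, a tuple of ints/strings, NULL or MULTIBAND."""
    markers = list(columns)
    lines = list(next(iter(columns.values())))
    calls = {}
    for line in lines:
        row = {}
        for marker in markers:
            cell = columns[marker][line]
            if cell is NULL or cell is MULTIBAND:
                row[marker] = cell
            elif isinstance(cell, tuple):
                row[marker] = make_call(*cell)
            else:
                row[marker] = make_call(cell)
        calls[line] = row
    return GenotypeTable(lines=lines, markers=markers, calls=calls)


@pytest.fixture(scope="session")
def reference_population():
    """The default study-condition panel: K=4 clusters of 30 lines genotyped
    at 60 markers with divergence 0.9, 5% nulls and 2% hybrid lines."""
    return simulate_population(PopulationDesign(seed=1))
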