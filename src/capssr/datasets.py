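"""Bundled reference data.

Per-cluster genotype frequencies for the 19 cluster-associated genotypes
observed in a 192-line Capsicum diversity panel: clusters A (C. annuum),
B (C. baccatum), C (C. chinense) and F (C. frutescens).  Eighteen rows are
EST-SSR fragment genotypes (sizes in bp); one is the plastid matK SNP
haplotype "AC".  Values are the percentage of each cluster's lines carrying
the genotype.
"""

from __future__ import annotations

import pandas as pd

# (marker, genotype, %A, %B, %C, %F)
_CLUSTER_GENOTYPE_FREQUENCIES = [
    ("CaES2655", "102", 87, 4, 0, 0),
    ("CaES4192", "166", 97, 0, 0, 0),
    ("CaES5301", "624", 90, 0, 0, 0),
    ("CaES0404", "271", 0, 89, 0, 0),
    ("CaES1137", "127", 0, 96, 0, 0),
    ("CaES2027", "254", 0, 96, 6, 0),
    ("CaES2505", "237", 0, 100, 0, 0),
    ("CaES2930", "175", 3, 92, 0, 0),
    ("CaES4584", "102", 3, 100, 1, 0),
    ("CaES4597", "251", 0, 100, 0, 0),
    ("CaES4666", "133/172", 0, 100, 1, 0),
    ("CaES5512", "344", 0, 100, 0, 0),
    ("matK", "AC", 0, 100, 0, 0),
    ("CaES1112", "208", 0, 4, 95, 14),
    ("CaES4410", "481", 0, 0, 97, 4),
    ("CaES2027", "251", 3, 0, 0, 100),
    ("CaES2666", "271", 0, 0, 0, 82),
    ("CaES4616", "294", 3, 0, 1, 89),
    ("CaES4665", "113", 0, 0, 0, 82),
]


def cluster_genotype_frequency_table() -> pd.DataFrame:
    """The reference frequency table, shaped like
    :func:`capssr.diagnostics.genotype_frequencies` output: wide percentages
    indexed by (marker, genotype) with cluster columns A, B, C, F."""
    index = pd.MultiIndex.from_tuples(
        [(m, g) for m, g, *_ in _CLUSTER_GENOTYPE_FREQUENCIES],
        names=["marker", "genotype"])
    data = [[a, b, c, f] for _, _, a, b, c, f in _CLUSTER_GENOTYPE_FREQUENCIES]
    return pd.DataFrame(data, index=index, columns=["A", "B", "C", "F"],
                        dtype=float)
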