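import numpy as np
import pandas as pd
import pytest

from l1regkit.setstats import DETable, GeneSet, GeneUniverse


@pytest.fixture
def small_universe() -> GeneUniverse:
    return GeneUniverse(f"g{i}" for i in range(1, 21))


def make_de_table(up=(), down=(), null=(), label="t", threshold=0.05) -> DETable:
    """Hand-built DE table: listed genes are clearly significant in the
    stated direction, ``null`` genes clearly not."""
    rows = [(g, 1.0, 0.01) for g in up]
    rows += [(g, -1.0, 0.01) for g in down]
    rows += [(g, 0.0, 0.5) for g in null]
    frame = pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])
    return DETable(frame, threshold=threshold, label=label)


def gene_set(*genes, label="s") -> GeneSet:
    return GeneSet.from_iterable(label, genes)
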