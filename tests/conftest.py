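import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sjkit.io import JUNCTION_INDEX, GeneModel, JunctionTable, SampleInfo

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(counts_by_key: dict, samples: list[str], annotated=None) -> JunctionTable:
    """Small junction table from {key: [counts per sample]}."""
    idx = pd.MultiIndex.from_tuples(counts_by_key.keys(), names=JUNCTION_INDEX)
    counts = pd.DataFrame(list(counts_by_key.values()), index=idx, columns=samples)
    if annotated is None:
        flags = pd.Series(True, index=idx)
    else:
        flags = pd.Series([annotated[k] for k in counts_by_key], index=idx)
    return JunctionTable(counts, flags)


@pytest.fixture
def six_samples() -> list[SampleInfo]:
    return [
        SampleInfo(f"wt{i}", "WT", f"litter{i}") for i in (1, 2, 3)
    ] + [
        SampleInfo(f"het{i}", "HET", f"litter{i}") for i in (1, 2, 3)
    ]


@pytest.fixture
def cassette_gene() -> GeneModel:
    """Three-exon gene whose second transcript skips the middle exon."""
    return GeneModel.from_transcripts(
        "geneA",
        "chr1",
        "+",
        {
            "geneA.t1": [(1, 100), (201, 300), (401, 500)],
            "geneA.t2": [(1, 100), (401, 500)],
        },
    )
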