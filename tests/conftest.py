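import numpy as np
import pandas as pd
import pytest

from fibervit.annotation import builtin_demo_annotation
from fibervit.metabolome import MetabolomeTable
from fibervit.transcripts import StratifiedAbundanceTable


@pytest.fixture(scope="session")
def demo_ann():
    return builtin_demo_annotation()


def make_stratified(rows: dict[str, list[float]], samples: list[str], units="counts"):
    """Build a StratifiedAbundanceTable from {'FEAT' or 'FEAT|taxon': values}."""
    index, data = [], []
    for key, vals in rows.items():
        if "|" in key:
            f, t = key.split("|", 1)
        else:
            f, t = key, "TOTAL"
        index.append((f, t))
        data.append(vals)
    df = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_tuples(index, names=["feature_id", "taxon"]),
        columns=samples,
    ).astype(float)
    return StratifiedAbundanceTable(df, units=units)


def make_metabolome(values: pd.DataFrame, groups: dict[str, str], compartment="cecum", size=1.0):
    """MetabolomeTable from a metabolite×sample frame; groups maps sample -> 'COL:DIET'."""
    meta_rows = []
    for s in values.columns:
        col, diet = groups[s].split(":")
        meta_rows.append((s, diet, col, compartment, size))
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "diet_group", "colonization", "compartment", "size_factor"]
    ).set_index("sample_id")
    return MetabolomeTable(values.astype(float), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
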