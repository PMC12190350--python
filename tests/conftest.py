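import numpy as np
import pandas as pd
import pytest

from isousage.annotation_io import CATALOG_COLUMNS, CellTable, IsoformCatalog
from isousage.synthetic_data import SimulationConfig, simulate_dataset


def make_catalog(rows: list[dict]) -> IsoformCatalog:
    """Toy catalog from partial per-isoform dicts (sensible defaults filled)."""
    defaults = dict(
        gene_name=None, chrom="chr1", strand="+", tss=0, pas=999, length=1000,
        exon_count=1, coding=True, tsl=1.0, cds_length=np.nan,
        utr5_length=np.nan, utr3_length=np.nan,
    )
    full = []
    for r in rows:
        d = {**defaults, **r}
        if d["gene_name"] is None:
            d["gene_name"] = d["gene_id"]
        full.append(d)
    df = pd.DataFrame(full).set_index("isoform_id")
    return IsoformCatalog(df[CATALOG_COLUMNS])


def make_cells(n: int, cell_type="neuron", sample_id="s1", age_months=4.0,
               age_category="young", sex="M", region="cortex", prefix="BC") -> CellTable:
    df = pd.DataFrame({
        "sample_id": sample_id, "cell_type": cell_type, "age_months": age_months,
        "age_category": age_category, "sex": sex, "region": region,
    }, index=pd.Index([f"{prefix}{i:05d}" for i in range(n)], name="barcode"))
    return CellTable(df)


@pytest.fixture(scope="session")
def dataset():
    """Default desk-scale synthetic dataset (2000 cells, 500 genes)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def immune_dataset():
    """Immune-heavy dataset for senescence analyses."""
    props = {"neuron": 0.2, "oligo": 0.15, "astrocyte": 0.15,
             "vascular": 0.1, "immune": 0.4}
    cfg = SimulationConfig(seed=5, cell_type_proportions=props,
                           n_cells_per_sample=400)
    return cfg, simulate_dataset(cfg)
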