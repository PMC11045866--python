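import numpy as np
import pandas as pd
import pytest

from mucoflow.community_profiles import AbundanceTable


@pytest.fixture
def toy_table() -> AbundanceTable:
    """5-taxon, 5-sample table with genus taxonomy and two groups.

    Hand-designed so filtering, prevalence and normalization rules can be
    enumerated by hand:
      t1: present in 1 sample, total 500  -> filtered (prevalence)
      t2: present in 3 samples, total 9   -> filtered (total)
      t3: present in 3 samples, total 10  -> kept (boundary)
      t4: present in all samples          -> kept
      t5: present in 4 of 5 samples       -> kept
    """
    counts = pd.DataFrame(
        {
            "t1": [500, 0, 0, 0, 0],
            "t2": [3, 3, 3, 0, 0],
            "t3": [4, 3, 3, 0, 0],
            "t4": [10, 20, 30, 40, 50],
            "t5": [5, 5, 5, 5, 0],
        },
        index=["s1", "s2", "s3", "s4", "s5"],
    )
    taxonomy = {
        "t1": "Bacteria;Firmicutes;Blautia",
        "t2": "Bacteria;Firmicutes;Blautia",
        "t3": "Bacteria;Bacteroidota;Bacteroides",
        "t4": "Bacteria;Verrucomicrobiota;Akkermansia",
        "t5": "Bacteria;Firmicutes;Enterococcus",
    }
    meta = {"s1": "A", "s2": "A", "s3": "B", "s4": "B", "s5": "B"}
    return AbundanceTable(counts, taxonomy=taxonomy, sample_meta=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240425)
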