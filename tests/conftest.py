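import numpy as np
import pandas as pd
import pytest

from dmsort import library as lib
from dmsort import simulate as sim


@pytest.fixture(scope="session")
def paper_manifest() -> lib.LibraryManifest:
    """Manifest with the study's stated composition (4,920 clones)."""
    return lib.build_manifest(lib.LibraryDesign(rng_seed=20240501))


@pytest.fixture(scope="session")
def small_manifest() -> lib.LibraryManifest:
    """An 88-clone manifest for fast end-to-end runs."""
    return lib.build_manifest(
        lib.LibraryDesign(
            n_wt_syn=20, n_stop=8, n_missense_clones=60,
            median_barcodes_per_missense=3, rng_seed=1,
        )
    )


def counts_from_truth(truth: sim.GroundTruth) -> pd.DataFrame:
    """Counts table straight from simulation ground truth (lossless counting)."""
    clones = truth.manifest.clones
    return pd.DataFrame(
        {
            "barcode": [c.barcode for c in clones],
            "clone_id": [c.clone_id for c in clones],
            "count_low": truth.reads_low,
            "count_high": truth.reads_high,
        }
    )
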