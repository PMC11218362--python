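import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

SAMPLES = [f"S{i}" for i in range(1, 7)]
ASVS = [f"A{i}" for i in range(1, 11)]


@pytest.fixture
def toy_counts():
    """Hand-built 10-ASV x 6-sample table.

    A7 is a singleton (total 1), A8 totals 2; S6 totals 999 reads, everything
    else is comfortably above 1000.
    """
    data = {
        # A1, A9, A10 carry the bulk of every sample
        "A1": [500, 500, 500, 500, 500, 400],
        "A2": [50, 50, 50, 50, 50, 50],
        "A3": [50, 50, 50, 50, 50, 50],
        "A4": [50, 50, 50, 50, 50, 50],
        "A5": [50, 50, 50, 50, 50, 50],
        "A6": [50, 50, 50, 50, 50, 50],
        "A7": [1, 0, 0, 0, 0, 0],
        "A8": [1, 1, 0, 0, 0, 0],
        "A9": [300, 300, 300, 300, 300, 200],
        "A10": [200, 200, 200, 200, 200, 149],
    }
    return pd.DataFrame(data, index=SAMPLES)


@pytest.fixture
def toy_taxonomy():
    rows = {
        "A1": ("Bacteria", "Firmicutes", None, None, "Lactobacillaceae", "Lactobacillus", None),
        "A2": ("Archaea", "Euryarchaeota", None, None, "Methanobacteriaceae", None, None),
        "A3": ("Bacteria", "Cyanobacteria", None, None, None, None, None),
        "A4": ("Bacteria", "Proteobacteria", None, None, "Mitochondria", None, None),
        "A5": ("Bacteria", "Cyanobacteria_unrelated", None, "Chloroplast", None, None, None),
        "A6": ("Bacteria", "Proteobacteria", None, None, "Beijerinckiaceae",
               "Methylobacterium-Methylorubrum", None),
        "A7": ("Bacteria", "Firmicutes", None, None, "Ruminococcaceae", None, None),
        "A8": ("Bacteria", "Firmicutes", None, None, "Ruminococcaceae", None, None),
        "A9": ("Bacteria", "Proteobacteria", None, None, "Pseudomonadaceae", "Pseudomonas", None),
        "A10": ("Bacteria", "Bacteroidota", None, None, "Flavobacteriaceae", None, None),
    }
    cols = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame({
        "group": ["M", "M", "M", "V", "V", "V"],
        "phase": ["stimulus"] * 6,
        "sample_type": ["intestine"] * 6,
    }, index=SAMPLES)


@pytest.fixture
def rng():
    return np.random.default_rng(20240701)
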