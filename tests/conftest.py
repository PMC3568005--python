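import numpy as np
import pytest

from mixqspr import (
    CompoundRef,
    DescriptorMatrix,
    MixtureDataset,
    MixtureRecord,
    SyntheticSpec,
    generate_mixture_dataset,
)

# A small pool of real structures for tests that exercise SMILES canonicalization.
SMILES_POOL = [
    "CCO", "OCC", "c1ccccc1", "C1=CC=CC=C1", "CC(C)O", "CCCCCC", "CC(=O)C",
    "ClCCl", "CCOC(C)=O", "CC#N", "C1CCCCC1", "CO", "CCCO", "CC(C)=O",
]


def make_row(s1, frac, s2=None, value=1.0, prop="density", unit="g/cm3", source="test"):
    row = {
        "SMILES1": s1,
        "MOLAR_FRACTION": frac,
        "PROPERTY": prop,
        "VALUE": value,
        "UNIT": unit,
        "SOURCE": source,
    }
    if s2 is not None:
        row["SMILES2"] = s2
    return row


def opaque_dataset(pairs, prop="p", values=None, **kwargs):
    """Dataset over opaque compound tokens, one record per (a, b, x1) triple."""
    records = []
    for i, (a, b, x1) in enumerate(pairs):
        v = values[i] if values is not None else float(i)
        c1, c2 = CompoundRef(a), (CompoundRef(b) if b is not None else None)
        records.append(MixtureRecord(c1, c2, x1, prop, v))
    return MixtureDataset(records=records, property=prop, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression_study():
    """Small synthetic concentration-dependent study with known truth."""
    spec = SyntheticSpec(
        n_compounds=20,
        m_descriptors=5,
        n_pairs=40,
        compositions_per_mixture=5,
        interaction_strength=0.5,
        compound_effect_sd=0.5,
        noise_sd=0.05,
        seed=3,
    )
    return generate_mixture_dataset(spec)


@pytest.fixture
def toy_matrix():
    names = ["a", "b", "c"]
    rows = {
        CompoundRef("X"): np.array([1.0, 2.0, 3.0]),
        CompoundRef("Y"): np.array([4.0, 0.0, -1.0]),
        CompoundRef("Z"): np.array([-2.0, 5.0, 0.5]),
    }
    return DescriptorMatrix(descriptor_names=names, rows=rows, backend_id="toy")
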