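import numpy as np
import pytest

from csiscan.alignment_io import Alignment, TaxonPartition
from csiscan.scanner import ScanConfig
from csiscan.simulate import PlantedIndel, SyntheticSpec, simulate_msa


@pytest.fixture
def noiseless_insert_fixture():
    """One planted 4 aa in-group insert with fully conserved flanks."""
    spec = SyntheticSpec(
        seed=11,
        n_ingroup=6,
        n_outgroup=5,
        core_length_aa=200,
        substitution_rate=0.0,
        planted_indels=(PlantedIndel(position=100, length_aa=4, type="insert"),),
    )
    return simulate_msa(spec)


@pytest.fixture
def spectrum_fixture():
    """Study-scale fixture spanning the reported indel-length spectrum:
    1 and 4 aa deletions, 2 aa and 43-or-44 aa inserts."""
    spec = SyntheticSpec(
        seed=23,
        planted_indels=(
            PlantedIndel(position=90, length_aa=1, type="deletion"),
            PlantedIndel(position=200, length_aa=2, type="insert"),
            PlantedIndel(position=310, length_aa=4, type="deletion"),
            PlantedIndel(position=430, length_aa=(43, 44), type="insert"),
        ),
    )
    return simulate_msa(spec)


def random_tiny_alignment(seed: int):
    """Random gapped alignment (<= 8 rows, <= 12 columns), a random
    partition, and a random scan configuration — fuel for the brute-force
    oracle comparison."""
    rng = np.random.default_rng(seed)
    n_rows = int(rng.integers(4, 9))
    n_cols = int(rng.integers(6, 13))
    alphabet = np.array(list("ACD-"))
    probs = np.array([0.25, 0.2, 0.2, 0.35])
    pairs = []
    for i in range(n_rows):
        residues = "".join(rng.choice(alphabet, size=n_cols, p=probs))
        pairs.append((f"s{i}", residues))
    alignment = Alignment.from_pairs(pairs)
    k = int(rng.integers(1, n_rows))
    ids = [f"s{i}" for i in range(n_rows)]
    partition = TaxonPartition(frozenset(ids[:k]), frozenset(ids[k:]))
    config = ScanConfig(
        flank_window_aa=int(rng.integers(2, 5)),
        min_flank_conserved=int(rng.integers(0, 2)),
        conservation_fraction=float(rng.choice([0.6, 0.8, 1.0])),
        ingroup_presence_fraction=float(rng.choice([0.5, 0.8, 1.0])),
        outgroup_absence_fraction=float(rng.choice([0.5, 0.8, 1.0])),
    )
    reference_id = ids[0]
    return alignment, partition, config, reference_id
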