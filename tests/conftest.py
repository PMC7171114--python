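import numpy as np
import pytest

from dtirf.dataset import build_dataset
from dtirf.interaction_data import sample_balanced_pairs
from dtirf.protein_features import extract_dct_descriptor
from dtirf.synthetic_data import SyntheticConfig, generate, write_fixture_bundle

#: Toy 5-residue ASCII PSSM in the PSI-BLAST dialect (log-odds block only).
TOY_PSSM_SCORES = np.arange(100).reshape(5, 20) % 13 - 6
TOY_PSSM_SEQUENCE = "MKTAY"


def toy_pssm_text() -> str:
    header = (
        "\nLast position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
        "            A   R   N   D   C   Q   E   G   H   I   L   K   M   F   P   S   T   W   Y   V\n"
    )
    rows = []
    for i, (residue, row) in enumerate(zip(TOY_PSSM_SEQUENCE, TOY_PSSM_SCORES), start=1):
        rows.append(f"{i:5d} {residue}  " + " ".join(f"{v:3d}" for v in row))
    return header + "\n".join(rows) + "\n"


@pytest.fixture(scope="session")
def toy_pssm():
    from dtirf.protein_features import parse_ascii_pssm

    return parse_ascii_pssm(toy_pssm_text(), protein_id="TOY")


def make_pipeline_dataset(signal: float, seed: int, n_drugs=20, n_targets=20, n_positives=100):
    """Generate a synthetic benchmark and assemble the balanced feature matrix."""
    config = SyntheticConfig(
        n_drugs=n_drugs,
        n_targets=n_targets,
        n_positives=n_positives,
        seq_len_range=(40, 120),
        signal_strength=signal,
        seed=seed,
    )
    data = generate(config)
    pairs = sample_balanced_pairs(data.network, seed=seed + 1)
    descriptors = {t: extract_dct_descriptor(p) for t, p in data.pssms.items()}
    return build_dataset(pairs, descriptors, data.fingerprints)


@pytest.fixture(scope="session")
def pipeline_dataset():
    """200-pair balanced dataset with a strong planted signal."""
    return make_pipeline_dataset(signal=5.0, seed=7)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Small on-disk fixture bundle shared by the CLI tests."""
    directory = tmp_path_factory.mktemp("bundle")
    config = SyntheticConfig(
        n_drugs=12, n_targets=12, n_positives=30,
        seq_len_range=(30, 60), signal_strength=5.0, seed=11,
    )
    bundle = write_fixture_bundle(config, directory)
    bundle["directory"] = directory
    bundle["config"] = config
    return bundle
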