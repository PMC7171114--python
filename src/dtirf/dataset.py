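"""Assembly of labelled drug-target pairs into a feature matrix.

Each pair's row concatenates the target's 400-dim protein descriptor with
the drug's 881-bit fingerprint, giving 1281 features.  Pair provenance
(which drug/target produced each row) travels with the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from dtirf.drug_features import FINGERPRINT_LENGTH, FingerprintVector
from dtirf.interaction_data import LabeledPairSet
from dtirf.protein_features import ProteinDescriptor

__all__ = ["DatasetMatrix", "build_dataset"]


@dataclass
class DatasetMatrix:
    """n_samples x n_features matrix with labels and pair provenance."""

    X: np.ndarray
    y: np.ndarray
    pairs: list[tuple[str, str]]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.pairs):
            raise ValueError("X, y and pairs must agree in length")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_dataset(
    labeled_pairs: LabeledPairSet,
    protein_descriptors: dict[str, ProteinDescriptor],
    fingerprints: dict[str, FingerprintVector],
    on_missing: str = "error",
) -> DatasetMatrix:
    """Join labelled pairs with their feature vectors.

    ``on_missing`` controls pairs whose drug or target lacks features:
    "error" raises, "skip" drops them (recorded in ``skipped``).
    Descriptor lengths are validated so every row has exactly
    ``descriptor_length + 881`` features.
    """
    if on_missing not in ("error", "skip"):
        raise ValueError("on_missing must be 'error' or 'skip'")
    rows: list[np.ndarray] = []
    labels: list[int] = []
    kept: list[tuple[str, str]] = []
    skipped: list[tuple[str, str]] = []
    desc_len: int | None = None
    for (drug_id, target_id), label in zip(labeled_pairs.pairs, labeled_pairs.labels):
        desc = protein_descriptors.get(target_id)
        fp = fingerprints.get(drug_id)
        if desc is None or fp is None:
            if on_missing == "skip":
                skipped.append((drug_id, target_id))
                continue
            missing = "protein descriptor" if desc is None else "fingerprint"
            raise KeyError(f"pair ({drug_id}, {target_id}): missing {missing}")
        if desc_len is None:
            desc_len = desc.values.size
        elif desc.values.size != desc_len:
            raise ValueError(
                f"target {target_id!r}: descriptor length {desc.values.size} != {desc_len}"
            )
        if fp.bits.size != FINGERPRINT_LENGTH:
            raise ValueError(f"drug {drug_id!r}: fingerprint length {fp.bits.size}")
        rows.append(np.concatenate([desc.values, fp.bits.astype(float)]))
        labels.append(int(label))
        kept.append((drug_id, target_id))
    if not rows:
        raise ValueError("no pairs with complete features")
    return DatasetMatrix(X=np.vstack(rows), y=np.array(labels), pairs=kept, skipped=skipped)
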