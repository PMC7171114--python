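"""881-bit substructure fingerprints for drug molecules.

Each drug is a fixed-length Boolean vector over 881 predefined chemical
substructure keys (the PubChem key set): bit k is 1 iff the molecule
contains substructure k.  Fingerprints are consumed precomputed, either as
TSV/CSV bit tables or as PubChem's base64-encoded packed strings; computing
the keys from chemical structures is out of scope, but any callable mapping
a structure string to 881 bits can be plugged in via
:func:`fingerprints_from_structures`.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

__all__ = [
    "FINGERPRINT_LENGTH",
    "FingerprintVector",
    "read_fingerprint_table",
    "write_fingerprint_table",
    "decode_pubchem_base64",
    "encode_pubchem_base64",
    "fingerprints_from_structures",
]

#: Number of PubChem substructure keys.
FINGERPRINT_LENGTH = 881


class FingerprintError(ValueError):
    """Raised on fingerprints of wrong length or with non-binary entries."""


@dataclass
class FingerprintVector:
    """Binary substructure descriptor of one drug."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=int)
        if self.bits.shape != (FINGERPRINT_LENGTH,):
            raise FingerprintError(
                f"drug {self.drug_id!r}: fingerprint length {self.bits.size} != {FINGERPRINT_LENGTH}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise FingerprintError(f"drug {self.drug_id!r}: fingerprint has non-binary entries")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def read_fingerprint_table(path) -> dict[str, FingerprintVector]:
    """Read a TSV/CSV fingerprint table into an id -> fingerprint map.

    Each row is a drug id followed by either 881 separate 0/1 columns or a
    single 881-character 0/1 string.  Rows of any other shape are rejected
    with the offending drug id in the message.
    """
    out: dict[str, FingerprintVector] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            sep = "\t" if "\t" in line else ","
            fields = line.split(sep)
            drug_id = fields[0]
            if len(fields) == 2:
                bitstring = fields[1]
                if len(bitstring) != FINGERPRINT_LENGTH:
                    raise FingerprintError(
                        f"drug {drug_id!r}: bit string length {len(bitstring)} != {FINGERPRINT_LENGTH}"
                    )
                if set(bitstring) - {"0", "1"}:
                    raise FingerprintError(f"drug {drug_id!r}: non-binary character in bit string")
                bits = np.frombuffer(bitstring.encode(), dtype=np.uint8) - ord("0")
            elif len(fields) == FINGERPRINT_LENGTH + 1:
                try:
                    bits = np.array([int(v) for v in fields[1:]])
                except ValueError:
                    raise FingerprintError(f"drug {drug_id!r}: non-integer bit value") from None
            else:
                raise FingerprintError(
                    f"drug {drug_id!r}: row has {len(fields) - 1} bit columns, "
                    f"expected {FINGERPRINT_LENGTH} or one bit string"
                )
            out[drug_id] = FingerprintVector(drug_id=drug_id, bits=bits)
    return out


def write_fingerprint_table(fingerprints: Iterable[FingerprintVector], path) -> None:
    """Write fingerprints as TSV rows of ``id<TAB>881-char bit string``."""
    with open(path, "wt", encoding="utf-8") as fh:
        for fp in fingerprints:
            fh.write(fp.drug_id + "\t" + "".join(str(b) for b in fp.bits) + "\n")


def decode_pubchem_base64(encoded: str, drug_id: str = "") -> FingerprintVector:
    """Decode PubChem's base64 fingerprint string.

    The payload is a 4-byte big-endian bit-length prefix followed by the
    bit-packed keys, most-significant bit first.  The declared length must
    be 881.
    """
    try:
        raw = base64.b64decode(encoded, validate=True)
    except Exception as exc:
        raise FingerprintError(f"invalid base64 fingerprint: {exc}") from None
    if len(raw) < 4:
        raise FingerprintError("fingerprint payload shorter than the 4-byte length prefix")
    declared = int.from_bytes(raw[:4], "big")
    if declared != FINGERPRINT_LENGTH:
        raise FingerprintError(f"declared bit length {declared} != {FINGERPRINT_LENGTH}")
    payload = np.frombuffer(raw[4:], dtype=np.uint8)
    if payload.size * 8 < FINGERPRINT_LENGTH:
        raise FingerprintError("fingerprint payload truncated")
    bits = np.unpackbits(payload, bitorder="big")[:FINGERPRINT_LENGTH]
    return FingerprintVector(drug_id=drug_id, bits=bits)


def encode_pubchem_base64(fingerprint: FingerprintVector) -> str:
    """Inverse of :func:`decode_pubchem_base64` (round-trip identity)."""
    packed = np.packbits(fingerprint.bits.astype(np.uint8), bitorder="big")
    raw = FINGERPRINT_LENGTH.to_bytes(4, "big") + packed.tobytes()
    return base64.b64encode(raw).decode("ascii")


def fingerprints_from_structures(
    structures: dict[str, str], keygen: Callable[[str], np.ndarray]
) -> dict[str, FingerprintVector]:
    """Hook for user-supplied key generators.

    ``keygen`` maps a structure string (SMILES, InChI, ...) to 881 bits;
    outputs are validated like any other fingerprint.
    """
    return {
        drug_id: FingerprintVector(drug_id=drug_id, bits=np.asarray(keygen(s)))
        for drug_id, s in structures.items()
    }
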