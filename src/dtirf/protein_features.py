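"""Protein sequence descriptors: PSSM + 2-D DCT (main) and PseAAC (baseline).

The main protein representation starts from a position-specific scoring
matrix (PSSM): the L x 20 log-odds profile produced by iterative PSI-BLAST
search, whose entry (i, j) scores residue i mutating to amino-acid type j
over evolution.  The orthonormal type-II 2-D discrete cosine transform
compacts that profile into its low-frequency corner; the top-left 20 x 20
coefficient block (400 values) is the fixed-length descriptor regardless of
sequence length.

The baseline representation is Chou's pseudo amino acid composition
(PseAAC): the 20 amino-acid frequencies augmented with q sequence-order
correlation factors computed from standardized hydrophobicity,
hydrophilicity and side-chain mass, weighted by a factor w.
"""

from __future__ import annotations

import csv
import importlib.resources
import shlex
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

__all__ = [
    "PSSM",
    "ProteinDescriptor",
    "PseAACParams",
    "AA_ORDER",
    "parse_ascii_pssm",
    "read_ascii_pssm",
    "write_ascii_pssm",
    "dct2",
    "idct2",
    "extract_dct_descriptor",
    "pseaac_descriptor",
    "sequence_correlation_factor",
    "read_fasta",
    "write_descriptor_table",
    "read_descriptor_table",
    "psiblast_command",
]

#: PSI-BLAST amino-acid column order.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"


class PSSMParseError(ValueError):
    """Raised on malformed ASCII PSSM content; carries the line number."""


@dataclass
class PSSM:
    """L x 20 evolutionary profile for one protein."""

    protein_id: str
    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError("PSSM scores must have exactly 20 columns")
        if self.scores.shape[0] != len(self.sequence):
            raise ValueError("PSSM row count must equal sequence length")


@dataclass
class ProteinDescriptor:
    """Fixed-length numeric protein descriptor."""

    protein_id: str
    values: np.ndarray
    method: str  # "dct" or "pseaac"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.method == "dct" and self.values.size != 400:
            raise ValueError(f"dct descriptor must have length 400, got {self.values.size}")


def _load_property_table() -> dict[str, np.ndarray]:
    ref = importlib.resources.files("dtirf").joinpath("data/aa_properties.tsv")
    with ref.open("rt", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    props = np.array(
        [[float(r["hydrophobicity"]), float(r["hydrophilicity"]), float(r["side_chain_mass"])] for r in rows]
    )
    # standardized to zero mean / unit variance over the 20 residues
    props = (props - props.mean(axis=0)) / props.std(axis=0)
    return {r["residue"]: props[i] for i, r in enumerate(rows)}


_STANDARDIZED_PROPERTIES = _load_property_table()


@dataclass
class PseAACParams:
    """PseAAC parameters: weight ``w`` and number of correlation tiers ``q``.

    Defaults follow Chou's conventional choices (w = 0.05, q = 10);
    ``q`` must stay below the length of every sequence it is applied to.
    """

    w: float = 0.05
    q: int = 10
    property_set: dict[str, np.ndarray] = field(
        default_factory=lambda: dict(_STANDARDIZED_PROPERTIES)
    )

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be nonnegative")
        if self.q < 0:
            raise ValueError("q must be nonnegative")


# ---------------------------------------------------------------------------
# ASCII PSSM I/O


def parse_ascii_pssm(text: str, protein_id: str = "") -> PSSM:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content.

    Only the first 20 numeric columns (the log-odds block) are kept; the
    sequence is reconstructed from the residue column.  Rows may carry the
    trailing 20 weighted-percentage columns and the two per-position
    statistics, or the log-odds block alone.
    """
    rows: list[list[float]] = []
    residues: list[str] = []
    expected_pos = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        # data rows start with the 1-based position index
        if not fields[0].isdigit():
            continue
        if len(fields) < 2 or len(fields[1]) != 1 or not fields[1].isalpha():
            continue
        pos = int(fields[0])
        residue = fields[1]
        numeric = fields[2:]
        try:
            values = [float(v) for v in numeric]
        except ValueError:
            raise PSSMParseError(f"line {lineno}: non-numeric cell in PSSM row") from None
        if len(values) not in (20, 40, 42):
            raise PSSMParseError(
                f"line {lineno}: expected 20, 40 or 42 numeric columns, got {len(values)}"
            )
        expected_pos += 1
        if pos != expected_pos:
            raise PSSMParseError(
                f"line {lineno}: position {pos} out of order (expected {expected_pos})"
            )
        residues.append(residue)
        rows.append(values[:20])
    if not rows:
        raise PSSMParseError("no PSSM rows found")
    return PSSM(protein_id=protein_id, sequence="".join(residues), scores=np.array(rows))


def read_ascii_pssm(path, protein_id: str | None = None) -> PSSM:
    """Read an ASCII PSSM file; the protein id defaults to the file stem."""
    import pathlib

    p = pathlib.Path(path)
    with open(p, "rt", encoding="utf-8") as fh:
        text = fh.read()
    return parse_ascii_pssm(text, protein_id=protein_id if protein_id is not None else p.stem)


def write_ascii_pssm(pssm: PSSM, path) -> None:
    """Write a PSSM in the ``-out_ascii_pssm`` dialect (log-odds block only)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write("            " + "   ".join(AA_ORDER) + "\n")
        for i, (residue, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
            cells = " ".join(f"{v:6g}" for v in row)
            fh.write(f"{i:5d} {residue}  {cells}\n")


# ---------------------------------------------------------------------------
# 2-D DCT descriptor


def dct2(matrix: np.ndarray) -> np.ndarray:
    """Orthonormal type-II 2-D discrete cosine transform.

    Energy is conserved (Parseval) and :func:`idct2` inverts exactly.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValueError("dct2 requires a nonempty 2-D matrix")
    return scipy.fft.dctn(matrix, type=2, norm="ortho")


def idct2(coefficients: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct2`."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.ndim != 2 or coefficients.size == 0:
        raise ValueError("idct2 requires a nonempty 2-D matrix")
    return scipy.fft.idctn(coefficients, type=2, norm="ortho")


def _zigzag_indices(n_rows: int, n_cols: int) -> list[tuple[int, int]]:
    order = []
    for s in range(n_rows + n_cols - 1):
        diag = [(i, s - i) for i in range(max(0, s - n_cols + 1), min(n_rows, s + 1))]
        order.extend(diag if s % 2 else diag[::-1])
    return order


def extract_dct_descriptor(
    pssm: PSSM,
    n_rows: int = 20,
    n_cols: int = 20,
    normalize: bool = False,
    order: str = "block",
) -> ProteinDescriptor:
    """Low-frequency DCT descriptor of a PSSM.

    The score matrix (optionally squashed element-wise through the logistic
    1/(1+e^-x) when ``normalize`` is set) is transformed with :func:`dct2`
    and the top-left ``n_rows x n_cols`` block is flattened row-major
    (``order="block"``); ``order="zigzag"`` instead takes the first
    ``n_rows*n_cols`` coefficients in zigzag scan order.  Sequences shorter
    than ``n_rows`` are zero-padded to ``n_rows`` rows before the transform,
    so the descriptor length is always ``n_rows * n_cols`` (400 at the
    defaults).
    """
    scores = pssm.scores
    if normalize:
        scores = 1.0 / (1.0 + np.exp(-scores))
    if scores.shape[0] < n_rows:
        pad = np.zeros((n_rows - scores.shape[0], scores.shape[1]))
        scores = np.vstack([scores, pad])
    coeff = dct2(scores)
    if order == "block":
        values = coeff[:n_rows, :n_cols].ravel()
    elif order == "zigzag":
        idx = _zigzag_indices(*coeff.shape)[: n_rows * n_cols]
        values = np.array([coeff[i, j] for i, j in idx])
    else:
        raise ValueError(f"unknown coefficient order {order!r}")
    return ProteinDescriptor(protein_id=pssm.protein_id, values=values, method="dct")


# ---------------------------------------------------------------------------
# PseAAC baseline


def _theta_pair(a: str, b: str, property_set: dict[str, np.ndarray]) -> float:
    """Mean squared difference of the standardized properties of two residues."""
    pa, pb = property_set[a], property_set[b]
    return float(np.mean((pb - pa) ** 2))


def sequence_correlation_factor(
    sequence: str, j: int, property_set: dict[str, np.ndarray] | None = None
) -> float:
    """Tier-``j`` sequence correlation factor theta_j.

    theta_j = (1/(L-j)) * sum_i Theta(R_i, R_{i+j}) where Theta averages the
    squared differences of standardized hydrophobicity, hydrophilicity and
    side-chain mass.  Always nonnegative; zero for homopolymers.
    """
    if property_set is None:
        property_set = _STANDARDIZED_PROPERTIES
    L = len(sequence)
    if not 1 <= j < L:
        raise ValueError(f"tier j={j} out of range for sequence of length {L}")
    total = sum(_theta_pair(sequence[i], sequence[i + j], property_set) for i in range(L - j))
    return total / (L - j)


def pseaac_descriptor(
    sequence: str,
    params: PseAACParams | None = None,
    protein_id: str = "",
    unknown_residues: str = "strict",
) -> ProteinDescriptor:
    """Pseudo amino acid composition of a sequence.

    The first 20 entries are amino-acid frequencies F_mu and the last q
    entries are the weighted correlation factors w*theta_j, all divided by
    the common denominator sum(F) + w*sum(theta), so the vector is a
    partition of 1 with nonnegative components.

    ``unknown_residues``: "strict" rejects any residue outside the 20
    standard ones; "skip" drops them before computing the composition.
    """
    if params is None:
        params = PseAACParams()
    if unknown_residues == "skip":
        sequence = "".join(r for r in sequence if r in params.property_set)
    else:
        bad = sorted({r for r in sequence if r not in params.property_set})
        if bad:
            raise ValueError(f"unknown residues {bad} (strict mode)")
    L = len(sequence)
    if L <= params.q:
        raise ValueError(f"sequence length {L} must exceed q={params.q}")
    freqs = np.array([sequence.count(a) for a in AA_ORDER], dtype=float) / L
    thetas = np.array(
        [sequence_correlation_factor(sequence, j, params.property_set) for j in range(1, params.q + 1)]
    )
    denom = freqs.sum() + params.w * thetas.sum()
    values = np.concatenate([freqs, params.w * thetas]) / denom
    return ProteinDescriptor(protein_id=protein_id, values=values, method="pseaac")


# ---------------------------------------------------------------------------
# Sequence and descriptor I/O


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence map."""
    from Bio import SeqIO

    return {record.id: str(record.seq) for record in SeqIO.parse(str(path), "fasta")}


def write_descriptor_table(descriptors: list[ProteinDescriptor], path) -> None:
    """Write descriptors as TSV: id, then one column per component."""
    with open(path, "wt", encoding="utf-8") as fh:
        for d in descriptors:
            fh.write(d.protein_id + "\t" + "\t".join(repr(float(v)) for v in d.values) + "\n")


def read_descriptor_table(path, method: str = "dct") -> dict[str, ProteinDescriptor]:
    """Read a descriptor TSV back into an id -> descriptor map."""
    out: dict[str, ProteinDescriptor] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            out[fields[0]] = ProteinDescriptor(
                protein_id=fields[0],
                values=np.array([float(v) for v in fields[1:]]),
                method=method,
            )
    return out


def psiblast_command(
    query_fasta: str,
    database: str,
    out_ascii_pssm: str,
    evalue: float = 0.001,
    iterations: int = 3,
) -> str:
    """Shell command that would generate the PSSM for one protein.

    Profiles are built by iterative PSI-BLAST search (e-value 0.001, three
    iterations) against a curated database such as SwissProt supplied by the
    user.  This helper only formats the command; nothing here executes it.
    """
    return shlex.join(
        [
            "psiblast",
            "-query", query_fasta,
            "-db", database,
            "-evalue", str(evalue),
            "-num_iterations", str(iterations),
            "-out_ascii_pssm", out_ascii_pssm,
        ]
    )
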