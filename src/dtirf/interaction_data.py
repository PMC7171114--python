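"""Bipartite drug-target interaction networks and balanced pair sampling.

A DTI benchmark is a bipartite graph: drugs on one side, protein targets on
the other, with an edge for every experimentally verified interaction.  All
drug x target pairs form the candidate space; pairs with a known interaction
are positives, every other pair is (putatively) negative.  Because the
networks are sparse, negatives vastly outnumber positives, so training sets
are built by down-sampling the negatives to the positive count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InteractionNetwork",
    "LabeledPairSet",
    "load_interaction_matrix",
    "write_interaction_matrix",
    "write_edgelist",
    "enumerate_negatives",
    "sample_balanced_pairs",
]


class InteractionDataError(ValueError):
    """Raised on malformed network files or invalid sampling requests."""


@dataclass
class InteractionNetwork:
    """Bipartite drug-target network.

    Parameters
    ----------
    drug_ids, target_ids
        Ordered identifier lists.  Ids are opaque strings; order is the
        order they were read in and is preserved by the writers.
    positives
        Set of ``(drug_id, target_id)`` pairs with a known interaction.
    """

    drug_ids: list[str]
    target_ids: list[str]
    positives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise InteractionDataError("duplicate drug ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise InteractionDataError("duplicate target ids")
        drugs, targets = set(self.drug_ids), set(self.target_ids)
        for d, t in self.positives:
            if d not in drugs:
                raise InteractionDataError(f"positive pair references unknown drug {d!r}")
            if t not in targets:
                raise InteractionDataError(f"positive pair references unknown target {t!r}")

    @property
    def n_candidates(self) -> int:
        """Size of the full candidate space |drugs| x |targets|."""
        return len(self.drug_ids) * len(self.target_ids)

    def candidate_pairs(self) -> list[tuple[str, str]]:
        """All drug x target pairs, drug-major in id-list order."""
        return [(d, t) for d in self.drug_ids for t in self.target_ids]


@dataclass
class LabeledPairSet:
    """Balanced labelled sample: all positives plus an equal number of
    down-sampled negatives."""

    pairs: list[tuple[str, str]]
    labels: np.ndarray
    sampling_seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.pairs) != len(self.labels):
            raise InteractionDataError("pairs and labels length mismatch")
        if len(set(self.pairs)) != len(self.pairs):
            raise InteractionDataError("duplicate pairs in labelled set")

    def __len__(self) -> int:
        return len(self.pairs)


def load_interaction_matrix(
    path, dialect: str = "adjacency", transpose: bool = False
) -> InteractionNetwork:
    """Read an interaction network from a TSV file.

    ``adjacency`` dialect follows the Yamanishi gold-standard distribution
    files: a header row of drug ids, then one row per target whose first
    column is the target id and whose cells are 0/1.  ``transpose`` flips
    that convention (rows = drugs).  ``edgelist`` is a two-column TSV of
    ``drug_id<TAB>target_id`` lines, one positive pair per line.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if dialect == "adjacency":
        return _parse_adjacency(lines, transpose=transpose)
    if dialect == "edgelist":
        return _parse_edgelist(lines)
    raise InteractionDataError(f"unknown dialect {dialect!r}")


def _parse_adjacency(lines: list[str], transpose: bool) -> InteractionNetwork:
    if not lines:
        raise InteractionDataError("empty adjacency file")
    header = lines[0].split("\t")
    # header may or may not carry a corner label; cells decide the width
    col_ids = [c for c in header if c != ""]
    row_ids: list[str] = []
    cells: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        row_ids.append(fields[0])
        if len(fields) - 1 != len(col_ids):
            raise InteractionDataError(
                f"row {lineno}: expected {len(col_ids)} cells, got {len(fields) - 1}"
            )
        row = []
        for j, cell in enumerate(fields[1:]):
            if cell not in ("0", "1"):
                raise InteractionDataError(
                    f"row {lineno}, column {col_ids[j]!r}: cell {cell!r} is not 0/1"
                )
            row.append(int(cell))
        cells.append(row)
    if transpose:
        drug_ids, target_ids = row_ids, col_ids
        positives = {
            (d, t) for i, d in enumerate(row_ids) for j, t in enumerate(col_ids) if cells[i][j]
        }
    else:
        drug_ids, target_ids = col_ids, row_ids
        positives = {
            (d, t) for j, d in enumerate(col_ids) for i, t in enumerate(row_ids) if cells[i][j]
        }
    return InteractionNetwork(drug_ids, target_ids, positives)


def _parse_edgelist(lines: list[str]) -> InteractionNetwork:
    drug_ids: list[str] = []
    target_ids: list[str] = []
    positives: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise InteractionDataError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        d, t = fields
        if d not in drug_ids:
            drug_ids.append(d)
        if t not in target_ids:
            target_ids.append(t)
        positives.add((d, t))
    return InteractionNetwork(drug_ids, target_ids, positives)


def write_interaction_matrix(network: InteractionNetwork, path) -> None:
    """Write the adjacency TSV dialect (rows = targets, columns = drugs)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(network.drug_ids) + "\n")
        for t in network.target_ids:
            row = ["1" if (d, t) in network.positives else "0" for d in network.drug_ids]
            fh.write(t + "\t" + "\t".join(row) + "\n")


def write_edgelist(network: InteractionNetwork, path) -> None:
    """Write positives as a two-column edge list, drug-major in id order."""
    with open(path, "wt", encoding="utf-8") as fh:
        for d in network.drug_ids:
            for t in network.target_ids:
                if (d, t) in network.positives:
                    fh.write(f"{d}\t{t}\n")


def enumerate_negatives(network: InteractionNetwork) -> set[tuple[str, str]]:
    """All candidate pairs without a known interaction."""
    return {p for p in network.candidate_pairs() if p not in network.positives}


def sample_balanced_pairs(network: InteractionNetwork, seed: int) -> LabeledPairSet:
    """Down-sample negatives to the positive count, forming a balanced set.

    Negatives are drawn uniformly without replacement from the full
    negative pool; the draw is deterministic for a fixed ``seed``.
    Positives are listed first (drug-major id order), then the sampled
    negatives in pool order.
    """
    positives = [p for p in network.candidate_pairs() if p in network.positives]
    negative_pool = [p for p in network.candidate_pairs() if p not in network.positives]
    n_pos = len(positives)
    if len(negative_pool) < n_pos:
        raise InteractionDataError(
            f"cannot sample {n_pos} negatives from a pool of {len(negative_pool)}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(negative_pool), size=n_pos, replace=False))
    negatives = [negative_pool[i] for i in idx]
    assert not set(negatives) & network.positives
    pairs = positives + negatives
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_pos, dtype=int)])
    return LabeledPairSet(pairs=pairs, labels=labels, sampling_seed=seed)
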