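"""Reading and writing the pipeline's standard formats.

Sequences arrive as FASTA (DNA or RNA alphabet; normalized to A/C/G/U),
interactions as delimited pair tables, and predictions leave as ranked
delimited tables.  Known interactions are held in a binary circRNA x miRNA
association matrix ``A`` with ``A[i, j] = 1`` for an observed interaction
and 0 for an unobserved (presumed negative) cell.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("circmi")

_CANONICAL = frozenset("ACGU")
_HEADER_NAMES = frozenset(
    {
        "circ", "circrna", "circ_id", "circrna_id",
        "mi", "mirna", "mi_id", "mirna_id",
        "label", "score", "id",
    }
)


@dataclass(frozen=True)
class RnaRecord:
    """One identified RNA molecule, normalized to the A/C/G/U alphabet."""

    id: str
    molecule_class: str  # "circRNA" | "miRNA"
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("RnaRecord id must be non-empty")
        if self.molecule_class not in ("circRNA", "miRNA"):
            raise ValueError(f"unknown molecule_class {self.molecule_class!r}")
        if len(self.sequence) < 1:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical bases {sorted(bad)} after normalization"
            )


@dataclass
class InteractionTable:
    """Deduplicated (circ_id, mi_id, label) triples with a provenance tag."""

    pairs: list[tuple[str, str, int]]
    provenance: str = "observed"

    def __post_init__(self) -> None:
        keys = [(c, m) for c, m, _ in self.pairs]
        if len(keys) != len(set(keys)):
            raise ValueError("InteractionTable contains duplicate (circ, mi) pairs")

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [(c, m) for c, m, y in self.pairs if y == 1]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AssociationMatrix:
    """Binary association matrix A (n_circ x n_mi) with id indexes."""

    A: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    row_index: dict[str, int] = field(repr=False, default_factory=dict)
    col_index: dict[str, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValueError("duplicate circRNA ids in association matrix")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ValueError("duplicate miRNA ids in association matrix")
        if not self.row_index:
            self.row_index = {r: i for i, r in enumerate(self.row_ids)}
        if not self.col_index:
            self.col_index = {c: j for j, c in enumerate(self.col_ids)}

    @property
    def n_interactions(self) -> int:
        return int(self.A.sum())


def _normalize_sequence(
    raw: str,
    record_id: str,
    ambiguous: str,
    rng: np.random.Generator | None,
) -> str | None:
    """Uppercase, T->U; returns None if the record should be dropped."""
    seq = raw.upper().replace("T", "U")
    bad_positions = [i for i, b in enumerate(seq) if b not in _CANONICAL]
    if not bad_positions:
        return seq
    if ambiguous == "drop":
        logger.warning(
            "dropping record %s: %d ambiguous base(s)", record_id, len(bad_positions)
        )
        return None
    if ambiguous == "randomize":
        if rng is None:
            raise ValueError("ambiguous='randomize' requires a seed")
        bases = list(seq)
        draws = rng.choice(list("ACGU"), size=len(bad_positions))
        for pos, b in zip(bad_positions, draws):
            bases[pos] = str(b)
        return "".join(bases)
    raise ValueError(f"unknown ambiguous-base policy {ambiguous!r}")


def read_fasta(
    path: str | Path,
    molecule_class: str,
    ambiguous: str = "drop",
    seed: int | None = None,
) -> list[RnaRecord]:
    """Read a FASTA file into :class:`RnaRecord` objects.

    ``ambiguous`` chooses the policy for non-ACGU(T) bases: ``"drop"``
    discards the record with a warning, ``"randomize"`` replaces each
    offending base with a random canonical base under ``seed``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rng = np.random.default_rng(seed) if seed is not None else None
    records: list[RnaRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = _normalize_sequence(str(entry.seq), entry.id, ambiguous, rng)
        if seq is None:
            continue
        records.append(RnaRecord(id=entry.id, molecule_class=molecule_class, sequence=seq))
    if not seen:
        raise ValueError(f"no FASTA entries found in {path}")
    logger.info("read %d %s record(s) from %s", len(records), molecule_class, path)
    return records


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _looks_like_header(fields: list[str]) -> bool:
    # a header row is made of known column names, never of record ids
    return any(f.strip().lower() in _HEADER_NAMES for f in fields)


def read_pairs(path: str | Path) -> InteractionTable:
    """Read a TSV/CSV pair table: circ_id, mi_id[, label].

    A missing label column means every pair is a positive (label 1).
    Duplicate (circ, mi) rows keep the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty pair table {path}")
    delim = _sniff_delimiter(lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    start = 1 if _looks_like_header(rows[0]) else 0
    pairs: list[tuple[str, str, int]] = []
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for lineno, fields in enumerate(rows[start:], start=start + 1):
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(fields)}")
        circ, mi = fields[0].strip(), fields[1].strip()
        if len(fields) >= 3 and fields[2].strip() != "":
            label_str = fields[2].strip()
            if label_str not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {label_str!r}")
            label = int(label_str)
        else:
            label = 1
        key = (circ, mi)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        pairs.append((circ, mi, label))
    if start == 1 and not pairs:
        raise ValueError(f"pair table {path} has a header but no data rows")
    logger.info("read %d pair(s) from %s (%d duplicate(s) dropped)", len(pairs), path, n_dup)
    return InteractionTable(pairs=pairs, provenance="observed")


def build_association_matrix(
    records_circ: list[RnaRecord],
    records_mi: list[RnaRecord],
    table: InteractionTable,
) -> AssociationMatrix:
    """Build the binary association matrix from positive pairs.

    ``A[i, j] = 1`` exactly for the positive pairs of ``table``; every other
    cell is 0 (no known interaction).  Label-0 rows in the table do not set
    matrix entries.
    """
    row_ids = [r.id for r in records_circ]
    col_ids = [r.id for r in records_mi]
    assoc = AssociationMatrix(
        A=np.zeros((len(row_ids), len(col_ids)), dtype=np.int8),
        row_ids=row_ids,
        col_ids=col_ids,
    )
    for circ, mi in table.positives:
        if circ not in assoc.row_index:
            raise KeyError(f"unknown circRNA id {circ!r} in pair table")
        if mi not in assoc.col_index:
            raise KeyError(f"unknown miRNA id {mi!r} in pair table")
        assoc.A[assoc.row_index[circ], assoc.col_index[mi]] = 1
    return assoc


def write_predictions(
    pairs: list[tuple[str, str]],
    scores: np.ndarray | list[float],
    path: str | Path,
) -> None:
    """Write a ranked prediction table (descending score), TSV with header."""
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(pairs):
        raise ValueError(f"{len(pairs)} pairs but {len(scores)} scores")
    frame = pd.DataFrame(
        {
            "circRNA_id": [c for c, _ in pairs],
            "miRNA_id": [m for _, m in pairs],
            "score": scores,
        }
    )
    frame = frame.sort_values("score", ascending=False, kind="stable")
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t")


def write_pairs(table: InteractionTable, path: str | Path) -> None:
    """Write an interaction table as TSV (circ_id, mi_id, label)."""
    with open(path, "w") as fh:
        for circ, mi, label in table.pairs:
            fh.write(f"{circ}\t{mi}\t{label}\n")


def write_fasta(records: list[RnaRecord], path: str | Path) -> None:
    """Write records as plain FASTA (one line per sequence)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")
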