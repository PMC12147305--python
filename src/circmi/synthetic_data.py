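"""Synthetic circRNA/miRNA benchmark with a planted interaction rule.

The generator emulates a sponge-style interaction screen: miRNAs and
circRNA backbones are drawn uniformly over A/C/G/U, a set of positive
(circ, mi) cells is chosen at a target density, and for each positive pair
the reverse complement of the miRNA seed (positions 2-8, 7 nt) is embedded
at a random position of the circRNA.  At label noise 0 a pair is positive
iff its circRNA contains the seed's reverse complement (up to chance 7-mer
collisions in the random background, which are left in deliberately).

Label noise epsilon is swap noise: an epsilon-fraction of planted positives
is relabeled 0 and replaced by an equal number of random unplanted cells
labeled 1, keeping the positive count at the target density while creating
both false positives and false negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from circmi.io_formats import InteractionTable, RnaRecord, write_fasta, write_pairs

logger = logging.getLogger("circmi")

_BASES = np.array(list("ACGU"))
_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticConfig:
    n_circ: int = 300
    n_mi: int = 100
    circ_len_range: tuple[int, int] = (300, 1500)
    mi_len_range: tuple[int, int] = (20, 24)
    seed_region: tuple[int, int] = (2, 8)  # 1-based inclusive miRNA positions
    planting_prob: float = 1.0
    label_noise: float = 0.05
    target_density: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.planting_prob, self.label_noise, self.target_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.n_circ < 2 or self.n_mi < 2:
            raise ValueError("entity counts must be >= 2")
        for lo, hi in (self.circ_len_range, self.mi_len_range):
            if lo <= 0 or hi < lo:
                raise ValueError("length ranges must be positive and ordered")
        lo, hi = self.seed_region
        if lo < 1 or hi < lo:
            raise ValueError("seed region must be a valid 1-based range")
        if hi > self.mi_len_range[0]:
            raise ValueError("seed region exceeds the shortest miRNA")


@dataclass
class SyntheticDataset:
    circ_records: list[RnaRecord]
    mi_records: list[RnaRecord]
    positives: InteractionTable
    truth: pd.DataFrame  # circ_id, mi_id, planted (per designated cell)
    config: SyntheticConfig

    def to_dataset(self):
        """View as a :class:`circmi.pipeline.CmiDataset` for evaluation."""
        from circmi.pipeline import CmiDataset

        return CmiDataset(
            records_circ=self.circ_records,
            records_mi=self.mi_records,
            positives=self.positives,
        )

    def write(self, directory: str | Path) -> None:
        """Emit the exact formats the io layer consumes, plus the truth table."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_fasta(self.circ_records, directory / "circ.fasta")
        write_fasta(self.mi_records, directory / "mi.fasta")
        write_pairs(self.positives, directory / "pairs.tsv")
        self.truth.to_csv(directory / "truth.tsv", sep="\t", index=False)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _seed_of(mi_seq: str, region: tuple[int, int]) -> str:
    lo, hi = region
    return mi_seq[lo - 1 : hi]


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a fully seeded benchmark dataset."""
    rng = np.random.default_rng(config.rng_seed)
    n_cells = config.n_circ * config.n_mi
    n_pos = int(round(config.target_density * n_cells))
    if n_pos < 1 or n_pos > n_cells:
        raise ValueError(
            f"target density {config.target_density} infeasible for "
            f"{config.n_circ} x {config.n_mi} cells"
        )

    mi_records = []
    for j in range(config.n_mi):
        length = int(rng.integers(config.mi_len_range[0], config.mi_len_range[1] + 1))
        mi_records.append(
            RnaRecord(id=f"mi-{j:04d}", molecule_class="miRNA", sequence=_random_seq(rng, length))
        )
    circ_seqs = []
    for i in range(config.n_circ):
        length = int(rng.integers(config.circ_len_range[0], config.circ_len_range[1] + 1))
        circ_seqs.append(_random_seq(rng, length))

    planted_cells = rng.choice(n_cells, size=n_pos, replace=False)
    planted_set: set[tuple[int, int]] = set()
    occupied: dict[int, list[tuple[int, int]]] = {}
    for cell in planted_cells:
        i, j = int(cell) // config.n_mi, int(cell) % config.n_mi
        planted_set.add((i, j))
        if rng.random() < config.planting_prob:
            motif = reverse_complement(_seed_of(mi_records[j].sequence, config.seed_region))
            seq = circ_seqs[i]
            taken = occupied.setdefault(i, [])
            # avoid overwriting a motif planted for another partner of this circRNA
            for _ in range(50):
                pos = int(rng.integers(0, len(seq) - len(motif) + 1))
                if all(pos + len(motif) <= lo or pos >= hi for lo, hi in taken):
                    break
            else:
                logger.warning("no free window on %s; motif overlaps", f"circ-{i:04d}")
            taken.append((pos, pos + len(motif)))
            circ_seqs[i] = seq[:pos] + motif + seq[pos + len(motif) :]

    # swap noise: flip an eps-fraction of planted positives out, random cells in
    planted_list = sorted(planted_set)
    n_flip = int(round(config.label_noise * len(planted_list)))
    positives_set = set(planted_list)
    flipped_out: list[tuple[int, int]] = []
    flipped_in: list[tuple[int, int]] = []
    if n_flip:
        out_idx = rng.choice(len(planted_list), size=n_flip, replace=False)
        flipped_out = [planted_list[i] for i in out_idx]
        positives_set -= set(flipped_out)
        free = [
            (i, j)
            for i in range(config.n_circ)
            for j in range(config.n_mi)
            if (i, j) not in planted_set
        ]
        in_idx = rng.choice(len(free), size=n_flip, replace=False)
        flipped_in = [free[i] for i in in_idx]
        positives_set |= set(flipped_in)

    circ_records = [
        RnaRecord(id=f"circ-{i:04d}", molecule_class="circRNA", sequence=s)
        for i, s in enumerate(circ_seqs)
    ]
    positives = InteractionTable(
        pairs=[
            (circ_records[i].id, mi_records[j].id, 1)
            for i, j in sorted(positives_set)
        ],
        provenance="synthetic",
    )
    truth_cells = sorted(planted_set | set(flipped_in))
    truth = pd.DataFrame(
        {
            "circ_id": [circ_records[i].id for i, _ in truth_cells],
            "mi_id": [mi_records[j].id for _, j in truth_cells],
            "planted": [int((i, j) in planted_set) for i, j in truth_cells],
            "labeled_positive": [int((i, j) in positives_set) for i, j in truth_cells],
        }
    )
    logger.info(
        "synthetic dataset: %d circ x %d mi, %d positives (%d label flips)",
        config.n_circ,
        config.n_mi,
        len(positives),
        n_flip,
    )
    return SyntheticDataset(
        circ_records=circ_records,
        mi_records=mi_records,
        positives=positives,
        truth=truth,
        config=config,
    )


def motif_oracle(
    dataset: SyntheticDataset,
    pairs: list[tuple[str, str]] | None = None,
) -> np.ndarray:
    """Rule-based per-pair truth: does the circRNA contain the reverse
    complement of the miRNA seed?  Independent of the emitted labels; the
    Bayes-optimal reference for bounding pipeline performance."""
    circ_by_id = {r.id: r.sequence for r in dataset.circ_records}
    mi_by_id = {r.id: r.sequence for r in dataset.mi_records}
    if pairs is None:
        pairs = [(c, m) for c, m, _ in dataset.positives.pairs]
    region = dataset.config.seed_region
    out = np.zeros(len(pairs), dtype=bool)
    for n, (c, m) in enumerate(pairs):
        motif = reverse_complement(_seed_of(mi_by_id[m], region))
        out[n] = motif in circ_by_id[c]
    return out
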