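"""Sequence-divergence summaries for lineage delimitation.

Works on an aligned nucleotide set with group labels (e.g. the two
*Alpheus lottini* mitochondrial lineages): uncorrected pairwise p-distance
with pairwise deletion of gap/ambiguous sites, mean within- and
between-group distances, and Nei's net divergence

    Da = d_XY - (d_X + d_Y) / 2,

the between-group mean minus the average of the two within-group means.  A
Jukes-Cantor correction of the per-pair distances is available for
comparison with model-corrected software output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping

from Bio import SeqIO

__all__ = ["AlignedSeqSet", "p_distance", "jc69", "net_divergence"]

_VALID = set("ACGT")
_SKIP = set("-N")


def _clean(seq: str, name: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - _VALID - _SKIP
    if bad:
        raise ValueError(f"{name}: unexpected characters {sorted(bad)}")
    return s


def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing sites, excluding sites with a gap or N in
    either sequence (pairwise deletion)."""
    a, b = _clean(seq_a, "seq_a"), _clean(seq_b, "seq_b")
    if len(a) != len(b):
        raise ValueError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    compared = mismatch = 0
    for x, y in zip(a, b):
        if x in _SKIP or y in _SKIP:
            continue
        compared += 1
        mismatch += x != y
    if compared == 0:
        raise ValueError("no comparable sites (all gapped or ambiguous)")
    return mismatch / compared


def jc69(p: float) -> float:
    """Jukes-Cantor correction of a p-distance."""
    if p >= 0.75:
        raise ValueError(f"p-distance {p} saturates the Jukes-Cantor model")
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass
class AlignedSeqSet:
    """Equal-length aligned sequences with per-sequence group labels."""

    sequences: dict[str, str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
        for sid in self.groups:
            if sid not in self.sequences:
                raise ValueError(f"group label for unknown sequence {sid!r}")
        self.sequences = {k: _clean(v, k) for k, v in self.sequences.items()}

    @classmethod
    def from_fasta(
        cls, fasta: str | Path, groups: Mapping[str, str] | str | Path
    ) -> "AlignedSeqSet":
        """Load an aligned FASTA plus groups (mapping or TSV seq_id<TAB>group)."""
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")}
        if not isinstance(groups, Mapping):
            with open(groups, newline="") as fh:
                rows = list(csv.reader(fh, delimiter="\t"))
            if rows and rows[0][:2] == ["seq_id", "group"]:
                rows = rows[1:]
            groups = {r[0]: r[1] for r in rows if r}
        return cls(seqs, dict(groups))

    def members(self, group: str) -> list[str]:
        ids = [sid for sid, g in self.groups.items() if g == group]
        if not ids:
            raise ValueError(f"unknown group label {group!r}")
        return ids


def _mean_within(seqs: AlignedSeqSet, ids: list[str], correction) -> float:
    if len(ids) < 2:
        return 0.0  # convention: single-sequence group has zero within-distance
    pairs = list(combinations(ids, 2))
    return sum(
        correction(p_distance(seqs.sequences[a], seqs.sequences[b])) for a, b in pairs
    ) / len(pairs)


def net_divergence(
    seqs: AlignedSeqSet,
    group_x: str,
    group_y: str,
    correction: str = "none",
) -> float:
    """Nei's net between-group divergence Da on p-distances.

    ``correction="jc69"`` applies the Jukes-Cantor transform to every pairwise
    distance before averaging.  Groups with a single sequence contribute a
    within-group distance of 0.
    """
    corr = {"none": lambda p: p, "jc69": jc69}.get(correction)
    if corr is None:
        raise ValueError(f"unknown correction {correction!r}")
    xs, ys = seqs.members(group_x), seqs.members(group_y)
    # identical ids only arise when comparing a group with itself; skipping
    # them makes d_XX equal the within-group mean, hence Da(X, X) = 0
    pairs = [(a, b) for a in xs for b in ys if a != b]
    if not pairs:
        raise ValueError("no cross-group sequence pairs to compare")
    d_xy = sum(
        corr(p_distance(seqs.sequences[a], seqs.sequences[b])) for a, b in pairs
    ) / len(pairs)
    d_x = _mean_within(seqs, xs, corr)
    d_y = _mean_within(seqs, ys, corr)
    return d_xy - (d_x + d_y) / 2.0
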