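"""Gapped multiple-alignment container with group annotations.

Sequences are equal-length strings over {A, C, G, T, N, -}; each taxon carries
a group label (morphotype or species). Groups are the unit at which
between-group polymorphism and diagnostic markers are assessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

ALPHABET = frozenset("ACGTN-")
GAP = "-"


@dataclass
class AlignedSequenceSet:
    """An ordered, group-annotated multiple sequence alignment.

    Parameters
    ----------
    taxa:
        Taxon labels in display order.
    group_of:
        Mapping taxon -> group label; every taxon must be present.
    sequences:
        Mapping taxon -> aligned sequence (uppercase, gap character ``-``).
    """

    taxa: list[str]
    group_of: dict[str, str]
    sequences: dict[str, str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.taxa:
            raise InputError("alignment has no taxa")
        lengths = {len(self.sequences[t]) for t in self.taxa}
        if len(lengths) != 1:
            ragged = sorted(
                t for t in self.taxa if len(self.sequences[t]) != len(self.sequences[self.taxa[0]])
            )
            raise InputError(f"ragged alignment: sequence length differs for {ragged}")
        for t in self.taxa:
            if t not in self.group_of:
                raise InputError(f"taxon {t!r} has no group label")
            bad = set(self.sequences[t]) - ALPHABET
            if bad:
                raise InputError(f"unknown symbols {sorted(bad)} in sequence of {t!r}")

    @property
    def length(self) -> int:
        return len(self.sequences[self.taxa[0]])

    @property
    def groups(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.taxa:
            seen.setdefault(self.group_of[t], None)
        return list(seen)

    def taxa_in(self, group: str) -> list[str]:
        members = [t for t in self.taxa if self.group_of[t] == group]
        if not members:
            raise InputError(f"unknown group label {group!r}")
        return members

    def matrix(self) -> np.ndarray:
        """Character matrix of shape (n_taxa, length), dtype '<U1'.

        Cached; rows follow ``self.taxa`` order.
        """
        if self._matrix is None:
            self._matrix = np.array(
                [list(self.sequences[t]) for t in self.taxa], dtype="<U1"
            )
        return self._matrix

    def column(self, j: int) -> dict[str, str]:
        m = self.matrix()
        return {t: m[i, j] for i, t in enumerate(self.taxa)}
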