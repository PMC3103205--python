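"""Pedigree container and validation.

A pedigree is an ordered list of individuals with integer ids, parent ids
(0 = unknown), sex (M/F) and a generation label.  Parents must precede
their offspring, which also guarantees acyclicity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Pedigree", "PedigreeError"]


class PedigreeError(ValueError):
    """Raised when a pedigree violates a structural invariant."""


@dataclass
class Pedigree:
    """Ordered pedigree with parents preceding offspring.

    Parameters
    ----------
    ids : array of positive int
        Unique individual identifiers, in pedigree order.
    sire, dam : arrays of int
        Parent ids; 0 means unknown.
    sex : array of str
        'M' or 'F' per individual.
    generation : array of int
        Non-negative generation label per individual.
    """

    ids: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.sex = np.asarray(self.sex, dtype="U1")
        self.generation = np.asarray(self.generation, dtype=np.int64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}
        self.validate()

    # -- structural checks -------------------------------------------------

    def validate(self) -> None:
        n = len(self.ids)
        for arr, name in ((self.sire, "sire"), (self.dam, "dam"),
                          (self.sex, "sex"), (self.generation, "generation")):
            if len(arr) != n:
                raise PedigreeError(f"{name} length {len(arr)} != ids length {n}")
        if len(self._index) != n:
            raise PedigreeError("ids are not unique")
        if np.any(self.ids <= 0):
            raise PedigreeError("ids must be positive")
        if np.any(self.generation < 0):
            raise PedigreeError("generations must be non-negative")
        bad_sex = set(np.unique(self.sex)) - {"M", "F"}
        if bad_sex:
            raise PedigreeError(f"invalid sex codes: {sorted(bad_sex)}")
        seen: set[int] = set()
        for k in range(n):
            for pid, want in ((int(self.sire[k]), "M"), (int(self.dam[k]), "F")):
                if pid == 0:
                    continue
                if pid not in seen:
                    raise PedigreeError(
                        f"parent {pid} of {int(self.ids[k])} does not precede it")
                if self.sex[self._index[pid]] != want:
                    role = "sire" if want == "M" else "dam"
                    raise PedigreeError(
                        f"{role} {pid} of {int(self.ids[k])} has sex "
                        f"{self.sex[self._index[pid]]}")
            seen.add(int(self.ids[k]))

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual_id: int) -> int:
        return self._index[int(individual_id)]

    @property
    def sire_index(self) -> np.ndarray:
        """Row index of each individual's sire, -1 if unknown."""
        return np.array([self._index[s] if s else -1 for s in self.sire],
                        dtype=np.int64)

    @property
    def dam_index(self) -> np.ndarray:
        """Row index of each individual's dam, -1 if unknown."""
        return np.array([self._index[d] if d else -1 for d in self.dam],
                        dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)

    def offspring_of(self, parent_id: int) -> np.ndarray:
        """Row indices of all offspring of the given parent id."""
        return np.flatnonzero((self.sire == parent_id) | (self.dam == parent_id))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "id": self.ids, "sire": self.sire, "dam": self.dam,
            "sex": self.sex, "generation": self.generation,
        })
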