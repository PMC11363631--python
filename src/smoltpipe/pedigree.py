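"""Pedigree container shared by the simulator, the relationship-matrix builder
and the liability model.

A pedigree is a topologically ordered list of individuals: every parent
appears before any of its offspring, and unknown parents are recorded as
missing (written as ``0`` in the TSV representation, the convention of
most animal-breeding software).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

UNKNOWN = -1

PEDIGREE_COLUMNS = ["id", "sire", "dam", "family", "cross", "strain", "role"]


class PedigreeError(ValueError):
    """Raised for unordered, cyclic or otherwise invalid pedigrees."""


@dataclass
class Pedigree:
    """Ordered pedigree with integer parent pointers.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, ancestors first.
    sire, dam : ndarray of int
        Index of each parent within ``ids``; ``-1`` when unknown.
    family, cross, strain, role : list of str
        Grouping labels.  ``role`` distinguishes ``founder``, ``f1``
        (intermediate hybrid parents) and ``offspring`` (phenotyped fish).
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    family: list[str]
    cross: list[str]
    strain: list[str]
    role: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self._index = {s: i for i, s in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            dup = pd.Series(self.ids).duplicated()
            raise PedigreeError(f"duplicate id: {self.ids[int(np.argmax(dup.values))]!r}")
        self.validate()

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` (any iterable of str) in pedigree order."""
        try:
            return np.array([self._index[s] for s in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise PedigreeError(f"id {exc.args[0]!r} not in pedigree") from None

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def validate(self) -> None:
        """Check topological order; implies acyclicity."""
        n = self.n
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if par.shape != (n,):
                raise PedigreeError(f"{name} array has wrong length")
            bad = (par >= np.arange(n)) & (par != UNKNOWN)
            if bad.any():
                i = int(np.argmax(bad))
                raise PedigreeError(
                    f"pedigree not ancestor-ordered: {name} of {self.ids[i]!r} "
                    f"does not precede it"
                )
            if ((par < UNKNOWN)).any():
                raise PedigreeError(f"negative {name} index other than -1")

    def to_frame(self) -> pd.DataFrame:
        def name(idx: np.ndarray) -> list[str]:
            return ["0" if j == UNKNOWN else self.ids[j] for j in idx]

        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": name(self.sire),
                "dam": name(self.dam),
                "family": self.family,
                "cross": self.cross,
                "strain": self.strain,
                "role": self.role,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        required = {"id", "sire", "dam"}
        missing = required - set(df.columns)
        if missing:
            raise PedigreeError(f"pedigree table lacks columns: {sorted(missing)}")
        ids = [str(s) for s in df["id"]]
        index = {s: i for i, s in enumerate(ids)}

        def resolve(col: str) -> np.ndarray:
            out = np.empty(len(ids), dtype=np.int64)
            for i, raw in enumerate(df[col]):
                s = str(raw)
                if s in ("0", "", "nan", "NA", "."):
                    out[i] = UNKNOWN
                elif s in index:
                    out[i] = index[s]
                else:
                    raise PedigreeError(f"row {i + 1}: unknown {col} {s!r}")
            return out

        def opt(col: str) -> list[str]:
            if col in df.columns:
                return [str(s) for s in df[col]]
            return [""] * len(ids)

        return cls(
            ids=ids,
            sire=resolve("sire"),
            dam=resolve("dam"),
            family=opt("family"),
            cross=opt("cross"),
            strain=opt("strain"),
            role=opt("role"),
        )
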