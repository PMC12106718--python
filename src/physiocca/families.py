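"""Family structure and restricted (exchangeability-block) permutations.

Twin cohorts violate the independence assumption of naive permutation
tests: members of one family share genetic and environmental influences.
The restricted scheme used throughout this package permutes whole
families among families of identical size, keeping the within-family
member order fixed.  Families of size one therefore reduce the scheme to
an unrestricted permutation, and a cohort where some size class contains
a single family simply leaves that family in place.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


@dataclass
class FamilyStructure:
    """Participant -> family assignment with optional zygosity labels."""

    table: pd.DataFrame  # columns: participant, family_id, zygosity

    def __post_init__(self) -> None:
        required = {"participant", "family_id"}
        if not required.issubset(self.table.columns):
            raise InvalidArgumentError("family table needs participant and family_id")
        if self.table["participant"].duplicated().any():
            raise InvalidArgumentError("a participant appears in two families")
        if "zygosity" not in self.table.columns:
            self.table = self.table.assign(zygosity="NT")

    @classmethod
    def from_series(cls, family_of: pd.Series, zygosity: pd.Series | None = None
                    ) -> "FamilyStructure":
        df = pd.DataFrame({"participant": family_of.index.astype(str),
                           "family_id": family_of.values})
        if zygosity is not None:
            df["zygosity"] = zygosity.reindex(family_of.index).values
        return cls(df)

    def family_ids_for(self, roster) -> np.ndarray:
        mapping = self.table.set_index("participant")["family_id"]
        roster = pd.Index(map(str, roster))
        missing = roster.difference(mapping.index)
        if len(missing):
            raise InvalidArgumentError(f"participants without family: {list(missing)[:5]}")
        return mapping.loc[roster].to_numpy()

    def mz_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        mz = self.table[self.table["zygosity"] == "MZ"]
        for _, grp in mz.groupby("family_id"):
            ids = list(grp["participant"])
            if len(ids) == 2:
                pairs.append(tuple(ids))
        return pairs


class BlockPermuter:
    """Precompiled family-blocked permutation generator for one roster.

    Permutations swap whole families among families of equal size;
    member order within a family is preserved.
    """

    def __init__(self, family_ids: np.ndarray):
        family_ids = np.asarray(family_ids)
        self.n = family_ids.size
        fams: dict = {}
        for i, f in enumerate(family_ids):
            fams.setdefault(f, []).append(i)
        by_size: dict[int, list[list[int]]] = {}
        for members in fams.values():
            by_size.setdefault(len(members), []).append(members)
        self._groups = []  # (member index matrix n_fam x size) per size class
        movable = False
        for size, fam_list in sorted(by_size.items()):
            block = np.asarray(fam_list)  # (n_fam, size)
            self._groups.append(block)
            if len(fam_list) > 1:
                movable = True
        if not movable and self.n > 1:
            warnings.warn("no two families share a size; falling back to "
                          "unrestricted permutation", stacklevel=2)
            self._groups = [np.arange(self.n).reshape(-1, 1)]

    def permutation(self, rng: np.random.Generator) -> np.ndarray:
        """One permutation as an index array ``perm`` (row i takes old row perm[i])."""
        perm = np.empty(self.n, dtype=np.intp)
        for block in self._groups:
            order = rng.permutation(block.shape[0])
            perm[block.ravel()] = block[order].ravel()
        return perm

    def permutations(self, n_perm: int, rng: np.random.Generator) -> np.ndarray:
        """(n_perm, n) batch of independent blocked permutations."""
        return np.stack([self.permutation(rng) for _ in range(n_perm)])
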