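"""Pedigree of F1 hybrids: each F1 maps to a (mother, father) cross."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class Pedigree:
    """F1 sample ids with their maternal and paternal parent ids.

    Every (mother, father) pair is unique: an NC-II factorial produces at
    most one F1 per cross.
    """

    f1_ids: list[str]
    mother: list[str]
    father: list[str]

    def __post_init__(self) -> None:
        n = len(self.f1_ids)
        if len(self.mother) != n or len(self.father) != n:
            raise ValueError("f1_ids, mother and father must have equal length")
        if len(set(self.f1_ids)) != n:
            raise ValueError("duplicate F1 ids in pedigree")
        pairs = set(zip(self.mother, self.father))
        if len(pairs) != n:
            raise ValueError("duplicate (mother, father) cross in pedigree")

    def __len__(self) -> int:
        return len(self.f1_ids)

    @property
    def mothers(self) -> list[str]:
        """Distinct maternal ids, in first-appearance order."""
        return list(dict.fromkeys(self.mother))

    @property
    def fathers(self) -> list[str]:
        """Distinct paternal (tester) ids, in first-appearance order."""
        return list(dict.fromkeys(self.father))

    def parents_of(self, f1_id: str) -> tuple[str, str]:
        i = self.f1_ids.index(f1_id)
        return self.mother[i], self.father[i]

    def subset(self, f1_ids: list[str]) -> "Pedigree":
        idx = {s: i for i, s in enumerate(self.f1_ids)}
        rows = [idx[s] for s in f1_ids]
        return Pedigree(
            [self.f1_ids[i] for i in rows],
            [self.mother[i] for i in rows],
            [self.father[i] for i in rows],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"f1_id": self.f1_ids, "mother": self.mother, "father": self.father}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            df["f1_id"].astype(str).tolist(),
            df["mother"].astype(str).tolist(),
            df["father"].astype(str).tolist(),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Pedigree":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
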