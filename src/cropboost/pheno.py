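"""Phenotype handling: within-group z-scores, general combining ability,
and quantile class labels for classification tasks.

A hybrid population bred as paternal half-sib families (thirty tester
families in the motivating design) shows systematic mean differences
between families; z-scoring within each family removes that bias so that
relative rankings carry the signal. General combining ability (GCA) of a
parent is its offspring mean minus the grand offspring mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree


@dataclass
class PhenotypeTable:
    """One row per sample, one column per trait; NaN marks missing."""

    sample_ids: list[str]
    trait_names: list[str]
    values: np.ndarray
    group: list[str] | None = None
    observed: np.ndarray | None = None  # False for model-predicted rows

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        n, t = len(self.sample_ids), len(self.trait_names)
        if self.values.shape != (n, t):
            raise ValueError("values shape does not match ids/traits")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.trait_names)) != t:
            raise ValueError("duplicate trait names")
        if self.group is not None and len(self.group) != n:
            raise ValueError("group length mismatch")
        if self.observed is not None:
            self.observed = np.asarray(self.observed, dtype=bool)
            if len(self.observed) != n:
                raise ValueError("observed length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def trait(self, name: str) -> np.ndarray:
        return self.values[:, self.trait_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.trait_names)
        df.index.name = "sample_id"
        if self.group is not None:
            df["group"] = self.group
        if self.observed is not None:
            df["observed"] = self.observed
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeTable":
        group = df["group"].astype(str).tolist() if "group" in df else None
        observed = df["observed"].to_numpy() if "observed" in df else None
        traits = [c for c in df.columns if c not in ("group", "observed")]
        return cls(df.index.astype(str).tolist(), traits,
                   df[traits].to_numpy(dtype=float), group, observed)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "PhenotypeTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", index_col="sample_id"))


@dataclass
class GCATable:
    """Per-parent general combining ability and offspring counts."""

    parent_ids: list[str]
    gca: np.ndarray
    n_offspring: np.ndarray

    def __post_init__(self) -> None:
        self.gca = np.asarray(self.gca, dtype=float)
        self.n_offspring = np.asarray(self.n_offspring, dtype=int)
        if (self.n_offspring < 1).any():
            raise ValueError("every listed parent needs >= 1 offspring")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parent_id": self.parent_ids, "gca": self.gca,
                             "n_offspring": self.n_offspring})


def zscore_by_group(P: PhenotypeTable, trait: str,
                    groups: list[str] | None = None) -> PhenotypeTable:
    """Normalise one trait to z-scores within each group.

    The sample standard deviation (denominator n-1) is used. Groups default
    to ``P.group``. A group with fewer than two non-missing values, or zero
    variance, cannot be standardised and raises with the group named.
    """
    if groups is None:
        groups = P.group
    if groups is None:
        groups = ["all"] * P.n_samples
    t = P.trait_names.index(trait)
    out = P.values.copy()
    col = out[:, t]
    for g in dict.fromkeys(groups):
        rows = np.array([i for i, gi in enumerate(groups) if gi == g])
        vals = col[rows]
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            raise ValueError(
                f"group {g!r} has {int(ok.sum())} non-missing values for "
                f"{trait!r}; need at least 2")
        mu = vals[ok].mean()
        sd = vals[ok].std(ddof=1)
        if sd == 0:
            raise ValueError(f"group {g!r} is constant for {trait!r} (sd=0)")
        col[rows] = (vals - mu) / sd
    return PhenotypeTable(list(P.sample_ids), list(P.trait_names), out,
                          P.group, P.observed)


def compute_gca(P: PhenotypeTable, pedigree: Pedigree, side: str,
                trait: str) -> GCATable:
    """GCA_i = mean(trait over parent i's F1 offspring) - mean(all F1s in P).

    ``side`` selects the maternal or paternal parent. Parents with no
    offspring in ``P`` are excluded with a warning. Missing trait values are
    ignored in both means.
    """
    if side not in ("mother", "father"):
        raise ValueError("side must be 'mother' or 'father'")
    parent_of = dict(zip(pedigree.f1_ids,
                         pedigree.mother if side == "mother"
                         else pedigree.father))
    y = P.trait(trait)
    offspring: dict[str, list[float]] = {}
    all_vals = []
    for sid, v in zip(P.sample_ids, y):
        if sid not in parent_of:
            raise ValueError(f"F1 {sid!r} not in pedigree")
        if np.isnan(v):
            continue
        offspring.setdefault(parent_of[sid], []).append(v)
        all_vals.append(v)
    grand_mean = float(np.mean(all_vals))
    parents = (pedigree.mothers if side == "mother" else pedigree.fathers)
    missing_parents = [p for p in parents if p not in offspring]
    if missing_parents:
        warnings.warn(
            f"{len(missing_parents)} {side}(s) have no phenotyped offspring "
            "and are excluded", stacklevel=2)
    kept = [p for p in parents if p in offspring]
    gca = np.array([np.mean(offspring[p]) - grand_mean for p in kept])
    n_off = np.array([len(offspring[p]) for p in kept])
    return GCATable(kept, gca, n_off)


def label_quantiles(values: np.ndarray, low_cut: float = 0.25,
                    high_cut: float = 0.75,
                    sample_ids: list[str] | None = None) -> np.ndarray:
    """Assign each sample to {low, mid, high} by empirical quantile rank.

    Ranks are computed with a stable sort on (value, sample id) so tied
    values receive deterministic class assignments; the lowest
    ``floor(low_cut*n)`` ranks are "low" and the highest
    ``n - floor(high_cut*n)`` ranks are "high".
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if not 0 < low_cut < high_cut < 1:
        raise ValueError("need 0 < low_cut < high_cut < 1")
    if n < 4:
        raise ValueError("need at least 4 samples for quantile classes")
    if np.isnan(values).any():
        raise ValueError("missing values not allowed in label_quantiles")
    if np.ptp(values) == 0:
        raise ValueError("constant values: no quantile separation")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (values[i], sample_ids[i]))
    n_low = int(np.floor(low_cut * n))
    n_high = n - int(np.floor(high_cut * n))
    labels = np.empty(n, dtype="<U4")
    for rank, i in enumerate(order):
        if rank < n_low:
            labels[i] = "low"
        elif rank >= n - n_high:
            labels[i] = "high"
        else:
            labels[i] = "mid"
    return labels
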