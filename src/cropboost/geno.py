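"""Diploid SNP genotypes: parsing, filtering, numeric coding, F1 inference.

Genotype calls are stored as ordered two-character base strings ("AG" keeps
the maternal/first allele distinct from "GA"), which is what makes the
ten-state coding scheme representable. Two numeric codings are supported:

* ``additive012`` — 0 = homozygous major, 1 = heterozygous, 2 = homozygous
  minor, relative to the major allele in a reference panel. This is the
  conventional coding for linear marker-effect models and requires markers
  to be biallelic.
* ``tenstate`` — a fixed 16-entry map sending every ordered base pair to one
  of ten integer codes (unordered heterozygotes share a code). It needs no
  population allele frequencies, so coding a sample never depends on which
  other samples are present.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

#: Missing-call token for raw genotypes.
MISSING = "NN"
#: Missing sentinel in encoded matrices; reserved integer outside 0..9.
MISSING_CODE = -1

BASES = frozenset("ACGT")

#: Ordered base pair -> ten-state code. Heterozygotes collapse: XY and YX
#: share a code, so the 16 ordered pairs image onto exactly 10 codes.
TENSTATE_MAP = {
    "AA": 0, "AT": 1, "TA": 1, "AC": 2, "CA": 2, "AG": 3, "GA": 3,
    "TT": 4, "TC": 5, "CT": 5, "TG": 6, "GT": 6,
    "CC": 7, "CG": 8, "GC": 8, "GG": 9,
}


class ParseError(ValueError):
    """Raised when a genotype file does not parse under its format."""


def split_alleles(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First and second allele characters of an array of 2-char calls."""
    calls = np.ascontiguousarray(calls, dtype="<U2")
    first = calls.astype("<U1")
    second = calls.view("<U1").reshape(*calls.shape, 2)[..., 1]
    return first, second


@dataclass
class GenotypeMatrix:
    """Samples x markers of raw diploid base-pair genotype calls.

    ``calls[i, j]`` is an ordered two-character string over ACGT, or
    :data:`MISSING`. ``chrom``/``pos`` carry the marker map (1-based bp).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype="<U2")
        n, m = len(self.sample_ids), len(self.marker_ids)
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} samples x {m} markers"
            )
        if len(self.chrom) != m or len(self.pos) != m:
            raise ValueError("marker map length does not match marker_ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([idx[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            list(sample_ids), self.marker_ids, self.chrom, self.pos,
            self.calls[rows],
        )

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.sample_ids,
            [self.marker_ids[j] for j in keep],
            self.chrom[keep],
            self.pos[keep],
            self.calls[:, keep],
        )

    def allele_counts(self, j: int, rows: np.ndarray | None = None) -> dict[str, int]:
        """Count alleles at marker ``j`` over non-missing calls."""
        col = self.calls[:, j] if rows is None else self.calls[rows, j]
        col = col[col != MISSING]
        counts: dict[str, int] = {}
        if len(col):
            first, second = split_alleles(col)
            for a in np.concatenate([first, second]):
                counts[str(a)] = counts.get(str(a), 0) + 1
        return counts


@dataclass
class EncodedMatrix:
    """Numeric feature matrix under a named genotype coding scheme.

    ``values`` holds small non-negative integers (int8), with
    :data:`MISSING_CODE` marking missing calls. ``ref_allele`` records the
    per-marker major allele for the additive012 scheme.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    scheme: str
    values: np.ndarray
    ref_allele: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n, m = len(self.sample_ids), len(self.marker_ids)
        if self.values.shape != (n, m):
            raise ValueError("values shape does not match ids")
        if self.scheme not in ("additive012", "tenstate"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        hi = 2 if self.scheme == "additive012" else 9
        bad = (self.values != MISSING_CODE) & (
            (self.values < 0) | (self.values > hi)
        )
        if bad.any():
            raise ValueError(f"values out of range for scheme {self.scheme}")
        if self.scheme == "additive012" and self.ref_allele is None:
            raise ValueError("additive012 requires ref_allele per marker")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_array(self, dtype=np.float64) -> np.ndarray:
        """Float array with missing as NaN (model-facing view)."""
        out = self.values.astype(dtype)
        out[self.values == MISSING_CODE] = np.nan
        return out

    def subset_samples(self, sample_ids: list[str]) -> "EncodedMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        rows = np.array([idx[s] for s in sample_ids], dtype=int)
        return EncodedMatrix(
            list(sample_ids), self.marker_ids, self.scheme,
            self.values[rows], self.ref_allele,
        )

    def subset_markers(self, cols: np.ndarray) -> "EncodedMatrix":
        cols = np.asarray(cols)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return EncodedMatrix(
            self.sample_ids,
            [self.marker_ids[j] for j in cols],
            self.scheme,
            self.values[:, cols],
            None if self.ref_allele is None
            else [self.ref_allele[j] for j in cols],
        )

    def write_tsv(self, path) -> None:
        """Write samples x markers TSV plus a ``.json`` sidecar of scheme
        and reference alleles."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=self.sample_ids,
                          columns=self.marker_ids)
        df.to_csv(path, sep="\t", index_label="sample_id")
        sidecar = {"scheme": self.scheme, "ref_allele": self.ref_allele}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar))

    @classmethod
    def read_tsv(cls, path) -> "EncodedMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        sidecar = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            df.index.astype(str).tolist(),
            [str(c) for c in df.columns],
            sidecar["scheme"],
            df.to_numpy(dtype=np.int8),
            sidecar["ref_allele"],
        )


# ---------------------------------------------------------------------------
# Parsing


def _read_ped(path: Path) -> GenotypeMatrix:
    map_path = path.with_suffix(".map")
    if not map_path.exists():
        raise ParseError(f"missing .map companion for {path}")
    marker_ids, chrom, pos = [], [], []
    for lineno, line in enumerate(map_path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{map_path}:{lineno}: expected 4 columns")
        chrom.append(parts[0])
        marker_ids.append(parts[1])
        try:
            pos.append(int(parts[3]))
        except ValueError as e:
            raise ParseError(f"{map_path}:{lineno}: bad position") from e
    m = len(marker_ids)

    sample_ids: list[str] = []
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{path}:{lineno}: expected {6 + 2 * m} fields, "
                f"got {len(parts)}"
            )
        sid = parts[1]
        if sid in sample_ids:
            raise ParseError(f"{path}:{lineno}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        alleles = parts[6:]
        row = []
        for j in range(m):
            a, b = alleles[2 * j], alleles[2 * j + 1]
            if a == "0" or b == "0":
                row.append(MISSING)
            elif a in BASES and b in BASES:
                row.append(a + b)
            else:
                raise ParseError(
                    f"{path}:{lineno}: bad allele pair {a!r}/{b!r}")
        rows.append(row)
    return GenotypeMatrix(sample_ids, marker_ids, np.array(chrom, dtype=object),
                          np.array(pos), np.array(rows, dtype="<U2"))


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample id in VCF header")
    marker_ids, chrom, pos, cols = [], [], [], []
    n_dropped = 0
    for v in vcf:
        alts = v.ALT
        if len(alts) != 1 or len(v.REF) != 1 or len(alts[0]) != 1 \
                or v.REF not in BASES or alts[0] not in BASES:
            n_dropped += 1  # multi-allelic, indel, or symbolic
            continue
        alleles = (v.REF, alts[0])
        col = []
        for g in v.genotypes:  # [a1, a2, phased]
            a1, a2 = g[0], g[1]
            if a1 < 0 or a2 < 0:
                col.append(MISSING)
            else:
                col.append(alleles[a1] + alleles[a2])
        marker_ids.append(v.ID if v.ID not in (None, ".") else
                          f"{v.CHROM}_{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        cols.append(col)
    if n_dropped:
        logger.info("dropped %d non-biallelic-SNP records from %s",
                    n_dropped, path)
    calls = (np.array(cols, dtype="<U2").T if cols
             else np.empty((len(sample_ids), 0), dtype="<U2"))
    G = GenotypeMatrix(sample_ids, marker_ids, np.array(chrom, dtype=object),
                       np.array(pos, dtype=np.int64), calls)
    G.n_dropped = n_dropped  # type: ignore[attr-defined]
    return G


def read_genotypes(path, format: str) -> GenotypeMatrix:
    """Read genotypes from a PLINK .ped/.map pair or a VCF.

    ``format="ped"`` expects ``path`` to be the .ped file (the .map sibling
    is found by extension). VCF records that are not biallelic SNPs are
    dropped with a logged count; phased and unphased heterozygotes both map
    to the ordered base pair as written.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "ped":
        return _read_ped(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown format {format!r}; use 'ped' or 'vcf'")


def write_ped(G: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK .ped/.map pair."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(G.n_markers):
            fh.write(f"{G.chrom[j]}\t{G.marker_ids[j]}\t0\t{G.pos[j]}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, sid in enumerate(G.sample_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            for call in G.calls[i]:
                if call == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [call[0], call[1]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Filtering and encoding


def _per_marker_stats(G: GenotypeMatrix):
    """Vectorised per-marker (missing rate, minor-allele frequency)."""
    n = G.n_samples
    miss = G.calls == MISSING
    first, second = split_alleles(G.calls)
    miss_rate = miss.mean(axis=0)
    maf = np.zeros(G.n_markers)
    for j in range(G.n_markers):
        ok = ~miss[:, j]
        if not ok.any():
            maf[j] = 0.0
            continue
        alleles = np.concatenate([first[ok, j], second[ok, j]])
        _, counts = np.unique(alleles, return_counts=True)
        if len(counts) < 2:
            maf[j] = 0.0
        else:
            maf[j] = np.sort(counts)[-2:][0] / counts.sum() \
                if len(counts) == 2 else np.sort(counts)[:-1].sum() / counts.sum()
    return miss_rate, maf


def filter_markers(G: GenotypeMatrix, maf_min: float = 0.0,
                   missing_max: float = 1.0) -> GenotypeMatrix:
    """Keep markers with MAF >= ``maf_min`` and missing rate <= ``missing_max``.

    MAF is computed from allele counts over non-missing calls; for markers
    with more than two alleles the "minor" frequency is the total frequency
    of all non-major alleles.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    miss_rate, maf = _per_marker_stats(G)
    keep = (maf >= maf_min) & (miss_rate <= missing_max)
    if not keep.any():
        raise ValueError(
            "all markers removed by filtering; relax maf_min/missing_max")
    return G.subset_markers(keep)


def encode_additive(G: GenotypeMatrix,
                    ref_panel: list[str] | None = None) -> EncodedMatrix:
    """Code biallelic genotypes as 0/1/2 copies of the minor allele.

    The major allele per marker is determined from allele frequencies in
    ``ref_panel`` (default: all samples); a 50/50 frequency tie is broken
    alphabetically so coding is deterministic. Markers with more than two
    observed alleles raise an error naming the marker.
    """
    if ref_panel is None:
        panel_rows = None
    else:
        idx = {s: i for i, s in enumerate(G.sample_ids)}
        panel_rows = np.array([idx[s] for s in ref_panel], dtype=int)

    values = np.full((G.n_samples, G.n_markers), MISSING_CODE, dtype=np.int8)
    ref_alleles: list[str] = []
    for j in range(G.n_markers):
        col = G.calls[:, j]
        obs = col[col != MISSING]
        alleles = sorted({a for call in np.unique(obs) for a in call})
        if len(alleles) > 2:
            raise ValueError(
                f"marker {G.marker_ids[j]!r} has {len(alleles)} observed "
                "alleles; additive012 coding requires biallelic markers"
            )
        counts = G.allele_counts(j, panel_rows)
        if not counts:  # panel all-missing; fall back to overall counts
            counts = G.allele_counts(j)
        if not counts:
            ref = alleles[0] if alleles else "A"
        else:
            # max count, ties broken alphabetically
            ref = min(counts, key=lambda a: (-counts[a], a))
        ref_alleles.append(ref)
        if len(alleles) == 2:
            alt = alleles[0] if alleles[1] == ref else alleles[1]
        else:
            alt = None
        vj = values[:, j]
        nonmiss = col != MISSING
        hom_ref = col == ref + ref
        vj[nonmiss] = 1  # heterozygotes by elimination
        vj[hom_ref] = 0
        if alt is not None:
            vj[col == alt + alt] = 2
    return EncodedMatrix(list(G.sample_ids), list(G.marker_ids),
                         "additive012", values, ref_alleles)


def encode_tenstate(G: GenotypeMatrix) -> EncodedMatrix:
    """Apply the fixed ten-state map to every ordered base pair.

    Purely symbolic: no allele frequencies are involved, so the coding of a
    sample is independent of the rest of the population.
    """
    uniq, inv = np.unique(G.calls, return_inverse=True)
    lut = np.array(
        [TENSTATE_MAP.get(u, MISSING_CODE) for u in uniq], dtype=np.int8)
    values = lut[inv].reshape(G.calls.shape)
    return EncodedMatrix(list(G.sample_ids), list(G.marker_ids),
                         "tenstate", values, None)


# ---------------------------------------------------------------------------
# F1 inference


def infer_f1_genotypes(maternal: GenotypeMatrix, paternal: GenotypeMatrix,
                       pedigree: Pedigree) -> GenotypeMatrix:
    """Combine inbred parents' alleles into F1 genotypes.

    Each F1 call is the mother's allele followed by the father's allele.
    Parents must be homozygous at every non-missing marker (inbred lines);
    a heterozygous parent call raises. Either parent missing makes the F1
    call missing.
    """
    if maternal.marker_ids != paternal.marker_ids \
            or not np.array_equal(maternal.pos, paternal.pos) \
            or not np.array_equal(maternal.chrom, paternal.chrom):
        raise ValueError("maternal and paternal marker maps disagree")

    for G, label in ((maternal, "maternal"), (paternal, "paternal")):
        first, second = split_alleles(G.calls)
        het = (first != second) & (G.calls != MISSING)
        if het.any():
            i, j = np.argwhere(het)[0]
            raise ValueError(
                f"{label} line {G.sample_ids[i]!r} is heterozygous at "
                f"{G.marker_ids[j]!r}; parents must be inbred"
            )

    m_idx = {s: i for i, s in enumerate(maternal.sample_ids)}
    p_idx = {s: i for i, s in enumerate(paternal.sample_ids)}
    for mo, fa in zip(pedigree.mother, pedigree.father):
        if mo not in m_idx:
            raise ValueError(f"pedigree mother {mo!r} not in maternal matrix")
        if fa not in p_idx:
            raise ValueError(f"pedigree father {fa!r} not in paternal matrix")

    mrows = np.array([m_idx[s] for s in pedigree.mother], dtype=int)
    prows = np.array([p_idx[s] for s in pedigree.father], dtype=int)
    m_allele = maternal.calls[mrows].astype("<U1")
    p_allele = paternal.calls[prows].astype("<U1")
    f1 = np.char.add(np.char.asarray(m_allele), np.char.asarray(p_allele))
    f1 = np.asarray(f1, dtype="<U2")
    missing = (maternal.calls[mrows] == MISSING) | \
              (paternal.calls[prows] == MISSING)
    f1[missing] = MISSING
    return GenotypeMatrix(list(pedigree.f1_ids), list(maternal.marker_ids),
                          maternal.chrom, maternal.pos, f1)
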