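"""Pool-seq SNP tables and PoPoolation2 sync files.

The central container is :class:`SnpTable`: a loci × samples matrix of
minor-allele read counts plus matching total coverages, with locus and
sample metadata.  The minor allele at each site is defined *globally* —
the less common of the two segregating nucleotides summed over every
sample — so a single frequency convention flows through all downstream
analyses (GLMM scans, heterozygosity, PCA, parallelism).

Coordinates are 1-based inclusive, following the sync convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Chromosome arms of the D. melanogaster nuclear genome used throughout.
CHROMOSOMES = ("2L", "2R", "3L", "3R", "X", "4")

#: Valid sample groups: the two shifted trajectories and their founders.
GROUPS = ("A2C", "C2A", "FOUNDER_A", "FOUNDER_C")

_NUCS = ("A", "T", "C", "G")  # sync count-string order is A:T:C:G:N:del
_LEX = ("A", "C", "G", "T")   # lexicographic order used for tie-breaks


class SyncParseError(ValueError):
    """Raised when a sync line cannot be parsed."""


@dataclass(frozen=True)
class Locus:
    """A biallelic site: chromosome arm, 1-based position, allele labels."""

    chrom: str
    pos: int
    minor_base: str
    major_base: str

    def __post_init__(self) -> None:
        if self.chrom not in CHROMOSOMES:
            raise ValueError(f"unknown chromosome arm {self.chrom!r}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.minor_base == self.major_base:
            raise ValueError("minor and major alleles must differ")
        for b in (self.minor_base, self.major_base):
            if b not in _NUCS:
                raise ValueError(f"invalid nucleotide {b!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one pooled sample.

    ``generation`` counts generations under the *current* selection regime
    (0 for founders); ``group`` is one of :data:`GROUPS`.
    """

    sample_id: str
    group: str
    replicate: int
    generation: float
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 1 <= int(self.replicate) <= 10:
            raise ValueError("replicate must lie in 1..10")
        if self.generation < 0:
            raise ValueError("generation must be non-negative")


@dataclass
class SnpTable:
    """Loci × samples matrices of minor-allele counts and coverages."""

    loci: list[Locus]
    samples: list[SampleMeta]
    minor: np.ndarray
    coverage: np.ndarray
    _sample_index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.minor = np.asarray(self.minor, dtype=np.int64)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        shape = (len(self.loci), len(self.samples))
        if self.minor.shape != shape or self.coverage.shape != shape:
            raise ValueError(
                f"matrix shapes {self.minor.shape}/{self.coverage.shape} "
                f"do not match loci × samples {shape}"
            )
        if np.any(self.minor < 0) or np.any(self.minor > self.coverage):
            raise ValueError("minor counts must satisfy 0 <= minor <= coverage")
        keys = [(s.group, s.replicate, s.timepoint) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValueError("(group, replicate, timepoint) must be unique")
        self._sample_index = {s.sample_id: j for j, s in enumerate(self.samples)}

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self._sample_index[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in table") from None

    def subset_loci(self, idx) -> "SnpTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpTable(
            [self.loci[i] for i in idx],
            list(self.samples),
            self.minor[idx],
            self.coverage[idx],
        )

    def subset_samples(self, idx) -> "SnpTable":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SnpTable(
            list(self.loci),
            [self.samples[j] for j in idx],
            self.minor[:, idx],
            self.coverage[:, idx],
        )

    def select_samples(self, **criteria) -> "SnpTable":
        """Subset samples by metadata equality, e.g. ``group="A2C"``.

        A criterion value may be a set/list, in which case membership is
        tested instead of equality.
        """
        keep = []
        for j, s in enumerate(self.samples):
            ok = True
            for key, want in criteria.items():
                have = getattr(s, key)
                if isinstance(want, (set, frozenset, list, tuple)):
                    ok = ok and have in want
                else:
                    ok = ok and have == want
            if ok:
                keep.append(j)
        return self.subset_samples(np.asarray(keep, dtype=int))

    def loci_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [l.chrom for l in self.loci],
                "pos": [l.pos for l in self.loci],
                "minor_base": [l.minor_base for l in self.loci],
                "major_base": [l.major_base for l in self.loci],
            }
        )

    def samples_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "group": [s.group for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "generation": [s.generation for s in self.samples],
                "timepoint": [s.timepoint for s in self.samples],
            }
        )


# ---------------------------------------------------------------------------
# sync format
# ---------------------------------------------------------------------------

def read_sync(path, sample_metas: Sequence[SampleMeta]) -> SnpTable:
    """Read a PoPoolation2 sync file into a :class:`SnpTable`.

    Only biallelic sites — exactly two nucleotides with nonzero total count
    across all samples — are retained; sites with more than two segregating
    nucleotides are dropped and counted in a log message.  The minor allele
    is the globally less common of the two; exact ties break toward the
    lexicographically smaller nucleotide (A < C < G < T).
    """
    metas = list(sample_metas)
    loci: list[Locus] = []
    minor_rows: list[list[int]] = []
    cov_rows: list[list[int]] = []
    n_multi = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3 + len(metas):
                raise SyncParseError(
                    f"line {lineno}: expected {3 + len(metas)} columns, got {len(parts)}"
                )
            chrom, pos_s = parts[0], parts[1]
            counts = np.empty((len(metas), 4), dtype=np.int64)
            for j, cell in enumerate(parts[3:]):
                fields = cell.split(":")
                if len(fields) != 6:
                    raise SyncParseError(
                        f"line {lineno}: malformed count-string {cell!r}"
                    )
                try:
                    counts[j] = [int(x) for x in fields[:4]]
                except ValueError:
                    raise SyncParseError(
                        f"line {lineno}: malformed count-string {cell!r}"
                    ) from None
            totals = counts.sum(axis=0)
            seg = np.flatnonzero(totals > 0)
            if len(seg) > 2:
                n_multi += 1
                continue
            if len(seg) != 2:
                continue  # monomorphic or empty: not a SNP
            b1, b2 = (_NUCS[k] for k in seg)
            t1, t2 = totals[seg[0]], totals[seg[1]]
            if t1 < t2:
                minor_b, major_b = b1, b2
                mi, ma = seg[0], seg[1]
            elif t2 < t1:
                minor_b, major_b = b2, b1
                mi, ma = seg[1], seg[0]
            else:  # tie: lexicographically smaller nucleotide is minor
                if _LEX.index(b1) < _LEX.index(b2):
                    minor_b, major_b, mi, ma = b1, b2, seg[0], seg[1]
                else:
                    minor_b, major_b, mi, ma = b2, b1, seg[1], seg[0]
            loci.append(Locus(chrom, int(pos_s), minor_b, major_b))
            minor_rows.append(counts[:, mi].tolist())
            cov_rows.append((counts[:, mi] + counts[:, ma]).tolist())

    if n_multi:
        logger.info("read_sync: dropped %d sites with >2 segregating alleles", n_multi)
    shape = (len(loci), len(metas))
    return SnpTable(
        loci,
        metas,
        np.asarray(minor_rows, dtype=np.int64).reshape(shape),
        np.asarray(cov_rows, dtype=np.int64).reshape(shape),
    )


def write_sync(table: SnpTable, path) -> None:
    """Write a table as a sync file (major allele in the reference column).

    ``read_sync(write_sync(t))`` reproduces the minor/coverage matrices of
    any table that respects the global minor-allele rule and segregates
    (at least one read of each allele summed over samples) at every locus.
    """
    with open(path, "w") as fh:
        for i, loc in enumerate(table.loci):
            cells = []
            for j in range(table.n_samples):
                c = [0, 0, 0, 0, 0, 0]
                mi = _NUCS.index(loc.minor_base)
                ma = _NUCS.index(loc.major_base)
                c[mi] = int(table.minor[i, j])
                c[ma] = int(table.coverage[i, j] - table.minor[i, j])
                cells.append(":".join(str(x) for x in c))
            fh.write(f"{loc.chrom}\t{loc.pos}\t{loc.major_base}\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# filtering and frequencies
# ---------------------------------------------------------------------------

def filter_snps(
    table: SnpTable,
    min_cov: int = 20,
    min_maf: float = 0.02,
    exclude_chrom4: bool = False,
) -> SnpTable:
    """Coverage and minor-allele-frequency filter.

    Retains loci where every sample has coverage >= ``min_cov`` and the
    pooled minor-allele frequency (summed minor counts over summed coverage
    across all samples) is >= ``min_maf``; both bounds inclusive.  With
    ``exclude_chrom4`` the dot chromosome is dropped as well.  Idempotent.
    """
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must lie in [0, 0.5], got {min_maf}")
    cov_ok = (table.coverage >= min_cov).all(axis=1)
    tot_minor = table.minor.sum(axis=1).astype(float)
    tot_cov = table.coverage.sum(axis=1).astype(float)
    pooled = np.divide(
        tot_minor, tot_cov, out=np.zeros_like(tot_minor), where=tot_cov > 0
    )
    keep = cov_ok & (pooled >= min_maf)
    if exclude_chrom4:
        keep &= np.array([l.chrom != "4" for l in table.loci])
    return table.subset_loci(keep)


def frequencies(table: SnpTable, pseudocount: int = 0) -> np.ndarray:
    """Minor-allele frequency matrix (minor + pc) / (coverage + 2·pc).

    With ``pseudocount=0`` these are the raw ratios and every cell must
    have positive coverage; with a positive pseudocount all frequencies
    lie strictly inside (0, 1).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if pseudocount == 0:
        bad = np.argwhere(table.coverage == 0)
        if len(bad):
            sites = ", ".join(
                f"({table.loci[i].chrom}:{table.loci[i].pos}, "
                f"{table.samples[j].sample_id})"
                for i, j in bad[:10]
            )
            raise ValueError(
                f"zero coverage with pseudocount 0 at {len(bad)} cells: {sites}"
            )
    return (table.minor + pseudocount) / (table.coverage + 2.0 * pseudocount)


# ---------------------------------------------------------------------------
# tabular SNP-table dialect
# ---------------------------------------------------------------------------

def write_snp_table(table: SnpTable, path, design_path) -> None:
    """Write the tabular dialect: one row per locus with per-sample
    ``<sample_id>.minor`` / ``<sample_id>.cov`` column pairs, sample
    metadata in a sidecar design table."""
    cols = {}
    for j, s in enumerate(table.samples):
        cols[f"{s.sample_id}.minor"] = table.minor[:, j]
        cols[f"{s.sample_id}.cov"] = table.coverage[:, j]
    df = pd.concat([table.loci_frame(), pd.DataFrame(cols)], axis=1)
    df.to_csv(path, sep="\t", index=False)
    table.samples_frame().to_csv(design_path, sep="\t", index=False)


def read_snp_table(path, design_path) -> SnpTable:
    """Read the tabular dialect written by :func:`write_snp_table`."""
    design = pd.read_csv(design_path, sep="\t", dtype={"timepoint": str})
    design["timepoint"] = design["timepoint"].fillna("")
    metas = [
        SampleMeta(
            str(r.sample_id), r.group, int(r.replicate), float(r.generation),
            str(r.timepoint),
        )
        for r in design.itertuples()
    ]
    df = pd.read_csv(path, sep="\t")
    loci = [
        Locus(str(c), int(p), mb, Mb)
        for c, p, mb, Mb in zip(
            df["chrom"], df["pos"], df["minor_base"], df["major_base"]
        )
    ]
    minor = np.column_stack(
        [df[f"{m.sample_id}.minor"].to_numpy(np.int64) for m in metas]
    ) if metas else np.zeros((len(loci), 0), dtype=np.int64)
    cov = np.column_stack(
        [df[f"{m.sample_id}.cov"].to_numpy(np.int64) for m in metas]
    ) if metas else np.zeros((len(loci), 0), dtype=np.int64)
    minor = minor.reshape(len(loci), len(metas))
    cov = cov.reshape(len(loci), len(metas))
    return SnpTable(loci, metas, minor, cov)
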