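"""Screen artefact I/O: library annotation, sample sheets, count matrices,
barcode counting from FASTQ reads and GMT gene-set files.

All tabular artefacts are plain TSV (tab separator, ``#`` comment lines
ignored, UTF-8).  FASTQ may be plain or gzip-compressed (detected from the
``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

BARCODE_LENGTH = 18
_BARCODE_ALPHABET = frozenset("ACGT")
TIMEPOINTS = ("t0", "t14")


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibraryAnnotation:
    """Mapping of shRNA constructs to target genes and 18-nt barcodes.

    Each hairpin carries a unique id, targets exactly one gene (genes are
    typically covered by 5–6 hairpins) and is identified in sequencing data
    by a unique 18-mer over {A,C,G,T}.
    """

    df: pd.DataFrame  # columns: shrna_id, gene_symbol, barcode

    def __post_init__(self) -> None:
        required = ["shrna_id", "gene_symbol", "barcode"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"library annotation missing column(s): {missing}")
        df = self.df
        dup = df["shrna_id"][df["shrna_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate shrna_id: {dup.iloc[0]!r}")
        dup = df["barcode"][df["barcode"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate barcode: {dup.iloc[0]!r}")
        bad = df["barcode"][
            ~df["barcode"].map(
                lambda b: isinstance(b, str)
                and len(b) == BARCODE_LENGTH
                and set(b) <= _BARCODE_ALPHABET
            )
        ]
        if not bad.empty:
            raise ValidationError(
                f"malformed barcode {bad.iloc[0]!r} (must be {BARCODE_LENGTH} nt over ACGT)"
            )

    @property
    def shrna_ids(self) -> pd.Index:
        return pd.Index(self.df["shrna_id"])

    @property
    def genes(self) -> pd.Index:
        return pd.Index(pd.unique(self.df["gene_symbol"]))

    @property
    def n_shrnas(self) -> int:
        return len(self.df)

    @property
    def n_genes(self) -> int:
        return self.df["gene_symbol"].nunique()

    def shrnas_per_gene(self) -> pd.Series:
        """Number of hairpins targeting each gene."""
        return self.df.groupby("gene_symbol", sort=False)["shrna_id"].count()

    def gene_of(self) -> pd.Series:
        """shrna_id -> gene_symbol mapping."""
        return self.df.set_index("shrna_id")["gene_symbol"]

    def barcode_index(self) -> dict[str, str]:
        """barcode -> shrna_id lookup table."""
        return dict(zip(self.df["barcode"], self.df["shrna_id"]))


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: screen label, timepoint (t0/t14) and replicate index."""

    df: pd.DataFrame  # columns: sample_id, screen, timepoint, replicate

    def __post_init__(self) -> None:
        required = ["sample_id", "screen", "timepoint", "replicate"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise FormatError(f"sample sheet missing column(s): {missing}")
        df = self.df
        dup = df["sample_id"][df["sample_id"].duplicated()]
        if not dup.empty:
            raise ValidationError(f"duplicate sample_id: {dup.iloc[0]!r}")
        bad_tp = set(df["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(
                f"unknown timepoint(s) {sorted(bad_tp)}; expected one of {TIMEPOINTS}"
            )
        if (df["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate indices must be positive integers")
        for screen, grp in df.groupby("screen"):
            present = set(grp["timepoint"])
            lacking = set(TIMEPOINTS) - present
            if lacking:
                raise ValidationError(
                    f"screen {screen!r} lacks samples for timepoint(s) {sorted(lacking)}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    @property
    def screens(self) -> list[str]:
        return list(pd.unique(self.df["screen"]))

    def samples_for(self, screen: str, timepoint: str) -> pd.DataFrame:
        df = self.df
        return df[(df["screen"] == screen) & (df["timepoint"] == timepoint)]


@dataclass(frozen=True)
class CountMatrix:
    """shRNA x sample matrix of barcode read counts plus its sample sheet."""

    counts: pd.DataFrame  # index shrna_id, columns sample_id, integer cells
    samples: SampleSheet

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", self.counts.rename_axis(index="shrna_id", columns=None)
        )
        unknown = set(self.counts.columns) - set(self.samples.sample_ids)
        if unknown:
            raise ValidationError(
                f"count column(s) {sorted(unknown)} absent from the sample sheet"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at shRNA {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )
            object.__setattr__(self, "counts", self.counts.round().astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at shRNA {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    @property
    def shrna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def column_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        """Write the counts table as TSV (first column shrna_id)."""
        out = self.counts.copy()
        out.index.name = "shrna_id"
        out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _data_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    """Yield (1-based line number, tab-split fields), skipping comments/blanks."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_library(path: str | Path) -> LibraryAnnotation:
    """Parse a library annotation TSV (columns shrna_id, gene_symbol, barcode).

    Raises :class:`FormatError` on a bad header and :class:`ValidationError`
    (with the offending line number) on duplicate ids/barcodes or malformed
    barcodes.
    """
    rows = []
    it = _data_lines(path)
    try:
        _, header = next(it)
    except StopIteration:
        raise FormatError(f"{path}: empty library file") from None
    try:
        idx = [header.index(c) for c in ("shrna_id", "gene_symbol", "barcode")]
    except ValueError as exc:
        raise FormatError(f"{path}: header must contain shrna_id, gene_symbol, barcode") from exc
    seen_ids: dict[str, int] = {}
    seen_bc: dict[str, int] = {}
    for lineno, fields in it:
        if len(fields) <= max(idx):
            raise FormatError(f"{path}:{lineno}: expected {len(header)} fields")
        sid, gene, bc = (fields[i] for i in idx)
        if sid in seen_ids:
            raise ValidationError(
                f"{path}:{lineno}: duplicate shrna_id {sid!r} (first seen line {seen_ids[sid]})"
            )
        if bc in seen_bc:
            raise ValidationError(
                f"{path}:{lineno}: duplicate barcode {bc!r} (first seen line {seen_bc[bc]})"
            )
        if len(bc) != BARCODE_LENGTH or not set(bc) <= _BARCODE_ALPHABET:
            raise ValidationError(
                f"{path}:{lineno}: malformed barcode {bc!r} "
                f"(must be {BARCODE_LENGTH} nt over ACGT)"
            )
        seen_ids[sid] = lineno
        seen_bc[bc] = lineno
        rows.append((sid, gene, bc))
    return LibraryAnnotation(
        pd.DataFrame(rows, columns=["shrna_id", "gene_symbol", "barcode"])
    )


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Parse a sample sheet TSV (sample_id, screen, timepoint, replicate)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "replicate" in df.columns:
        df["replicate"] = pd.to_numeric(df["replicate"], errors="raise").astype(int)
    return SampleSheet(df)


def load_count_matrix(
    counts_path: str | Path,
    samples_path: str | Path | SampleSheet,
    library: LibraryAnnotation,
) -> CountMatrix:
    """Load a counts TSV against a sample sheet and library annotation.

    Library hairpins missing from the counts file are zero-filled (a fully
    dropped-out hairpin should reach downstream depletion logic as zeros,
    not vanish); rows not present in the library are rejected.
    """
    samples = (
        samples_path
        if isinstance(samples_path, SampleSheet)
        else read_sample_sheet(samples_path)
    )
    df = pd.read_csv(counts_path, sep="\t", comment="#")
    if df.columns[0] != "shrna_id":
        raise FormatError(f"{counts_path}: first column must be shrna_id")
    df = df.set_index("shrna_id")
    unknown_rows = df.index.difference(library.shrna_ids)
    if len(unknown_rows):
        raise ValidationError(
            f"count rows not in library annotation: {list(unknown_rows[:5])}"
        )
    missing = library.shrna_ids.difference(df.index)
    if len(missing):
        logger.warning(
            "%d library shRNA(s) absent from %s; zero-filled (e.g. %s)",
            len(missing), counts_path, missing[0],
        )
        fill = pd.DataFrame(0, index=missing, columns=df.columns)
        df = pd.concat([df, fill])
    df = df.loc[library.shrna_ids]  # library order
    return CountMatrix(df, samples)


def read_count_matrix(
    counts_path: str | Path, samples: SampleSheet
) -> CountMatrix:
    """Read a counts TSV without library reconciliation (round-trip partner
    of :meth:`CountMatrix.to_tsv`)."""
    df = pd.read_csv(counts_path, sep="\t", comment="#").set_index("shrna_id")
    return CountMatrix(df, samples)


# ---------------------------------------------------------------------------
# Barcode counting
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seqs: Iterable[str]) -> np.ndarray:
    return np.array(
        [[_BASE_CODE.get(b, 4) for b in s] for s in seqs], dtype=np.uint8
    )


@dataclass
class BarcodeCountResult:
    """Per-shRNA read tallies plus the unassigned-read count."""

    counts: pd.Series  # index shrna_id, integer reads
    unassigned: int
    total_reads: int = field(default=0)

    @property
    def assigned(self) -> int:
        return int(self.counts.sum())


def count_barcodes(
    reads: str | Path | Iterable,
    library: LibraryAnnotation,
    offset: int = 0,
    max_mismatch: int = 0,
) -> BarcodeCountResult:
    """Assign FASTQ reads to library hairpins by their 18-mer barcode.

    A read is assigned when the 18-mer starting at ``offset`` (forward
    orientation) matches a library barcode with at most ``max_mismatch``
    substitutions *and* that best match is unique; ties at the minimal
    distance and reads too short to contain the barcode are tallied as
    unassigned.  Reads are conserved: assigned + unassigned == total.

    ``reads`` may be a FASTQ path (``.gz`` accepted) or any iterable of
    SeqRecords / plain sequence strings.
    """
    if not 0 <= max_mismatch <= 2:
        raise ValueError("max_mismatch must be in {0, 1, 2}")
    if offset < 0:
        raise ValueError("offset must be non-negative")

    lookup = library.barcode_index()
    shrna_ids = list(library.shrna_ids)
    counts = dict.fromkeys(shrna_ids, 0)
    unassigned = 0
    total = 0

    if max_mismatch > 0:
        codes = _encode(library.df["barcode"])
        id_arr = np.array(shrna_ids)

    close_cm = None
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        handle = gzip.open(path, "rt") if path.suffix == ".gz" else open(path)
        close_cm = handle
        record_iter = SeqIO.parse(handle, "fastq")
    else:
        record_iter = iter(reads)

    try:
        for rec in record_iter:
            seq = str(rec.seq if hasattr(rec, "seq") else rec).upper()
            total += 1
            kmer = seq[offset : offset + BARCODE_LENGTH]
            if len(kmer) < BARCODE_LENGTH:
                unassigned += 1
                continue
            hit = lookup.get(kmer)
            if hit is not None:
                counts[hit] += 1
                continue
            if max_mismatch == 0:
                unassigned += 1
                continue
            q = _encode([kmer])[0]
            dists = (codes != q).sum(axis=1)
            best = int(dists.min())
            if best > max_mismatch or (dists == best).sum() != 1:
                unassigned += 1
            else:
                counts[str(id_arr[int(np.argmin(dists))])] += 1
    finally:
        if close_cm is not None:
            close_cm.close()

    series = pd.Series(counts, name="count").reindex(shrna_ids).astype(np.int64)
    return BarcodeCountResult(counts=series, unassigned=unassigned, total_reads=total)


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list["GeneSet"]:
    """Read gene sets from a GMT file (name <tab> description <tab> symbols...).

    Symbols are upper-cased on load.
    """
    from .sets import GeneSet  # local import to avoid a cycle

    sets = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT rows need name, description, >=1 gene")
        name, _desc, *genes = fields
        members = frozenset(g.strip().upper() for g in genes if g.strip())
        if not members:
            raise ValidationError(f"{path}:{lineno}: gene set {name!r} has no members")
        sets.append(GeneSet(name=name, members=members))
    return sets
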