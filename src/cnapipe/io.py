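"""Readers and writers for the pipeline's tabular artifacts.

All coordinates are 0-based half-open throughout the package (BED-native).
Files are UTF-8, tab-delimited; lines starting with ``#`` are comments.
Chromosomes order naturally (chr1 < chr2 < ... < chr10, X and Y last).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from ._util import chrom_sort_key, sort_chromosomes

RATIO_COLUMNS = ["chromosome", "start", "end", "probe_id", "log2"]

_TABLE1_SHA256 = "7ee347c120f950cead1cfef99206ca3f75c18a1ca3189c621aceaf3ef3c9c776"


class ProfileFormatError(ValueError):
    """Raised when an input table violates the documented dialect."""


@dataclass
class RatioProfile:
    """Per-probe normalized log2 ratios for one aCGH sample.

    ``data`` has columns chromosome, start, end, probe_id, log2, sorted by
    (chromosome order, start). ``chrom_order`` fixes the chromosome ordering
    used for genome-wide tracks.
    """

    sample_id: str
    data: pd.DataFrame
    chrom_order: list = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in RATIO_COLUMNS if c not in df.columns]
        if missing:
            raise ProfileFormatError(f"ratio table missing columns: {missing}")
        if not self.chrom_order:
            self.chrom_order = sort_chromosomes(df["chromosome"])
        values = np.asarray(df["log2"], dtype=float)
        if not np.all(np.isfinite(values)):
            raise ProfileFormatError("non-finite log2 ratio values")
        if np.any(df["start"].to_numpy() >= df["end"].to_numpy()):
            bad = int(np.argmax(df["start"].to_numpy() >= df["end"].to_numpy()))
            raise ProfileFormatError(f"probe row {bad}: start >= end")
        order = {c: i for i, c in enumerate(self.chrom_order)}
        unknown = set(df["chromosome"]) - set(order)
        if unknown:
            raise ProfileFormatError(f"chromosomes outside layout: {sorted(unknown)}")
        for chrom, grp in df.groupby("chromosome", sort=False):
            starts = grp["start"].to_numpy()
            if np.any(np.diff(starts) <= 0):
                line = int(grp.index[int(np.argmax(np.diff(starts) <= 0)) + 1])
                raise ProfileFormatError(
                    f"{chrom}: probes not strictly increasing at row {line}"
                )
        idx = df.index[np.lexsort((df["start"].to_numpy(),
                                   [order[c] for c in df["chromosome"]]))]
        self.data = df.loc[idx].reset_index(drop=True)

    @property
    def values(self) -> np.ndarray:
        return self.data["log2"].to_numpy(dtype=float)

    @property
    def n_probes(self) -> int:
        return len(self.data)

    def chromosome_values(self, chrom: str) -> np.ndarray:
        return self.data.loc[self.data["chromosome"] == chrom, "log2"].to_numpy(float)


@dataclass(frozen=True)
class GeneModel:
    """A gene interval (0-based half-open) with strand."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ProfileFormatError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ProfileFormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SampleAnnotation:
    """One tumor's clinicopathological record."""

    case_id: str
    size_mm: float
    metastasis: str  # None | Lung
    invasion: str  # None | Peritoneal
    atypia: str  # Low | Intermediate | High
    growth: str  # Expansive | Intermediate | Infiltrating
    met_status: str  # None | Amplification
    cdkn2a_status: str  # None | Loss | HD

    _ENUMS = {
        "metastasis": {"None", "Lung"},
        "invasion": {"None", "Peritoneal"},
        "atypia": {"Low", "Intermediate", "High"},
        "growth": {"Expansive", "Intermediate", "Infiltrating"},
        "met_status": {"None", "Amplification"},
        "cdkn2a_status": {"None", "Loss", "HD"},
    }

    def __post_init__(self) -> None:
        if not self.size_mm > 0:
            raise ValueError(f"{self.case_id}: size_mm must be positive")
        for name, allowed in self._ENUMS.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"{self.case_id}: {name}={getattr(self, name)!r} not in {sorted(allowed)}"
                )


def _read_table(path, columns: int) -> pd.DataFrame:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < columns:
                raise ProfileFormatError(
                    f"{path}:{lineno}: expected >= {columns} tab-separated fields"
                )
            rows.append((lineno, fields))
    return rows


def read_ratio_profile(path, sample_id: Optional[str] = None,
                       chrom_order: Optional[list] = None) -> RatioProfile:
    """Read a probe-level log2-ratio TSV (chromosome, start, end, probe_id, log2).

    A single header line is tolerated (detected by a non-numeric 5th field).
    Chromosome order defaults to file order of first appearance.
    """
    rows = _read_table(path, 5)
    if not rows:
        raise ProfileFormatError(f"{path}: empty ratio table")
    # header detection: non-numeric ratio column on the first row only
    first_fields = rows[0][1]
    try:
        float(first_fields[4])
    except ValueError:
        rows = rows[1:]
    recs = []
    for lineno, f in rows:
        try:
            start, end = int(f[1]), int(f[2])
            ratio = float(f[4])
        except ValueError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: {exc}") from None
        if start >= end:
            raise ProfileFormatError(f"{path}:{lineno}: start >= end")
        recs.append((f[0], start, end, f[3], ratio))
    df = pd.DataFrame(recs, columns=RATIO_COLUMNS)
    if chrom_order is None:
        chrom_order = list(dict.fromkeys(df["chromosome"]))
    # reject unsorted input rather than silently reordering within a chromosome
    for chrom, grp in df.groupby("chromosome", sort=False):
        d = np.diff(grp["start"].to_numpy())
        if np.any(d <= 0):
            raise ProfileFormatError(
                f"{path}: {chrom} probes not strictly increasing by start"
            )
    if sample_id is None:
        sample_id = Path(path).stem
    return RatioProfile(sample_id=sample_id, data=df, chrom_order=list(chrom_order))


def write_ratio_profile(profile: RatioProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id={profile.sample_id}\n")
        fh.write("\t".join(RATIO_COLUMNS) + "\n")
        profile.data.to_csv(fh, sep="\t", header=False, index=False)


def read_genes_bed(path) -> list:
    """Read gene intervals from BED4+ (chrom, start, end, name[, score, strand])."""
    genes = []
    for lineno, f in _read_table(path, 4):
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            raise ProfileFormatError(f"{path}:{lineno}: non-integer interval") from None
        strand = f[5] if len(f) >= 6 else "+"
        try:
            genes.append(GeneModel(f[3], f[0], start, end, strand))
        except ProfileFormatError as exc:
            raise ProfileFormatError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_sample_annotations(path) -> list:
    """Read a sample-annotation TSV with the fixture's 8 columns (header required)."""
    rows = _read_table(path, 8)
    header = rows[0][1]
    expected = ["case_id", "size_mm", "metastasis", "invasion", "atypia",
                "growth", "met_status", "cdkn2a_status"]
    if header[:8] != expected:
        raise ProfileFormatError(f"{path}: header must be {expected}")
    return [
        SampleAnnotation(f[0], float(f[1]), f[2], f[3], f[4], f[5], f[6], f[7])
        for _, f in rows[1:]
    ]


def load_table1_fixture() -> list:
    """The packaged 13-tumor annotation table (checksummed, immutable)."""
    ref = resources.files("cnapipe").joinpath("data/table1_samples.tsv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE1_SHA256:
        raise RuntimeError(
            "packaged annotation fixture is corrupted "
            f"(sha256 {digest} != {_TABLE1_SHA256})"
        )
    with resources.as_file(ref) as p:
        records = read_sample_annotations(p)
    if len(records) != 13:
        raise RuntimeError(f"annotation fixture must hold 13 records, got {len(records)}")
    return records


def natural_chrom_order(names) -> list:
    """Public re-export of the package's chromosome ordering."""
    return sorted(dict.fromkeys(names), key=chrom_sort_key)
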