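"""Synthetic aCGH cohorts with known ground truth.

The forward model mirrors how a tumor/normal mixture appears on a CGH array:
a tumor of purity rho and average ploidy psi with integer copy number c at a
locus yields, after normalization to the mixture's average copy number, a
log2 ratio

    log2( (rho*c + 2*(1-rho)) / (rho*psi + 2*(1-rho)) )

(normal cells contribute copy number 2) plus additive Gaussian probe noise.
Copy number 0 in a pure tumor would give log2(0); the pre-noise value is
clipped at a configurable floor instead, as real arrays saturate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import child_rng
from .io import RATIO_COLUMNS, RatioProfile

DEFAULT_LOG2_FLOOR = -8.0
DEFAULT_C_MAX = 12


@dataclass
class GenomeLayout:
    """Chromosome sizes plus the probe grid (starts, fixed probe length)."""

    chromosomes: list  # ordered (name, length_bp)
    probes: dict  # name -> np.ndarray of probe start positions (strictly increasing)
    probe_length: int = 60

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length")
            pos = np.asarray(self.probes[name])
            if len(pos) < 2:
                raise ValueError(f"{name}: need at least 2 probes")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{name}: probe positions must be strictly increasing")
            if pos[0] < 0 or pos[-1] + self.probe_length > length:
                raise ValueError(f"{name}: probes outside chromosome bounds")

    @property
    def chrom_names(self) -> list:
        return [n for n, _ in self.chromosomes]

    @property
    def n_probes(self) -> int:
        return sum(len(self.probes[n]) for n in self.chrom_names)

    def length_of(self, chrom: str) -> int:
        return dict(self.chromosomes)[chrom]

    def probe_frame(self) -> pd.DataFrame:
        """All probes as a (chromosome, start, end, probe_id) table in layout order."""
        parts = []
        for name in self.chrom_names:
            pos = np.asarray(self.probes[name], dtype=int)
            parts.append(pd.DataFrame({
                "chromosome": name,
                "start": pos,
                "end": pos + self.probe_length,
                "probe_id": [f"{name}:{p}" for p in pos],
            }))
        return pd.concat(parts, ignore_index=True)


@dataclass(frozen=True)
class AberrationSpec:
    """How many events of each kind to plant, and their focal sizes (in probes).

    Gains and losses shift copy number by +/-1 from the baseline (the rounded
    target ploidy); homozygous deletions set it to 0; amplicons jump above the
    amplification threshold. Whole-chromosome losses occupy entire chromosomes.
    """

    n_gains: int = 0
    n_losses: int = 0
    n_hd: int = 0
    n_amplicons: int = 0
    whole_chromosome_losses: int = 0
    gain_length: tuple = (20, 120)
    loss_length: tuple = (20, 120)
    hd_length: tuple = (3, 12)
    amplicon_length: tuple = (5, 25)


@dataclass
class TruthProfile:
    """Ground-truth tumor state: tiling copy-number segments, purity, ploidy.

    ``ploidy`` is recomputed from the emitted segments as the genomic-length
    weighted mean copy number (an exact arithmetic identity, asserted here).
    """

    segments: list  # (chromosome, start, end, copy_number)
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be in (0, 1]")
        lengths = np.array([e - s for _, s, e, _ in self.segments], dtype=float)
        cns = np.array([c for *_, c in self.segments], dtype=float)
        if np.any(lengths <= 0) or np.any(cns < 0):
            raise ValueError("segments must be non-empty with non-negative copy number")
        expected = float(np.average(cns, weights=lengths))
        if abs(expected - self.ploidy) > 1e-9:
            raise ValueError("ploidy must equal the length-weighted mean copy number")

    def probe_copy_numbers(self, layout: GenomeLayout) -> np.ndarray:
        """Integer copy number under each probe, in layout probe order."""
        by_chrom: dict = {}
        for chrom, s, e, c in self.segments:
            by_chrom.setdefault(chrom, []).append((s, e, c))
        out = []
        for name in layout.chrom_names:
            segs = sorted(by_chrom.get(name, []))
            starts = np.array([s for s, _, _ in segs])
            cns = np.array([c for _, _, c in segs])
            idx = np.searchsorted(starts, layout.probes[name], side="right") - 1
            out.append(cns[idx])
        return np.concatenate(out)


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise on log2 ratios."""

    sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


def mixture_log2(c, purity: float, ploidy: float,
                 floor: float = DEFAULT_LOG2_FLOOR) -> np.ndarray:
    """Noise-free log2 ratio of a tumor/normal mixture at integer copy number c."""
    c = np.asarray(c, dtype=float)
    num = purity * c + 2.0 * (1.0 - purity)
    den = purity * ploidy + 2.0 * (1.0 - purity)
    with np.errstate(divide="ignore"):
        val = np.log2(num / den)
    return np.maximum(val, floor)


def make_genome(n_chromosomes: int = 20, chrom_length: int = 50_000_000,
                probes_per_chromosome: int = 500, seed: int = 0,
                probe_length: int = 60,
                chromosomes: Optional[Sequence] = None) -> GenomeLayout:
    """Lay out a genome with jittered, evenly spread probes.

    By default a desk-scale surrogate of a rat CGH array: 20 autosomes of
    50 Mb with 500 probes each (10,000 probes).
    """
    if chromosomes is None:
        if n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if chrom_length <= 0:
            raise ValueError("chromosome length must be positive")
        chromosomes = [(f"chr{i + 1}", int(chrom_length)) for i in range(n_chromosomes)]
    chromosomes = [(str(n), int(l)) for n, l in chromosomes]
    if probes_per_chromosome < 2:
        raise ValueError("need at least 2 probes per chromosome")
    probes = {}
    for k, (name, length) in enumerate(chromosomes):
        step = length // probes_per_chromosome
        if step <= probe_length:
            raise ValueError(f"{name}: too many probes for chromosome length")
        rng = child_rng(seed, 101, k)
        jitter = rng.integers(0, step - probe_length, size=probes_per_chromosome)
        pos = np.arange(probes_per_chromosome, dtype=np.int64) * step + jitter
        probes[name] = pos
    return GenomeLayout(chromosomes=list(chromosomes), probes=probes,
                        probe_length=probe_length)


def _place_events(rng, layout, counts_and_lengths, occupied):
    """Place focal events without overlap; returns (chrom, lo, hi, kind) blocks."""
    placed = []
    for kind, count, (lo_len, hi_len) in counts_and_lengths:
        for _ in range(count):
            ok = False
            for _attempt in range(500):
                ci = int(rng.integers(0, len(layout.chromosomes)))
                name = layout.chrom_names[ci]
                n = len(layout.probes[name])
                L = int(min(rng.integers(lo_len, hi_len + 1), n))
                start = int(rng.integers(0, n - L + 1))
                block = (start, start + L)
                if all(hi <= block[0] or lo >= block[1]
                       for lo, hi in occupied.get(name, [])):
                    occupied.setdefault(name, []).append(block)
                    placed.append((name, block[0], block[1], kind))
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"cannot place requested {kind} events without overlap; "
                    "reduce counts or lengths"
                )
    return placed


def simulate_truth(layout: GenomeLayout, spec: AberrationSpec, purity: float,
                   target_ploidy: float, seed: int = 0,
                   c_max: int = DEFAULT_C_MAX) -> TruthProfile:
    """Plant the requested aberrations on a baseline genome and report the
    realized (length-weighted) ploidy."""
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if not 1 <= target_ploidy <= c_max:
        raise ValueError(f"target ploidy must be in [1, {c_max}]")
    baseline = int(round(target_ploidy))
    rng = child_rng(seed, 202)

    occupied: dict = {}
    whole_loss_chroms = []
    if spec.whole_chromosome_losses:
        if spec.whole_chromosome_losses > len(layout.chromosomes):
            raise ValueError("more whole-chromosome losses than chromosomes")
        idx = rng.choice(len(layout.chromosomes),
                         size=spec.whole_chromosome_losses, replace=False)
        for ci in sorted(int(i) for i in idx):
            name = layout.chrom_names[ci]
            whole_loss_chroms.append(name)
            occupied[name] = [(0, len(layout.probes[name]))]

    events = _place_events(
        rng, layout,
        [("gain", spec.n_gains, spec.gain_length),
         ("loss", spec.n_losses, spec.loss_length),
         ("hd", spec.n_hd, spec.hd_length),
         ("amplicon", spec.n_amplicons, spec.amplicon_length)],
        occupied,
    )

    amp_min = int(np.ceil(target_ploidy * 2.0 ** 0.811))
    if amp_min > c_max:
        raise ValueError("amplicons cannot exceed the amplification threshold at c_max")

    def event_cn(kind):
        if kind == "gain":
            return min(baseline + 1, c_max)
        if kind == "loss":
            return max(baseline - 1, 0)
        if kind == "hd":
            return 0
        return int(rng.integers(amp_min, min(c_max, amp_min + 3) + 1))

    by_chrom: dict = {name: [] for name in layout.chrom_names}
    for name, lo, hi, kind in events:
        by_chrom[name].append((lo, hi, event_cn(kind)))
    for name in whole_loss_chroms:
        by_chrom[name] = [(0, len(layout.probes[name]), max(baseline - 1, 0))]

    segments = []
    for name in layout.chrom_names:
        pos = layout.probes[name]
        length = layout.length_of(name)
        blocks = sorted(by_chrom[name])
        cursor = 0  # probe index
        probe_blocks = []
        for lo, hi, c in blocks:
            if lo > cursor:
                probe_blocks.append((cursor, lo, baseline))
            probe_blocks.append((lo, hi, c))
            cursor = hi
        if cursor < len(pos) or not probe_blocks:
            probe_blocks.append((cursor, len(pos), baseline))
        for lo, hi, c in probe_blocks:
            gstart = 0 if lo == 0 else int(pos[lo])
            gend = length if hi == len(pos) else int(pos[hi])
            segments.append((name, gstart, gend, int(c)))

    lengths = np.array([e - s for _, s, e, _ in segments], dtype=float)
    cns = np.array([c for *_, c in segments], dtype=float)
    ploidy = float(np.average(cns, weights=lengths))
    return TruthProfile(segments=segments, purity=purity, ploidy=ploidy)


def render_ratios(truth: TruthProfile, layout: GenomeLayout, noise: NoiseModel,
                  sample_id: str = "synthetic",
                  floor: float = DEFAULT_LOG2_FLOOR) -> RatioProfile:
    """Forward-simulate the per-probe log2-ratio profile for one sample."""
    cn = truth.probe_copy_numbers(layout)
    clean = mixture_log2(cn, truth.purity, truth.ploidy, floor=floor)
    rng = np.random.default_rng(int(noise.seed) & 0x7FFFFFFF)
    values = clean + rng.normal(0.0, noise.sd, size=clean.shape)
    frame = layout.probe_frame()
    frame["log2"] = values
    return RatioProfile(sample_id=sample_id, data=frame[RATIO_COLUMNS],
                        chrom_order=layout.chrom_names)


def write_truth(truth: TruthProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# purity={truth.purity}\n# ploidy={truth.ploidy}\n")
        fh.write("chromosome\tstart\tend\tcopy_number\n")
        for chrom, s, e, c in truth.segments:
            fh.write(f"{chrom}\t{s}\t{e}\t{c}\n")
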