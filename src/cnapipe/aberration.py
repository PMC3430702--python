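"""Aberration calling, cohort frequency tracks and recurrence analysis.

Calls are made on the purity-free track log2(c_hat/psi_hat). The class
thresholds come from the distribution of recalculated log2 ratios in the
renal-carcinoma cohort this pipeline was built around: gain/loss at +/-0.377,
amplification at +0.811, and homozygous deletion wherever the estimated copy
number is 0. Classes are mutually exclusive with precedence
HD > amplification > gain > loss > neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .cn_estimation import CopyNumberProfile
from .io import GeneModel

AMPLIFICATION = "amplification"
GAIN = "gain"
NEUTRAL = "neutral"
LOSS = "loss"
HOMOZYGOUS_DELETION = "homozygous_deletion"

CLASSES = (AMPLIFICATION, GAIN, NEUTRAL, LOSS, HOMOZYGOUS_DELETION)
ABERRANT_CLASSES = (AMPLIFICATION, GAIN, LOSS, HOMOZYGOUS_DELETION)


@dataclass(frozen=True)
class CallerConfig:
    gain_loss_threshold: float = 0.377
    amplification_threshold: float = 0.811
    # display grading of amplifications (upper bin edges on log2(c/psi))
    amplification_grades: tuple = (1.2, 1.6, 2.0)

    def __post_init__(self) -> None:
        if not 0 < self.gain_loss_threshold < self.amplification_threshold:
            raise ValueError("need 0 < gain/loss threshold < amplification threshold")


@dataclass
class AberrationCall:
    """Per-probe aberration classes for one sample."""

    sample_id: str
    probes: pd.DataFrame  # chromosome, start, end, probe_id, copy_number, class

    @property
    def classes(self) -> np.ndarray:
        return self.probes["class"].to_numpy()


@dataclass(frozen=True)
class RecurrentRegion:
    chromosome: str
    start: int
    end: int
    support: int
    cls: str


def classify_track(copy_number: np.ndarray, track: np.ndarray,
                   config: CallerConfig) -> np.ndarray:
    """Vectorized class assignment; HD wins regardless of the track value."""
    copy_number = np.asarray(copy_number)
    track = np.asarray(track, dtype=float)
    out = np.full(track.shape, NEUTRAL, dtype=object)
    out[track < -config.gain_loss_threshold] = LOSS
    out[track > config.gain_loss_threshold] = GAIN
    out[track > config.amplification_threshold] = AMPLIFICATION
    out[copy_number == 0] = HOMOZYGOUS_DELETION
    return out


def call_probes(cn: CopyNumberProfile, config: CallerConfig = CallerConfig()
                ) -> AberrationCall:
    """Threshold the per-probe log2(c/psi) track into aberration classes."""
    probes = cn.probes[["chromosome", "start", "end", "probe_id", "copy_number",
                        "log2_cn_over_ploidy"]].copy()
    probes["class"] = classify_track(cn.probes["copy_number"].to_numpy(),
                                     cn.track, config)
    return AberrationCall(sample_id=cn.sample_id, probes=probes)


def amplification_grade(track_value: float, config: CallerConfig = CallerConfig()
                        ) -> int:
    """Display grade 1..4 for amplified values, 0 below the threshold."""
    if track_value <= config.amplification_threshold:
        return 0
    for grade, edge in enumerate(config.amplification_grades, start=1):
        if track_value <= edge:
            return grade
    return len(config.amplification_grades) + 1


def _check_common_grid(calls: Sequence[AberrationCall]) -> pd.DataFrame:
    if not calls:
        raise ValueError("need at least one call set")
    ref = calls[0].probes[["chromosome", "start", "end", "probe_id"]]
    for c in calls[1:]:
        grid = c.probes[["chromosome", "start", "end", "probe_id"]]
        if len(grid) != len(ref) or not grid.reset_index(drop=True).equals(
                ref.reset_index(drop=True)):
            raise ValueError(f"{c.sample_id}: probe grid differs from {calls[0].sample_id}")
    return ref.reset_index(drop=True)


def frequency_track(calls: Sequence[AberrationCall]) -> pd.DataFrame:
    """Cohort fraction of each non-neutral class at every probe.

    Returns chromosome, start, end, probe_id, f_amp, f_gain, f_loss, f_hd.
    """
    grid = _check_common_grid(calls)
    n = len(calls)
    stacked = np.stack([c.classes for c in calls])
    out = grid.copy()
    for col, cls in (("f_amp", AMPLIFICATION), ("f_gain", GAIN),
                     ("f_loss", LOSS), ("f_hd", HOMOZYGOUS_DELETION)):
        out[col] = (stacked == cls).sum(axis=0) / n
    return out


def most_overlapping_section(calls: Sequence[AberrationCall], chromosome: str,
                             cls: str) -> RecurrentRegion:
    """Maximal-support genomic interval for one class on one chromosome.

    Support at a probe is the number of samples carrying the class there; the
    returned region is the run of maximal-support probes, the longest run in
    base pairs when tied, the leftmost when still tied.
    """
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}")
    grid = _check_common_grid(calls)
    on_chrom = grid["chromosome"].to_numpy() == chromosome
    if not on_chrom.any():
        raise ValueError(f"no probes on {chromosome}")
    stacked = np.stack([c.classes for c in calls])[:, on_chrom]
    support = (stacked == cls).sum(axis=0)
    best = int(support.max())
    if best == 0:
        raise ValueError(f"class {cls} absent on {chromosome}")
    starts = grid.loc[on_chrom, "start"].to_numpy()
    ends = grid.loc[on_chrom, "end"].to_numpy()
    # a run can only extend while the *same* samples stay aberrant: the
    # support of an interval is the number of samples aberrant over all of it
    hit = stacked == cls
    at_peak = support == best
    same_set = np.all(hit[:, 1:] == hit[:, :-1], axis=0)
    extendable = at_peak[1:] & at_peak[:-1] & same_set
    spans = []
    k = 0
    n_probes = len(support)
    while k < n_probes:
        if not at_peak[k]:
            k += 1
            continue
        j = k
        while j + 1 < n_probes and extendable[j]:
            j += 1
        spans.append((int(starts[k]), int(ends[j])))
        k = j + 1
    start, end = max(spans, key=lambda se: (se[1] - se[0], -se[0]))
    return RecurrentRegion(chromosome=chromosome, start=start, end=end,
                           support=best, cls=cls)


def genes_in_calls(calls: Sequence[AberrationCall], genes: Iterable[GeneModel],
                   cls: str, min_samples: int = 2) -> List[tuple]:
    """Genes recurrently hit by a class across the cohort.

    A gene counts for a sample when every probe overlapping it carries the
    class (homozygous deletion: "completely deleted") or when at least one
    does (all other classes). Genes with no overlapping probes are skipped
    with a warning. Returns (gene_id, n_samples) with n >= min_samples,
    ordered by descending support then gene id.
    """
    grid = _check_common_grid(calls)
    stacked = np.stack([c.classes for c in calls])
    results = []
    for gene in genes:
        mask = ((grid["chromosome"].to_numpy() == gene.chromosome)
                & (grid["start"].to_numpy() < gene.end)
                & (grid["end"].to_numpy() > gene.start))
        if not mask.any():
            warnings.warn(f"gene {gene.gene_id}: no overlapping probes; skipped",
                          stacklevel=2)
            continue
        hits = stacked[:, mask] == cls
        per_sample = hits.all(axis=1) if cls == HOMOZYGOUS_DELETION else hits.any(axis=1)
        n = int(per_sample.sum())
        if n >= min_samples:
            results.append((gene.gene_id, n))
    return sorted(results, key=lambda t: (-t[1], t[0]))


def write_calls(call: AberrationCall, path) -> None:
    df = call.probes.copy()
    df.insert(0, "sample", call.sample_id)
    df.to_csv(path, sep="\t", index=False)


def read_calls(path) -> AberrationCall:
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no calls")
    sample = str(df["sample"].iloc[0])
    return AberrationCall(sample_id=sample, probes=df.drop(columns=["sample"]))


def write_frequency(freq: pd.DataFrame, path) -> None:
    freq.to_csv(path, sep="\t", index=False)
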