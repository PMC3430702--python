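"""Shared helpers: chromosome ordering and seeded random-number streams."""

from __future__ import annotations

import re

import numpy as np

_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def chrom_sort_key(name: str) -> tuple:
    """Natural chromosome order: chr1 < chr2 < ... < chr10 < ... < chrX < chrY.

    Non-numeric, non-X/Y names sort after Y, alphabetically.
    """
    body = _CHROM_RE.match(str(name)).group(2)
    if body.isdigit():
        return (0, int(body), "")
    upper = body.upper()
    if upper == "X":
        return (1, 0, "")
    if upper == "Y":
        return (1, 1, "")
    return (2, 0, body)


def sort_chromosomes(names) -> list:
    """Unique chromosome names in natural order."""
    return sorted(dict.fromkeys(names), key=chrom_sort_key)


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent generator for a sub-task, deterministic in (seed, keys).

    Keys isolate per-chromosome / per-sample streams so that results for one
    unit do not depend on how many draws another unit consumed.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]])
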