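"""Sliding-window quality trimming of short-read data.

Reproduces the classic windowed trimmer applied to the paired-end short
reads before co-assembly: a window of ``window_frac`` of the read length
slides 5'->3'; the 5' end is trimmed up to the first window whose mean
quality reaches the threshold, and the 3' end from the first later window
whose mean quality drops below it. Reads shorter than ``min_length`` after
trimming are discarded. Defaults (Q20, 10% window, 20 bp) are the trimmer's
documented defaults.

Long single-end reads (platform A) are deliberately not quality-trimmed by
the pipeline; only the short paired-end stream passes through here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .simdata import Read

DEFAULT_Q = 20
DEFAULT_WINDOW_FRAC = 0.1
DEFAULT_MIN_LENGTH = 20


@dataclass
class TrimResult:
    """Outcome of trimming a paired library: surviving pairs, orphaned singles, discards."""

    kept_pairs: list[tuple[Read, Read]] = field(default_factory=list)
    kept_singles: list[Read] = field(default_factory=list)
    discarded_count: int = 0


def trim_read(
    read: Read,
    q_threshold: int = DEFAULT_Q,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> Optional[Read]:
    """Trim one read; returns the trimmed read or None when discarded.

    The kept region runs from the start of the first window whose mean
    quality >= ``q_threshold`` to just before the start of the first
    subsequent window whose mean quality falls below it. The result is
    always a contiguous substring of the input.
    """
    if not 0.0 < window_frac <= 1.0:
        raise ValueError("window_frac must lie in (0,1]")
    if q_threshold < 0:
        raise ValueError("q_threshold must be >= 0")
    n = len(read.sequence)
    if n == 0:
        return None
    w = max(1, round(window_frac * n))
    q = np.asarray(read.qualities, dtype=float)
    cum = np.concatenate(([0.0], np.cumsum(q)))
    means = (cum[w:] - cum[:-w]) / w  # mean of window starting at i, i = 0..n-w
    good = means >= q_threshold
    first = np.argmax(good) if good.any() else None
    if first is None:
        return None
    later_bad = ~good[first + 1 :]
    cut = first + 1 + int(np.argmax(later_bad)) if later_bad.any() else n
    start, end = int(first), int(cut)
    if end - start < min_length:
        return None
    return replace(
        read,
        sequence=read.sequence[start:end],
        qualities=read.qualities[start:end],
    )


def trim_pairs(
    r1_reads: Sequence[Read],
    r2_reads: Sequence[Read],
    q_threshold: int = DEFAULT_Q,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    min_length: int = DEFAULT_MIN_LENGTH,
) -> TrimResult:
    """Trim mate pairs aligned by index; orphaned survivors become singles."""
    if len(r1_reads) != len(r2_reads):
        raise ValueError("r1 and r2 read lists differ in length")
    out = TrimResult()
    for r1, r2 in zip(r1_reads, r2_reads):
        t1 = trim_read(r1, q_threshold, window_frac, min_length)
        t2 = trim_read(r2, q_threshold, window_frac, min_length)
        if t1 is not None and t2 is not None:
            out.kept_pairs.append((t1, t2))
        elif t1 is not None:
            out.kept_singles.append(replace(t1, mate_id=None))
            out.discarded_count += 1
        elif t2 is not None:
            out.kept_singles.append(replace(t2, mate_id=None))
            out.discarded_count += 1
        else:
            out.discarded_count += 2
    return out
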