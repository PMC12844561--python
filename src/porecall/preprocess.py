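"""Raw-trace preprocessing: open-pore trimming, MAD normalization, chunking,
and the training-time coverage filter.

Normalization is per read over the trimmed (DNA-bound) region, so the
overlapping chunks cut from one read agree numerically sample for sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .sim import RawRead

DEFAULT_CHUNK_LEN = 6000
DEFAULT_OVERLAP = 500


class NoDNASignalError(ValueError):
    """Raised when a trace never leaves the open-pore state."""


class ZeroMADError(ValueError):
    """Raised when a segment is constant (MAD = 0) and cannot be normalized."""


@dataclass
class NormalizedSignal:
    """MAD-normalized DNA-bound region of one read.

    ``samples`` is (x - median) / MAD of the retained [trim_start, trim_end)
    window of the raw trace; median_pA and mad_pA let callers map pore-model
    levels (pA) into the normalized domain.
    """

    read_id: str
    samples: np.ndarray
    median_pA: float
    mad_pA: float
    trim_start: int
    trim_end: int


@dataclass
class Chunk:
    """Fixed-length window of a normalized signal.

    ``signal_offset`` is the index of the first element within the normalized
    signal (trimmed coordinates); the final chunk of a read is right-padded
    with zeros (the post-normalization median) and flagged.
    """

    read_id: str
    samples: np.ndarray
    signal_offset: int
    is_padded: bool = False
    pad_len: int = 0


# ------------------------------------------------------------------ trim
def trim_open_pore(
    raw: RawRead,
    threshold_pA: float | None = None,
    window: int = 25,
) -> tuple[int, int]:
    """Locate the DNA-bound window of a raw trace.

    Returns the longest half-open [start, end) window whose rolling median
    (box window of ``window`` samples) stays below the open-pore threshold.
    By default the threshold is an Otsu split of the sample histogram, which
    lands between the open-pore mode and the 100-200 pA DNA band; traces with
    too little spread for a meaningful split are kept whole (or rejected as
    open-pore-only when their median is above the DNA band).  A fixed
    ``threshold_pA`` overrides the automatic strategy.

    Raises NoDNASignalError if no sample lies below the threshold.
    """
    x = np.asarray(raw.signal, dtype=np.float64)
    if x.size == 0:
        raise ValueError("empty trace")

    if threshold_pA is None:
        spread = np.percentile(x, 95) - np.percentile(x, 5)
        if spread < 20.0:  # unimodal: all DNA or all open pore
            if np.median(x) > 200.0:
                raise NoDNASignalError(raw.read_id)
            return 0, x.size
        from skimage.filters import threshold_otsu

        # Otsu alone splits inside the DNA band when the open-pore fraction
        # is small; the midpoint between the trace's upper extreme (open
        # pore) and its median (DNA band center) is robust to that, so take
        # whichever is higher.
        upper_mode = np.percentile(x, 99.9)
        threshold_pA = max(float(threshold_otsu(x)),
                           0.5 * (upper_mode + float(np.median(x))))

    rolling = median_filter(x, size=window, mode="nearest")
    below = rolling < threshold_pA
    if not below.any():
        raise NoDNASignalError(raw.read_id)
    # longest run of below-threshold rolling median
    edges = np.diff(np.concatenate([[0], below.view(np.int8), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    best = np.argmax(ends - starts)
    return int(starts[best]), int(ends[best])


# ------------------------------------------------------------- normalize
def mad_normalize(segment: np.ndarray, read_id: str = "", trim_start: int = 0,
                  trim_end: int | None = None) -> NormalizedSignal:
    """(x - median) / MAD with MAD = median(|x - median|), no 1.4826 factor."""
    x = np.asarray(segment, dtype=np.float64)
    if x.size < 2:
        raise ValueError("segment too short to normalize")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        raise ZeroMADError("zero MAD: constant segment")
    out = (x - med) / mad
    return NormalizedSignal(
        read_id=read_id,
        samples=out,
        median_pA=med,
        mad_pA=mad,
        trim_start=trim_start,
        trim_end=x.size + trim_start if trim_end is None else trim_end,
    )


def normalize_read(raw: RawRead, threshold_pA: float | None = None) -> NormalizedSignal:
    """Trim the open-pore prefix/suffix and MAD-normalize the DNA region."""
    start, end = trim_open_pore(raw, threshold_pA=threshold_pA)
    return mad_normalize(raw.signal[start:end], read_id=raw.read_id,
                         trim_start=start, trim_end=end)


# --------------------------------------------------------------- chunking
def chunk_signal(
    norm: NormalizedSignal,
    chunk_len: int = DEFAULT_CHUNK_LEN,
    overlap: int = DEFAULT_OVERLAP,
) -> list[Chunk]:
    """Cut a normalized signal into overlapping fixed-length chunks.

    Chunks start at multiples of (chunk_len - overlap); the final chunk is
    zero-padded on the right and flagged.  Every sample belongs to at least
    one chunk.
    """
    if not chunk_len > overlap >= 0:
        raise ValueError("need chunk_len > overlap >= 0")
    x = norm.samples
    step = chunk_len - overlap
    chunks: list[Chunk] = []
    offset = 0
    while True:
        piece = x[offset : offset + chunk_len]
        pad = chunk_len - piece.size
        if pad > 0:
            piece = np.concatenate([piece, np.zeros(pad)])
        chunks.append(
            Chunk(norm.read_id, piece, offset, is_padded=pad > 0, pad_len=pad)
        )
        if offset + chunk_len >= x.size:
            break
        offset += step
    return chunks


# ---------------------------------------------------------------- filter
def coverage_filter(
    chunks: list[Chunk],
    covered_spans: np.ndarray,
    min_coverage: float = 0.95,
) -> list[Chunk]:
    """Training-time filter: keep chunks whose unpadded samples are
    sufficiently covered by spans of reference-aligned bases.

    ``covered_spans`` is an (n, 2) array of half-open [start, end) sample
    intervals (same coordinate system as Chunk.signal_offset).  Coverage is
    the fraction of a chunk's unpadded samples inside the union of spans;
    chunks with coverage <= min_coverage are dropped (the boundary itself is
    excluded: exactly 95% is filtered out).
    """
    spans = np.asarray(covered_spans, dtype=np.int64).reshape(-1, 2)
    if spans.size:
        order = np.argsort(spans[:, 0], kind="stable")
        spans = spans[order]
        merged = [spans[0].copy()]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append(np.array([s, e]))
        spans = np.array(merged)

    kept = []
    for chunk in chunks:
        n = len(chunk.samples) - chunk.pad_len
        if n <= 0:
            continue
        lo, hi = chunk.signal_offset, chunk.signal_offset + n
        covered = 0
        for s, e in spans:
            covered += max(0, min(hi, e) - max(lo, s))
        if covered / n > min_coverage:
            kept.append(chunk)
    return kept


def spans_from_alignment(aligned_query_positions: np.ndarray,
                         base_spans: np.ndarray) -> np.ndarray:
    """Signal spans of the bases that align to the reference (M/=/X columns),
    for coverage filtering of real data."""
    return np.asarray(base_spans)[np.asarray(aligned_query_positions, dtype=np.intp)]
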