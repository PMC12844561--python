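"""End-to-end glue: raw trace -> chunks -> basecalls -> stitched reads,
training-set construction from simulated truth, and methylation calling on
whole reads."""

from __future__ import annotations

import numpy as np

from .basecaller import BasecallerResults, encode_target
from .decoder import beam_decode, greedy_decode
from .methcaller import MethCall, MethylationResults, call_read_sites
from .preprocess import (
    NormalizedSignal,
    chunk_signal,
    coverage_filter,
    normalize_read,
)
from .sim import RawRead, TruthRecord
from .stitcher import ReadCall, stitch


def targets_for_chunk(chunk, base_spans: np.ndarray, sequence: str) -> str:
    """Bases whose signal spans lie fully inside the chunk's unpadded
    window (spans in the same coordinate system as chunk.signal_offset)."""
    n = len(chunk.samples) - chunk.pad_len
    lo, hi = chunk.signal_offset, chunk.signal_offset + n
    spans = np.asarray(base_spans)
    mask = (spans[:, 0] >= lo) & (spans[:, 1] <= hi)
    return "".join(np.array(list(sequence))[mask]) if mask.any() else ""


def frame_labels_for_chunk(chunk, base_spans: np.ndarray, sequence: str,
                           stride: int) -> np.ndarray:
    """A dense valid CTC path for the chunk's contained bases.

    Bases are laid out left to right: each contained base claims the frames
    spanning its samples but always at least one frame (short-dwell bases
    are pushed right past their predecessor rather than dropped), and a
    blank frame is inserted between consecutive identical bases so the
    CTC collapse reproduces the target exactly.  Frames outside any
    contained span are blank.  Returns an all-blank labeling only if the
    chunk ran out of frames (possible at a crowded chunk tail)."""
    n = len(chunk.samples) - chunk.pad_len
    n_frames = len(chunk.samples) // stride
    labels = np.zeros(n_frames, dtype=np.int64)
    lo = chunk.signal_offset
    spans = np.asarray(base_spans)

    prev_end = -1  # last frame used so far
    prev_base: str | None = None
    for i, (s, e) in enumerate(spans):
        if not (s >= lo and e <= lo + n):
            continue
        f_lo = max(prev_end + 1, int(round((s - lo) / stride)))
        if prev_base == sequence[i] and f_lo == prev_end + 1:
            f_lo += 1  # blank separator between identical neighbours
        f_hi = max(f_lo, min(n_frames - 1, int(round((e - lo) / stride)) - 1))
        if f_lo >= n_frames:
            break
        labels[f_lo : f_hi + 1] = encode_target(sequence[i])[0]
        prev_end = f_hi
        prev_base = sequence[i]
    return labels


def make_basecall_training_set(
    reads: list[RawRead],
    truths: list[TruthRecord],
    chunk_len: int = 6000,
    overlap: int = 500,
    min_coverage: float = 0.95,
    stride: int = 5,
    trim_threshold_pA: float | None = None,
):
    """(chunks, targets, frame_targets) for basecaller training.

    Each read is trimmed, MAD-normalized, chunked, coverage-filtered against
    its truth base spans, and paired with the bases fully contained in each
    chunk.  ``frame_targets`` are span-derived single-path CTC labelings for
    the alignment-bootstrap phase.  Chunks with empty targets are dropped.
    """
    all_chunks, all_targets, all_frames = [], [], []
    for raw, truth in zip(reads, truths, strict=True):
        norm = normalize_read(raw, threshold_pA=trim_threshold_pA)
        spans = truth.base_spans - norm.trim_start
        chunks = chunk_signal(norm, chunk_len, overlap)
        for chunk in coverage_filter(chunks, spans, min_coverage):
            target = targets_for_chunk(chunk, spans, truth.sequence)
            if target:
                all_chunks.append(chunk.samples)
                all_targets.append(encode_target(target))
                all_frames.append(
                    frame_labels_for_chunk(chunk, spans, truth.sequence,
                                           stride)
                )
    if not all_chunks:
        raise ValueError("no usable training chunks")
    return (np.asarray(all_chunks, dtype=np.float32), all_targets,
            np.asarray(all_frames))


def basecall_read(
    raw: RawRead,
    results: BasecallerResults,
    overlap: int = 500,
    decoder: str = "greedy",
    beam_width: int = 8,
    trim_threshold_pA: float | None = None,
) -> tuple[ReadCall, NormalizedSignal]:
    """Full single-read basecall: trim, normalize, chunk, call, decode,
    stitch.  Returns the stitched ReadCall (with base->signal spans in
    trimmed coordinates) and the normalized signal."""
    cfg = results.config
    norm = normalize_read(raw, threshold_pA=trim_threshold_pA)
    chunks = chunk_signal(norm, cfg.chunk_len, overlap)
    calls = results.predict(
        [c.samples for c in chunks],
        read_ids=[raw.read_id] * len(chunks),
        signal_offsets=[c.signal_offset for c in chunks],
    )
    if decoder == "greedy":
        decodes = [greedy_decode(c) for c in calls]
    elif decoder == "beam":
        decodes = [beam_decode(c, beam_width) for c in calls]
    else:
        raise ValueError("decoder must be 'greedy' or 'beam'")
    read_call = stitch(decodes, cfg.chunk_len, overlap,
                       stride=cfg.cumulative_stride)
    return read_call, norm


def basecall_run(reads, results, **kwargs) -> list[ReadCall]:
    out = []
    for raw in reads:
        call, _ = basecall_read(raw, results, **kwargs)
        out.append(call)
    return out


def methcall_read(
    read_call: ReadCall,
    norm: NormalizedSignal,
    results: MethylationResults,
    threshold: float = 0.5,
) -> list[MethCall]:
    """Methylation calls on a basecalled read, using the decoder-derived
    base->signal spans."""
    if read_call.base_spans is None:
        raise ValueError("read call carries no base->signal spans")
    return call_read_sites(
        read_call.sequence,
        read_call.base_spans,
        norm.samples,
        results,
        threshold=threshold,
        read_id=read_call.read_id,
    )


def attach_reference_sites(calls: list[MethCall], truth: TruthRecord) -> None:
    """Map read-coordinate calls to forward-strand reference sites using a
    truth record (valid when the calls' positions are truth coordinates)."""
    for c in calls:
        c.ref = truth.reference_name
        c.ref_pos = truth.ref_site(c.position)
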