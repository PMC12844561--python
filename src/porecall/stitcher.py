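"""Merge overlapping chunk decodes into full reads; FASTQ IO; pass rates.

Adjacent chunks overlap by a fixed number of samples; the stitcher cuts each
overlap at its midpoint in absolute signal coordinates and keeps left-chunk
bases strictly before the midpoint and right-chunk bases at or after it.
When the base-to-signal maps of the two chunks are consistent this is exact:
no base is duplicated or dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoder import ChunkDecode

PHRED_OFFSET = 33


@dataclass
class ReadCall:
    """Stitched read: sequence, Phred qualities, and the absolute signal
    sample (run center) of every base."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    base_signal_pos: np.ndarray
    base_spans: np.ndarray | None = None  # (n, 2) signal spans when known

    @property
    def mean_q(self) -> float:
        return float(np.mean(self.qualities)) if len(self.qualities) else 0.0


def base_signal_positions(decode: ChunkDecode, stride: int) -> np.ndarray:
    """Absolute signal sample of each base: center of its emitting-frame run
    mapped through the conv stride and the chunk's signal offset.

    The center uses integer floor arithmetic so that overlapping chunks
    assign identical absolute positions to the same base (a float round
    here would make the result depend on the chunk offset at exact
    half-sample centers, duplicating or dropping a base at the cut)."""
    pos = np.array(
        [
            decode.signal_offset
            + ((min(f) + max(f)) * stride) // 2
            + stride // 2
            for f in decode.base_frames
        ],
        dtype=np.int64,
    )
    return pos


def stitch(decodes: list[ChunkDecode], chunk_len: int, overlap: int,
           stride: int = 1) -> ReadCall:
    """Merge chunk decodes (sorted by signal_offset) into one ReadCall.

    Cut points sit at overlap midpoints in absolute signal coordinates.
    Adjacent chunks that do not overlap are joined whole with a warning (a
    hard gap in the read)."""
    if not decodes:
        raise ValueError("no decodes to stitch")
    decodes = sorted(decodes, key=lambda d: d.signal_offset)
    read_id = decodes[0].read_id

    positions = [base_signal_positions(d, stride) for d in decodes]
    seq_parts: list[str] = []
    qual_parts: list[np.ndarray] = []
    pos_parts: list[np.ndarray] = []
    span_parts: list[np.ndarray] = []
    lo = -np.inf
    for i, d in enumerate(decodes):
        if i + 1 < len(decodes):
            nxt = decodes[i + 1]
            right_end = d.signal_offset + chunk_len
            if nxt.signal_offset >= right_end:
                warnings.warn(
                    f"non-overlapping chunks at offsets {d.signal_offset} and "
                    f"{nxt.signal_offset}: joining across a hard gap",
                    stacklevel=2,
                )
                hi = nxt.signal_offset  # no bases dropped on either side
            else:
                hi = (nxt.signal_offset + right_end) / 2.0
        else:
            hi = np.inf
        keep = (positions[i] >= lo) & (positions[i] < hi)
        seq_parts.append("".join(np.array(list(d.sequence))[keep]) if keep.any()
                         else "")
        qual_parts.append(d.base_qual[keep])
        pos_parts.append(positions[i][keep])
        spans = np.array(
            [
                [d.signal_offset + min(f) * stride,
                 d.signal_offset + (max(f) + 1) * stride]
                for f in d.base_frames
            ],
            dtype=np.int64,
        ).reshape(-1, 2)
        span_parts.append(spans[keep])
        lo = hi

    quals = (np.concatenate(qual_parts) if qual_parts
             else np.array([], dtype=np.int64))
    pos = (np.concatenate(pos_parts) if pos_parts
           else np.array([], dtype=np.int64))
    spans_all = (np.concatenate(span_parts) if span_parts
                 else np.zeros((0, 2), dtype=np.int64))
    return ReadCall(read_id, "".join(seq_parts), quals, pos,
                    base_spans=spans_all)


# ------------------------------------------------------------------ FASTQ
def write_fastq(read_calls: list[ReadCall], path) -> None:
    """Sanger FASTQ (Phred+33)."""
    with open(path, "w") as fh:
        for rc in read_calls:
            if len(rc.qualities) and (
                rc.qualities.min() < 0 or rc.qualities.max() > 93
            ):
                raise ValueError("quality outside encodable Sanger range")
            qual = "".join(chr(PHRED_OFFSET + int(q)) for q in rc.qualities)
            fh.write(f"@{rc.read_id}\n{rc.sequence}\n+\n{qual}\n")


def read_fastq(path) -> list[ReadCall]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = np.array(rec.letter_annotations["phred_quality"], dtype=np.int64)
        out.append(
            ReadCall(rec.id, str(rec.seq), quals,
                     np.arange(len(quals), dtype=np.int64))
        )
    return out


# -------------------------------------------------------------- pass rates
def pass_rates(read_calls: list[ReadCall],
               q_threshold: float = 10.0) -> tuple[float, float]:
    """Fraction of reads with mean quality >= threshold, and the fraction of
    all bases that belong to those passing reads."""
    if not read_calls:
        raise ValueError("pass_rates undefined for empty input")
    passing = [rc for rc in read_calls if rc.mean_q >= q_threshold]
    read_rate = len(passing) / len(read_calls)
    total_bases = sum(len(rc.sequence) for rc in read_calls)
    pass_bases = sum(len(rc.sequence) for rc in passing)
    base_rate = pass_bases / total_bases if total_bases else 0.0
    return read_rate, base_rate
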