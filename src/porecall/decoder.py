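"""CTC decoding of chunk probability matrices into base strings.

Greedy (best-path) decoding is the pipeline default: per-frame argmax,
collapse consecutive repeats, drop blanks.  A prefix beam search over
collapsed sequences is available as an opt-in higher-accuracy decoder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basecaller import CLASS_BASES, ChunkCall

QUAL_MIN, QUAL_MAX = 1, 50


@dataclass
class ChunkDecode:
    """Decoded chunk: bases, their emitting frames, probabilities and
    Phred qualities.  ``base_frames[i]`` lists the frames of base i's
    collapsed run (strictly increasing across bases)."""

    read_id: str
    sequence: str
    base_frames: list[list[int]]
    base_prob: np.ndarray
    base_qual: np.ndarray
    signal_offset: int = 0


def phred_from_prob(p: float) -> int:
    """q = round(-10 log10(1 - p)), clamped into [1, 50]."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability outside [0, 1]")
    if p >= 1.0:
        return QUAL_MAX
    q = int(round(-10.0 * np.log10(1.0 - p)))
    return min(max(q, QUAL_MIN), QUAL_MAX)


def greedy_decode(call: ChunkCall) -> ChunkDecode:
    """Best-path decode: argmax per frame, collapse repeats, drop blanks.

    Per-base probability is the maximum frame probability within the base's
    run (an upper bound on the emission confidence)."""
    probs = np.asarray(call.probs)
    path = probs.argmax(axis=1)
    frame_p = probs[np.arange(len(path)), path]

    seq: list[str] = []
    base_frames: list[list[int]] = []
    base_prob: list[float] = []
    prev = -1
    for t, cls in enumerate(path):
        if cls == 0:
            prev = 0
            continue
        if cls == prev:
            base_frames[-1].append(t)
            base_prob[-1] = max(base_prob[-1], float(frame_p[t]))
        else:
            seq.append(CLASS_BASES[cls - 1])
            base_frames.append([t])
            base_prob.append(float(frame_p[t]))
        prev = cls
    bp = np.array(base_prob)
    quals = np.array([phred_from_prob(p) for p in bp], dtype=np.int64)
    return ChunkDecode(
        read_id=call.read_id,
        sequence="".join(seq),
        base_frames=base_frames,
        base_prob=bp,
        base_qual=quals,
        signal_offset=call.signal_offset,
    )


def _viterbi_frames(probs: np.ndarray, classes: np.ndarray):
    """Most probable CTC alignment of a fixed label sequence to the frames;
    used to attach frame coordinates to beam-search outputs.  Returns
    per-base emitting frames and per-base max frame probability."""
    T = probs.shape[0]
    L = classes.size
    S = 2 * L + 1
    ext = np.zeros(S, dtype=np.int64)
    ext[1::2] = classes
    logp = np.log(np.clip(probs, 1e-300, None))
    score = np.full((T, S), -np.inf)
    back = np.zeros((T, S), dtype=np.int64)
    score[0, 0] = logp[0, 0]
    if S > 1:
        score[0, 1] = logp[0, ext[1]]
    for t in range(1, T):
        for s in range(S):
            cands = [score[t - 1, s]]
            srcs = [s]
            if s >= 1:
                cands.append(score[t - 1, s - 1])
                srcs.append(s - 1)
            if s >= 2 and ext[s] != 0 and ext[s] != ext[s - 2]:
                cands.append(score[t - 1, s - 2])
                srcs.append(s - 2)
            k = int(np.argmax(cands))
            score[t, s] = cands[k] + logp[t, ext[s]]
            back[t, s] = srcs[k]
    end = S - 1
    if S > 1 and score[T - 1, S - 2] > score[T - 1, S - 1]:
        end = S - 2
    states = np.zeros(T, dtype=np.int64)
    states[T - 1] = end
    for t in range(T - 1, 0, -1):
        states[t - 1] = back[t, states[t]]
    frames: list[list[int]] = [[] for _ in range(L)]
    for t, s in enumerate(states):
        if s % 2 == 1:
            frames[s // 2].append(t)
    max_p = np.array([probs[f, classes[i]].max() for i, f in enumerate(frames)])
    return frames, max_p


def beam_decode(call: ChunkCall, beam_width: int = 8) -> ChunkDecode:
    """Prefix beam search over collapsed sequences.

    Tracks, for every surviving collapsed prefix, the probability mass of
    paths ending in blank vs ending in the prefix's last symbol, and keeps
    the ``beam_width`` most probable prefixes per frame.  With a beam wide
    enough to be exhaustive, the returned sequence maximises the full
    collapsed-sequence posterior.  Frame coordinates and per-base
    probabilities come from a Viterbi alignment of the winning sequence.
    """
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    probs = np.asarray(call.probs, dtype=np.float64)
    T, C = probs.shape
    # prefix -> (p_blank, p_nonblank)
    beams: dict[tuple[int, ...], tuple[float, float]] = {(): (1.0, 0.0)}
    for t in range(T):
        new: dict[tuple[int, ...], list[float]] = {}

        def add(prefix, pb, pnb):
            cur = new.setdefault(prefix, [0.0, 0.0])
            cur[0] += pb
            cur[1] += pnb

        for prefix, (pb, pnb) in beams.items():
            p_tot = pb + pnb
            add(prefix, p_tot * probs[t, 0], 0.0)  # blank
            for c in range(1, C):
                p = probs[t, c]
                if prefix and prefix[-1] == c:
                    add(prefix, 0.0, pnb * p)        # repeat merged into run
                    add(prefix + (c,), 0.0, pb * p)  # new base after blank gap
                else:
                    add(prefix + (c,), 0.0, p_tot * p)
        ranked = sorted(new.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0]))
        beams = {k: (v[0], v[1]) for k, v in ranked[:beam_width]}

    best = max(beams.items(), key=lambda kv: kv[1][0] + kv[1][1])[0]
    classes = np.array(best, dtype=np.int64)
    if classes.size:
        frames, max_p = _viterbi_frames(probs, classes)
    else:
        frames, max_p = [], np.array([])
    quals = np.array([phred_from_prob(p) for p in max_p], dtype=np.int64)
    return ChunkDecode(
        read_id=call.read_id,
        sequence="".join(CLASS_BASES[c - 1] for c in best),
        base_frames=frames,
        base_prob=max_p,
        base_qual=quals,
        signal_offset=call.signal_offset,
    )
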