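"""Synthetic nanopore run generator.

Emulates the signal phenomenology of a helicase-regulated nanopore platform:
DNA-bound current in the 100-200 pA band, an elevated open-pore level before
the molecule enters, ~400 bases/s translocation against a fixed sampling
clock (so ~10 samples per base at the 4 kHz default), 5-mer-dependent levels
with Gaussian noise, dwell-time overdispersion, and an additive current shift
at 5mC-containing 5-mers.  Unlike the real platform it also emits ground
truth: the sequence, the per-base signal spans, and the per-CpG methylation
labels of every read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .pore_model import BASE_TO_INT, LEVEL_BAND, PoreModel, revcomp

__all__ = [
    "SimParams",
    "RawRead",
    "TruthRecord",
    "simulate_read",
    "simulate_run",
    "simulate_bs_table",
    "random_reference",
    "cpg_positions",
]


@dataclass
class SimParams:
    """Physical parameters of a simulated sequencing run.

    sampling_rate_hz / speed_bp_s is the mean dwell in samples per base
    (10 at the defaults) and must be >= 2.  ``dwell_dispersion`` is the
    negative-binomial overdispersion of the per-base dwell (variance =
    mu + dispersion * mu^2 around the shifted mean); 0 means every base
    dwells exactly round(mean) samples.  ``open_pore_len`` is a (lo, hi)
    range in samples, drawn uniformly per read, or a fixed integer.
    """

    sampling_rate_hz: float = 4000.0
    speed_bp_s: float = 400.0
    noise_sd_pA: float = 2.5
    open_pore_pA: float = 240.0
    open_pore_len: tuple[int, int] | int = (500, 2000)
    dwell_dispersion: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz / self.speed_bp_s < 2:
            raise ValueError("need >= 2 samples per base on average")
        if self.open_pore_pA <= LEVEL_BAND[1]:
            raise ValueError("open-pore current must exceed the DNA-bound band")
        if self.dwell_dispersion < 0:
            raise ValueError("dwell_dispersion must be >= 0")

    @property
    def mean_dwell(self) -> float:
        return self.sampling_rate_hz / self.speed_bp_s


@dataclass
class RawRead:
    """One read's current trace in picoamperes."""

    read_id: str
    signal: np.ndarray  # float32 pA samples
    sampling_rate_hz: float


@dataclass
class TruthRecord:
    """Ground truth for one simulated read.

    ``meth_positions`` are read-coordinate indices of CpG cytosines (C of a
    CG dinucleotide in ``sequence``); ``meth_labels`` are the matching 0/1
    methylation states.  ``base_spans`` is an (n_bases, 2) array of half-open
    [start, end) sample spans, contiguous and ordered.
    """

    read_id: str
    reference_name: str
    reference_start: int
    strand: str
    sequence: str
    meth_positions: np.ndarray
    meth_labels: np.ndarray
    base_spans: np.ndarray

    def ref_site(self, read_pos: int) -> int:
        """Forward-strand reference coordinate (C of the CG) for a
        read-coordinate CpG position."""
        if self.strand == "+":
            return self.reference_start + read_pos
        return self.reference_start + len(self.sequence) - 2 - read_pos


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide in ``seq``."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hits)


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([BASE_TO_INT[b] for b in seq], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"sequence contains non-ACGT base: {exc}") from None


def _draw_dwells(n: int, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Per-base dwell in samples: 1 + NB(mean mu, overdispersion), min 1."""
    mu = params.mean_dwell - 1.0
    if params.dwell_dispersion == 0.0 or mu <= 0:
        return np.full(n, max(1, round(params.mean_dwell)), dtype=np.int64)
    r = 1.0 / params.dwell_dispersion
    p = r / (r + mu)
    return 1 + rng.negative_binomial(r, p, size=n).astype(np.int64)


def simulate_read(
    sequence: str,
    meth_labels,
    pore_model: PoreModel,
    params: SimParams,
    rng: np.random.Generator | None = None,
    read_id: str = "read_0",
) -> tuple[RawRead, TruthRecord]:
    """Synthesise one read: open-pore prefix, then per-base k-mer levels
    repeated for a random dwell, plus Gaussian noise.

    ``meth_labels`` may be None (all unmethylated), a dict {read_pos: 0/1}
    keyed by CpG cytosine positions, or an array aligned with
    ``cpg_positions(sequence)``.  The draw order (open-pore length, dwells,
    noise) depends only on the sequence length, so re-simulating with the
    same rng state and different labels changes the signal only inside the
    k-mer spans that overlap the flipped cytosines.
    """
    k = pore_model.k
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _encode(sequence)
    if rng is None:
        rng = np.random.default_rng(params.seed)

    cpgs = cpg_positions(sequence)
    labels = np.zeros(len(cpgs), dtype=np.int8)
    if meth_labels is not None:
        if isinstance(meth_labels, dict):
            site_index = {int(p): i for i, p in enumerate(cpgs)}
            for pos, lab in meth_labels.items():
                if pos not in site_index:
                    raise ValueError(f"position {pos} is not a CpG cytosine")
                labels[site_index[pos]] = int(lab)
        else:
            meth_labels = np.asarray(meth_labels)
            if len(meth_labels) != len(cpgs):
                raise ValueError("meth_labels length != number of CpG sites")
            labels[:] = meth_labels

    # substitute M at methylated cytosines
    mod = codes.copy()
    mod[cpgs[labels == 1]] = BASE_TO_INT["M"]

    if isinstance(params.open_pore_len, (tuple, list)):
        lo, hi = params.open_pore_len
        open_len = int(rng.integers(lo, hi + 1))
    else:
        open_len = int(params.open_pore_len)
    dwells = _draw_dwells(len(codes), params, rng)

    # k-mer centered on base i; ends padded with A
    half = k // 2
    padded = np.concatenate([np.zeros(half, np.int64), mod, np.zeros(half, np.int64)])
    powers = 5 ** np.arange(k - 1, -1, -1)
    kmer_idx = sliding_window_view(padded, k) @ powers
    levels = pore_model.mean_levels_encoded(kmer_idx)

    total = open_len + int(dwells.sum())
    clean = np.empty(total, dtype=np.float64)
    clean[:open_len] = params.open_pore_pA
    clean[open_len:] = np.repeat(levels, dwells)
    if params.noise_sd_pA > 0:
        clean = clean + rng.normal(0.0, params.noise_sd_pA, size=total)

    ends = open_len + np.cumsum(dwells)
    spans = np.stack([ends - dwells, ends], axis=1)

    raw = RawRead(read_id, clean.astype(np.float32), params.sampling_rate_hz)
    truth = TruthRecord(
        read_id=read_id,
        reference_name="",
        reference_start=0,
        strand="+",
        sequence=sequence,
        meth_positions=cpgs,
        meth_labels=labels,
        base_spans=spans,
    )
    return raw, truth


def random_reference(
    length: int, seed: int, gc: float = 0.5, name: str = "ref"
) -> dict[str, str]:
    """A random reference genome with the given GC content."""
    rng = np.random.default_rng(seed)
    p_each = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p_each))
    return {name: seq}


def simulate_run(
    reference: dict[str, str],
    n_reads: int,
    pore_model: PoreModel,
    params: SimParams,
    read_len_range: tuple[int, int] = (1000, 2000),
    per_site_meth_prob=0.0,
    site_consistent: bool = False,
) -> tuple[list[RawRead], list[TruthRecord]]:
    """Simulate a sequencing run against a reference.

    Reads are drawn uniformly over positions and strands.  CpG sites are
    defined on the forward strand (a CG at i labels the C at i); minus-strand
    reads inherit the same site.  Each read's methylation state at a site is
    Bernoulli(per_site_meth_prob[site]) — independent draws per read, i.e.
    each read samples a distinct molecule from a population whose site
    methylation frequency is the given probability.  With
    ``site_consistent=True`` the state is instead drawn once per site and
    shared by every covering read.  ``per_site_meth_prob`` is a scalar or a
    {contig: {pos: p}} mapping.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not reference or any(len(s) == 0 for s in reference.values()):
        raise ValueError("reference must be non-empty")
    rng = np.random.default_rng(params.seed)

    contigs = list(reference)
    lengths = np.array([len(reference[c]) for c in contigs], dtype=float)
    weights = lengths / lengths.sum()

    # per-contig site probability arrays over forward-strand CpG positions
    site_prob: dict[str, dict[int, float]] = {}
    site_state: dict[str, dict[int, int]] = {}
    for c in contigs:
        sites = cpg_positions(reference[c])
        if np.isscalar(per_site_meth_prob):
            probs = {int(p): float(per_site_meth_prob) for p in sites}
        else:
            probs = {int(p): float(per_site_meth_prob[c][int(p)]) for p in sites}
        site_prob[c] = probs
        if site_consistent:
            site_state[c] = {p: int(rng.random() < q) for p, q in probs.items()}

    reads: list[RawRead] = []
    truths: list[TruthRecord] = []
    for i in range(n_reads):
        c = contigs[int(rng.choice(len(contigs), p=weights))]
        ref_seq = reference[c]
        lo, hi = read_len_range
        L = int(rng.integers(lo, min(hi, len(ref_seq)) + 1))
        start = int(rng.integers(0, len(ref_seq) - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        segment = ref_seq[start : start + L]
        read_seq = segment if strand == "+" else revcomp(segment)

        read_cpgs = cpg_positions(read_seq)
        labels = np.zeros(len(read_cpgs), dtype=np.int8)
        for j, rp in enumerate(read_cpgs):
            site = start + int(rp) if strand == "+" else start + L - 2 - int(rp)
            if site in site_prob[c]:
                if site_consistent:
                    labels[j] = site_state[c][site]
                else:
                    labels[j] = int(rng.random() < site_prob[c][site])

        raw, truth = simulate_read(
            read_seq, labels, pore_model, params, rng=rng, read_id=f"read_{i:05d}"
        )
        truth.reference_name = c
        truth.reference_start = start
        truth.strand = strand
        reads.append(raw)
        truths.append(truth)
    return reads, truths


def simulate_bs_table(site_probs, depth: int, seed: int):
    """BS-seq-style per-site methylation frequency table.

    ``site_probs``: {contig: {pos: p}}.  Per site the observed frequency is
    Binomial(depth, p) / depth, emulating finite bisulfite coverage.
    Returns a DataFrame (ref, pos, strand, coverage, frequency).
    """
    import pandas as pd

    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for ref in sorted(site_probs):
        for pos in sorted(site_probs[ref]):
            p = site_probs[ref][pos]
            freq = rng.binomial(depth, p) / depth
            rows.append((ref, int(pos), "+", depth, freq))
    return pd.DataFrame(
        rows, columns=["ref", "pos", "strand", "coverage", "frequency"]
    )
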