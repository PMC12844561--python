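"""k-mer pore model: expected current level per 5-mer, canonical and 5mC-modified.

The pore reads out roughly five consecutive nucleotides at a time, so the
expected (noise-free) current while base i occupies the central position is a
function of the 5-mer centered on i.  Canonical levels live in the 100-200 pA
band characteristic of the DNA-bound state; 5-methylcytosine (symbol ``M``)
perturbs the level of every 5-mer that contains it by an additive k-mer
specific shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

CANONICAL_BASES = "ACGT"
METH_BASE = "M"  # 5-methylcytosine
EXTENDED_BASES = CANONICAL_BASES + METH_BASE

# integer encoding used throughout the simulator: A=0 C=1 G=2 T=3 M=4
BASE_TO_INT = {b: i for i, b in enumerate(EXTENDED_BASES)}

LEVEL_BAND = (100.0, 200.0)  # pA band of DNA-bound current


def revcomp(seq: str) -> str:
    """Reverse complement over the extended alphabet (M pairs with G)."""
    comp = str.maketrans("ACGTMN", "TGCAGN")
    return seq.translate(comp)[::-1]


@dataclass
class PoreModel:
    """Map from 5-mers to expected current level and spread.

    Parameters
    ----------
    k : k-mer length (the pore reads k consecutive bases; 5 here).
    levels : canonical k-mer -> (mean_pA, sd_pA).
    meth_shift : k-mer containing ``M`` -> additive level shift in pA.  The
        level of an M-containing k-mer is the level of its C-demethylated
        counterpart plus this shift.
    """

    k: int
    levels: dict[str, tuple[float, float]]
    meth_shift: dict[str, float]
    _mean5: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()
        self._mean5 = self._build_mean_table()

    def validate(self) -> None:
        n_expected = 4**self.k
        if len(self.levels) != n_expected:
            raise ValueError(
                f"pore model must define all {n_expected} canonical {self.k}-mers, "
                f"got {len(self.levels)}"
            )
        lo, hi = LEVEL_BAND
        for kmer, (mean, sd) in self.levels.items():
            if not lo <= mean <= hi:
                raise ValueError(f"level of {kmer} ({mean} pA) outside [{lo}, {hi}]")
            if sd <= 0:
                raise ValueError(f"sd of {kmer} must be positive")
        n_meth = 5**self.k - 4**self.k
        if len(self.meth_shift) != n_meth:
            raise ValueError(
                f"meth_shift must cover all {n_meth} M-containing {self.k}-mers"
            )

    # ------------------------------------------------------------------
    def mean_level(self, kmer: str) -> float:
        """Expected current (pA) for a k-mer over the extended alphabet."""
        if METH_BASE in kmer:
            canon = kmer.replace(METH_BASE, "C")
            return self.levels[canon][0] + self.meth_shift[kmer]
        return self.levels[kmer][0]

    def _build_mean_table(self) -> np.ndarray:
        """Dense level table indexed by base-5 encoding of the k-mer."""
        k = self.k
        table = np.empty(5**k, dtype=np.float64)
        for kmer_tuple in product(EXTENDED_BASES, repeat=k):
            kmer = "".join(kmer_tuple)
            idx = 0
            for b in kmer:
                idx = idx * 5 + BASE_TO_INT[b]
            table[idx] = self.mean_level(kmer)
        return table

    def mean_levels_encoded(self, kmer_codes: np.ndarray) -> np.ndarray:
        """Vectorised level lookup for base-5 encoded k-mer indices."""
        return self._mean5[kmer_codes]


def build_default_pore_model(
    seed: int,
    k: int = 5,
    meth_shift_mean: float = 8.0,
    meth_shift_sd: float = 3.0,
    meth_shift_pos_frac: float = 0.75,
) -> PoreModel:
    """Draw a random but reproducible pore model.

    Canonical 5-mer levels are built from per-(position, base) contributions —
    so each base leaves a position-dependent fingerprint on the level, the
    central position weighted most — plus a small k-mer specific deviation,
    then affinely mapped into the 100-200 pA DNA-bound band.

    5mC shifts: for every M-containing k-mer, magnitude ~ N(meth_shift_mean,
    meth_shift_sd) pA with a random sign drawn positive with probability
    ``meth_shift_pos_frac``.  The default bias (0.75) gives methylation a
    dominant current direction with k-mer-specific exceptions, so averaged
    methylated and unmethylated signal profiles differ visibly — the
    behaviour observed on the emulated platform — while individual contexts
    still scatter.  ``meth_shift_mean = meth_shift_sd = 0`` yields a model
    in which methylation is invisible; ``meth_shift_pos_frac=0.5`` gives
    fully balanced signs.
    """
    rng = np.random.default_rng(seed)
    # per-position, per-base contributions; center position dominates
    pos_weight = np.array([0.5, 0.8, 1.6, 0.8, 0.5])[:k] if k == 5 else np.ones(k)
    contrib = rng.normal(0.0, 1.0, size=(k, 4))
    contrib -= contrib.mean(axis=1, keepdims=True)
    contrib /= contrib.std(axis=1, keepdims=True)
    contrib *= pos_weight[:, None]

    kmers = ["".join(t) for t in product(CANONICAL_BASES, repeat=k)]
    codes = np.array(
        [[BASE_TO_INT[b] for b in kmer] for kmer in kmers], dtype=np.intp
    )
    raw = contrib[np.arange(k)[None, :], codes].sum(axis=1)
    raw = raw + rng.normal(0.0, 0.15 * raw.std(), size=raw.size)  # k-mer jitter
    lo, hi = raw.min(), raw.max()
    # map into [103, 197]: strictly inside the band even after jitter
    means = 103.0 + (raw - lo) / (hi - lo) * 94.0
    sds = rng.uniform(1.5, 3.5, size=len(kmers))

    levels = {kmer: (float(m), float(s)) for kmer, m, s in zip(kmers, means, sds)}

    meth_shift: dict[str, float] = {}
    for t in product(EXTENDED_BASES, repeat=k):
        kmer = "".join(t)
        if METH_BASE not in kmer:
            continue
        magnitude = rng.normal(meth_shift_mean, meth_shift_sd)
        sign = 1.0 if rng.random() < meth_shift_pos_frac else -1.0
        meth_shift[kmer] = float(sign * magnitude)

    return PoreModel(k=k, levels=levels, meth_shift=meth_shift)
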