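"""Evaluation computations: CIGAR-derived alignment identity and error
breakdown, ROC/PR and precision/recall/F1, per-site methylation frequency
aggregation, Pearson correlation against BS-seq tables, depth-subsampled
correlation curves, and error-stratified methylation accuracy.

Identity here uses every alignment column in the denominator (M/=/X plus I
and D), i.e. gap-compressed identity is NOT used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class AlnStats:
    identity: float
    error_rate: float
    mismatch_rate: float
    insertion_rate: float
    deletion_rate: float

    @property
    def columns(self) -> int:
        return self._columns

    def __post_init__(self):
        self._columns = 0


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{o}" for n, o in ops) != cigar:
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(int(n), o) for n, o in ops]


def aln_stats(cigar: str, nm: int | None = None) -> AlnStats:
    """Identity and error breakdown from a CIGAR string and the NM tag.

    Alignment columns = sum of M/=/X/I/D lengths.  With explicit =/X ops the
    mismatch count is the X total; otherwise it is NM minus inserted and
    deleted bases (NM = mismatches + I + D bases).  Identity is the fraction
    of columns that are matches.
    """
    ops = parse_cigar(cigar)
    counts = {o: 0 for o in "MIDNSHP=X"}
    for n, o in ops:
        counts[o] += n
    columns = counts["M"] + counts["="] + counts["X"] + counts["I"] + counts["D"]
    if columns == 0:
        raise ValueError("alignment has no columns")
    ins, dele = counts["I"], counts["D"]
    if counts["="] or counts["X"]:
        mismatch = counts["X"]
    else:
        if nm is None:
            raise ValueError("NM tag required for M-only CIGAR")
        if nm < ins + dele:
            raise ValueError("malformed: NM smaller than indel bases")
        mismatch = nm - ins - dele
        if mismatch > counts["M"]:
            raise ValueError("malformed: more mismatches than aligned bases")
    errors = mismatch + ins + dele
    stats = AlnStats(
        identity=(columns - errors) / columns,
        error_rate=errors / columns,
        mismatch_rate=mismatch / columns,
        insertion_rate=ins / columns,
        deletion_rate=dele / columns,
    )
    stats._columns = columns
    return stats


def aln_stats_from_sam(path) -> pd.DataFrame:
    """Per-alignment stats from a SAM/BAM file (primary alignments only)."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            st = aln_stats(aln.cigarstring, nm)
            rows.append((aln.query_name, st.identity, st.error_rate,
                         st.mismatch_rate, st.insertion_rate, st.deletion_rate))
    return pd.DataFrame(rows, columns=[
        "read_id", "identity", "error_rate", "mismatch_rate",
        "insertion_rate", "deletion_rate"])


def identity_to_truth(called: str, truth: str) -> AlnStats:
    """Global-alignment identity of a called sequence against its known true
    sequence (edlib Needleman-Wunsch path)."""
    import edlib

    if not called:
        st = AlnStats(0.0, 1.0, 0.0, 0.0, 1.0)
        st._columns = len(truth)
        return st
    res = edlib.align(called, truth, mode="NW", task="path")
    return aln_stats(res["cigar"], nm=res["editDistance"])


# ------------------------------------------------------------ classifiers
def roc_pr(labels, scores):
    """(auc_roc, auc_pr, curves) by threshold sweep.

    ROC AUC uses the trapezoidal rule (equivalently the midrank
    Mann-Whitney statistic under ties); PR AUC is the interpolation-free
    step-function area as returned by average precision.
    """
    from sklearn import metrics as skm

    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC/PR")
    fpr, tpr, roc_thr = skm.roc_curve(labels, scores)
    auc_roc = float(skm.auc(fpr, tpr))
    precision, recall, pr_thr = skm.precision_recall_curve(labels, scores)
    auc_pr = float(skm.average_precision_score(labels, scores))
    curves = {
        "fpr": fpr, "tpr": tpr, "roc_thresholds": roc_thr,
        "precision": precision, "recall": recall, "pr_thresholds": pr_thr,
    }
    return auc_roc, auc_pr, curves


def prf1(labels, predicted) -> tuple[float, float, float]:
    """Precision, recall and F1 for binary 0/1 arrays."""
    labels = np.asarray(labels)
    predicted = np.asarray(predicted)
    tp = int(np.sum((labels == 1) & (predicted == 1)))
    fp = int(np.sum((labels == 0) & (predicted == 1)))
    fn = int(np.sum((labels == 1) & (predicted == 0)))
    if tp + fp == 0:
        raise ValueError("no predicted positives: precision undefined")
    precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


# ------------------------------------------------------------- aggregation
def aggregate_sites(calls, p_threshold: float = 0.5,
                    min_coverage: int = 1) -> pd.DataFrame:
    """Per-genome-site methylation frequency from per-read calls.

    Calls must carry reference coordinates (ref, ref_pos).  frequency =
    #(p_m > p_threshold) / coverage; sites with coverage < min_coverage are
    dropped.  Returns a DataFrame (ref, pos, strand, coverage, frequency).
    """
    rows = [
        (c.ref, c.ref_pos, int(c.p_m > p_threshold))
        for c in calls
        if c.ref is not None and c.ref_pos is not None
    ]
    if not rows:
        return pd.DataFrame(
            columns=["ref", "pos", "strand", "coverage", "frequency"]
        )
    df = pd.DataFrame(rows, columns=["ref", "pos", "meth"])
    agg = (
        df.groupby(["ref", "pos"], sort=True)["meth"]
        .agg(coverage="size", n_meth="sum")
        .reset_index()
    )
    agg = agg[agg["coverage"] >= min_coverage]
    agg["strand"] = "+"
    agg["frequency"] = agg["n_meth"] / agg["coverage"]
    return agg[["ref", "pos", "strand", "coverage", "frequency"]].reset_index(
        drop=True
    )


def pearson(x, y):
    """Sample Pearson correlation rho = Cov(X,Y) / (sd_X sd_Y), n-1
    denominators throughout.  Returns a CorrelationResult."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("need two vectors of equal length >= 2")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input")
    cov = float(np.sum((x - x.mean()) * (y - y.mean())) / (x.size - 1))
    return CorrelationResult(rho=cov / (sx * sy), n_sites=int(x.size))


@dataclass
class CorrelationResult:
    rho: float
    n_sites: int


def correlate_with_bs(site_freq: pd.DataFrame,
                      bs_table: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation of per-site frequencies on the shared sites."""
    merged = site_freq.merge(bs_table, on=["ref", "pos"],
                             suffixes=("_call", "_bs"))
    return pearson(merged["frequency_call"], merged["frequency_bs"])


def depth_correlation_curve(calls, bs_table: pd.DataFrame, depths,
                            seed: int = 0, p_threshold: float = 0.5):
    """Correlation vs BS-seq after subsampling per-site coverage.

    For each target depth d, at most d calls per site are kept (seeded
    uniform subsample without replacement), frequencies re-aggregated, and
    the Pearson correlation recomputed on shared sites.  Returns
    {depth: rho}.
    """
    rng = np.random.default_rng(seed)
    by_site: dict[tuple, list] = {}
    for c in calls:
        if c.ref is None or c.ref_pos is None:
            continue
        by_site.setdefault((c.ref, c.ref_pos), []).append(c)

    out = {}
    for d in depths:
        sub = []
        for site in sorted(by_site):
            group = by_site[site]
            if len(group) > d:
                idx = rng.choice(len(group), size=d, replace=False)
                sub.extend(group[i] for i in idx)
            else:
                sub.extend(group)
        freq = aggregate_sites(sub, p_threshold=p_threshold)
        out[d] = correlate_with_bs(freq, bs_table).rho
    return out


DEFAULT_ERROR_BINS = (0.0, 0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 1.0)


def error_stratified_accuracy(calls_with_truth, read_error_rates: dict,
                              bin_edges=DEFAULT_ERROR_BINS) -> dict:
    """Binary-call accuracy stratified by per-read basecall error rate.

    ``calls_with_truth``: iterable of (MethCall, truth_label).  Reads are
    binned by error rate into left-closed right-open bins; empty bins are
    absent from the result (not zero).  Returns {(lo, hi): accuracy}.
    """
    edges = np.asarray(bin_edges, dtype=float)
    correct = np.zeros(len(edges) - 1)
    total = np.zeros(len(edges) - 1)
    for call, truth in calls_with_truth:
        err = read_error_rates[call.read_id]
        k = int(np.searchsorted(edges, err, side="right")) - 1
        if k < 0 or k >= len(edges) - 1:
            continue
        total[k] += 1
        correct[k] += int(call.label == int(truth))
    return {
        (float(edges[k]), float(edges[k + 1])): correct[k] / total[k]
        for k in range(len(edges) - 1)
        if total[k] > 0
    }
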