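"""On-disk formats: signal archives (HDF5 + TSV dialect), truth tables,
BS-seq-style frequency tables, and FASTA references."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .sim import RawRead, TruthRecord

TRUTH_COLUMNS = [
    "read_id",
    "ref",
    "start",
    "strand",
    "sequence",
    "meth_positions",
    "meth_labels",
    "signal_start",
    "dwells",
]


# ---------------------------------------------------------------- signals
def write_signal_archive(reads: list[RawRead], path, dialect: str = "hdf5") -> None:
    """One trace per read.  HDF5: one group per read with attributes
    (read_id, sampling_rate_hz, offset_pA=0, scale=1) and a float32 dataset
    "signal".  The TSV dialect (read_id, sampling_rate_hz, comma-joined
    samples at 4 decimals) exists for tiny plain-text fixtures."""
    if dialect == "hdf5":
        import h5py

        with h5py.File(path, "w", track_order=True) as fh:
            for read in reads:
                grp = fh.create_group(read.read_id)
                grp.attrs["read_id"] = read.read_id
                grp.attrs["sampling_rate_hz"] = float(read.sampling_rate_hz)
                grp.attrs["offset_pA"] = 0.0
                grp.attrs["scale"] = 1.0
                grp.create_dataset(
                    "signal",
                    data=np.asarray(read.signal, dtype=np.float32),
                    track_times=False,
                )
    elif dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("read_id\tsampling_rate_hz\tsamples\n")
            for read in reads:
                samples = ",".join(f"{x:.4f}" for x in read.signal)
                fh.write(f"{read.read_id}\t{read.sampling_rate_hz:g}\t{samples}\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_signal_archive(path, dialect: str = "hdf5") -> list[RawRead]:
    reads: list[RawRead] = []
    if dialect == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            for name in fh:
                grp = fh[name]
                reads.append(
                    RawRead(
                        read_id=str(grp.attrs["read_id"]),
                        signal=np.asarray(grp["signal"], dtype=np.float32),
                        sampling_rate_hz=float(grp.attrs["sampling_rate_hz"]),
                    )
                )
    elif dialect == "tsv":
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("read_id")
            for line in fh:
                rid, rate, samples = line.rstrip("\n").split("\t")
                sig = np.array(samples.split(","), dtype=np.float32)
                reads.append(RawRead(rid, sig, float(rate)))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return reads


# ---------------------------------------------------------------- truth
def write_truth_table(truths: list[TruthRecord], path) -> None:
    """TSV with base spans run-length encoded as (first-base start, dwells)."""
    with open(path, "w") as fh:
        fh.write("\t".join(TRUTH_COLUMNS) + "\n")
        for t in truths:
            dwells = t.base_spans[:, 1] - t.base_spans[:, 0]
            fh.write(
                "\t".join(
                    [
                        t.read_id,
                        t.reference_name or ".",
                        str(t.reference_start),
                        t.strand,
                        t.sequence,
                        ",".join(map(str, t.meth_positions.tolist())) or ".",
                        ",".join(map(str, t.meth_labels.tolist())) or ".",
                        str(int(t.base_spans[0, 0])) if len(t.base_spans) else "0",
                        ",".join(map(str, dwells.tolist())),
                    ]
                )
                + "\n"
            )


def read_truth_table(path) -> list[TruthRecord]:
    truths = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        assert header == TRUTH_COLUMNS, f"unexpected truth table header: {header}"
        for line in fh:
            rid, ref, start, strand, seq, mpos, mlab, sig0, dwells = line.rstrip(
                "\n"
            ).split("\t")
            d = np.array(dwells.split(","), dtype=np.int64)
            ends = int(sig0) + np.cumsum(d)
            spans = np.stack([ends - d, ends], axis=1)
            truths.append(
                TruthRecord(
                    read_id=rid,
                    reference_name="" if ref == "." else ref,
                    reference_start=int(start),
                    strand=strand,
                    sequence=seq,
                    meth_positions=(
                        np.array([], dtype=np.int64)
                        if mpos == "."
                        else np.array(mpos.split(","), dtype=np.int64)
                    ),
                    meth_labels=(
                        np.array([], dtype=np.int8)
                        if mlab == "."
                        else np.array(mlab.split(","), dtype=np.int64).astype(np.int8)
                    ),
                    base_spans=spans,
                )
            )
    return truths


# ---------------------------------------------------------------- tables
def write_bs_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bs_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- fasta
def write_fasta(reference: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
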