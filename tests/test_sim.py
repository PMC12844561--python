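import numpy as np
import pytest

import porecall as pc
from porecall.sim import cpg_positions


def test_signal_length_is_open_pore_plus_dwells(pore_model, sim_params):
    raw, truth = pc.simulate_read("ACGTACGTAC", None, pore_model, sim_params)
    dwells = truth.base_spans[:, 1] - truth.base_spans[:, 0]
    open_len = truth.base_spans[0, 0]
    assert len(raw.signal) == open_len + dwells.sum()
    # spans contiguous, ordered, non-overlapping
    assert (truth.base_spans[1:, 0] == truth.base_spans[:-1, 1]).all()
    assert (dwells >= 1).all()


def test_noise_free_fixed_dwell_reproduces_pore_levels_exactly(pore_model):
    params = pc.SimParams(seed=0, noise_sd_pA=0.0, dwell_dispersion=0.0,
                          open_pore_len=100)
    seq = "ACGTTGCACGTTA"
    raw, truth = pc.simulate_read(seq, None, pore_model, params)
    padded = "AA" + seq + "AA"
    for i, (s, e) in enumerate(truth.base_spans):
        level = pore_model.mean_level(padded[i : i + 5])
        seg = raw.signal[s:e].astype(np.float64)
        assert seg == pytest.approx(level, abs=1e-4)  # float32 storage
        assert e - s == 10  # fixed dwell at 4000 Hz / 400 bp/s


def test_mean_dwell_matches_sampling_over_speed(pore_model):
    params = pc.SimParams(seed=5)
    seq = "".join(np.random.default_rng(1).choice(list("ACGT"), size=10000))
    raw, truth = pc.simulate_read(seq, None, pore_model, params)
    dwells = truth.base_spans[:, 1] - truth.base_spans[:, 0]
    assert dwells.mean() == pytest.approx(10.0, rel=0.05)


def test_methylation_shifts_signal_only_near_the_cpg(pore_model):
    params = pc.SimParams(seed=9, open_pore_len=50)
    seq = "AATTACGTTAATTTAACCGGA"
    cpgs = cpg_positions(seq)
    assert len(cpgs) == 2
    target = int(cpgs[0])
    raw0, truth0 = pc.simulate_read(seq, {target: 0}, pore_model, params)
    raw1, truth1 = pc.simulate_read(seq, {target: 1}, pore_model, params)
    assert len(raw0.signal) == len(raw1.signal)
    diff = np.flatnonzero(raw0.signal != raw1.signal)
    # k-mers centered within +-2 of the C overlap it: spans of those bases
    lo = truth0.base_spans[max(target - 2, 0), 0]
    hi = truth0.base_spans[min(target + 2, len(seq) - 1), 1]
    assert len(diff) > 0
    assert diff.min() >= lo and diff.max() < hi


def test_signal_band_fraction_outside_is_tiny(pore_model, sim_params):
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=5000))
    raw, truth = pc.simulate_read(seq, None, pore_model, sim_params)
    dna = raw.signal[truth.base_spans[0, 0]:]
    sd = sim_params.noise_sd_pA
    outside = ((dna < 100 - 4 * sd) | (dna > 200 + 4 * sd)).mean()
    assert outside < 1e-3


def test_non_acgt_sequence_rejected(pore_model, sim_params):
    with pytest.raises(ValueError):
        pc.simulate_read("ACGTN", None, pore_model, sim_params)


def test_reverse_strand_equals_revcomp_forward(pore_model):
    """Simulating a minus-strand read is by construction simulating the
    reverse complement forward: verify on the run level that minus reads'
    sequences are revcomp of their reference window."""
    ref = pc.random_reference(3000, seed=8)
    params = pc.SimParams(seed=13)
    reads, truths = pc.simulate_run(ref, 20, pc.build_default_pore_model(2),
                                    params, read_len_range=(200, 400))
    seen_minus = 0
    for t in truths:
        window = ref["ref"][t.reference_start:
                            t.reference_start + len(t.sequence)]
        if t.strand == "-":
            seen_minus += 1
            assert t.sequence == pc.revcomp(window)
        else:
            assert t.sequence == window
    assert seen_minus > 0


def test_run_fully_methylated_and_unmethylated_extremes(pore_model, sim_params):
    ref = pc.random_reference(2000, seed=21)
    for p, expected in ((1.0, 1), (0.0, 0)):
        _, truths = pc.simulate_run(ref, 10, pore_model, sim_params,
                                    read_len_range=(300, 500),
                                    per_site_meth_prob=p)
        labels = np.concatenate([t.meth_labels for t in truths])
        assert len(labels) > 0
        assert (labels == expected).all()


def test_run_deterministic_and_archive_byte_identical(pore_model, sim_params,
                                                      tmp_path):
    from porecall.archive import write_signal_archive

    ref = pc.random_reference(2000, seed=22)
    out = []
    for rep in range(2):
        reads, truths = pc.simulate_run(ref, 5, pore_model, sim_params,
                                        read_len_range=(200, 300),
                                        per_site_meth_prob=0.5)
        path = tmp_path / f"run{rep}.h5"
        write_signal_archive(reads, path)
        tsv = tmp_path / f"run{rep}.tsv"
        write_signal_archive(reads, tsv, dialect="tsv")
        out.append((path.read_bytes(), tsv.read_bytes(),
                    [t.sequence for t in truths]))
    assert out[0][0] == out[1][0]  # HDF5 byte-identical
    assert out[0][1] == out[1][1]  # TSV byte-identical
    assert out[0][2] == out[1][2]


def test_minus_strand_cpg_maps_to_forward_site():
    ref = {"r": "TTACGTT"}  # CG at forward positions (3,4)
    params = pc.SimParams(seed=1)
    pm = pc.build_default_pore_model(3)
    # force reads until both strands observed
    reads, truths = pc.simulate_run(ref, 30, pm, params,
                                    read_len_range=(7, 7),
                                    per_site_meth_prob=0.0)
    for t in truths:
        assert list(t.meth_positions) == [3 if t.strand == "+" else 2]
        assert t.ref_site(int(t.meth_positions[0])) == 3


def test_bs_table_extremes_and_concentration():
    probs = {"ref": {10: 1.0, 20: 0.0, 30: 0.5}}
    df = pc.simulate_bs_table(probs, depth=1, seed=0)
    assert set(df["frequency"]) <= {0.0, 1.0}
    df = pc.simulate_bs_table(probs, depth=100000, seed=1)
    row = df[df.pos == 30].iloc[0]
    assert row.frequency == pytest.approx(0.5, abs=0.01)
    assert (df[df.pos == 10].frequency == 1.0).all()
    with pytest.raises(ValueError):
        pc.simulate_bs_table(probs, depth=0, seed=0)
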