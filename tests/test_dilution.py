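"""In-silico dilution: foreground extraction, injection conservation, labelling."""

import numpy as np
import pytest

import toffee as tf
from toffee._errors import WindowResolutionError
from toffee.dilution import (
    ConfusionCounts,
    GroundTruthEntry,
    extract_foreground,
    inject,
    label_detections,
)
from toffee.ims import round_half_away

from conftest import csr_to_dict


@pytest.fixture(scope="module")
def single_peptide_run():
    """One mono-isotopic peptide, no noise, extraction boxes covering it all."""
    q = tf.PeptideQuery(
        identifier="PEP", precursor_mz=455.0, charge=2,
        fragment_mzs=np.array([310.0, 620.0, 880.0]),
        expected_rt=70.0, rt_half_width=40.0, mz_half_width_ppm=300.0,
    )
    pept = tf.SyntheticPeptide(query=q, apex_intensity=800.0, sigma_t=0.02,
                               sigma_m=2.0, envelope=(1.0,))
    spec = tf.SyntheticSpec(seed=21, n_cycles=50, noise_rate=0.0, peptides=[pept])
    run, truth = tf.generate_run(spec)
    return spec, run, truth, q


def test_foreground_captures_exactly_the_peptide(single_peptide_run):
    _, run, truth, q = single_peptide_run
    region = extract_foreground(run, q)
    assert region.total_intensity() == truth.peptides.total_intensity.iloc[0]
    assert region.total_intensity() == run.total_intensity()


def test_foreground_apex_near_true_rt(single_peptide_run):
    _, run, _, q = single_peptide_run
    region = extract_foreground(run, q)
    cycle = run.ms1.header.scanCycleTime
    assert abs(region.apex_rt - q.expected_rt) <= cycle


def test_foreground_narrow_rt_limits_to_apex(single_peptide_run):
    spec, run, _, q = single_peptide_run
    narrow = tf.PeptideQuery(
        identifier=q.identifier, precursor_mz=q.precursor_mz, charge=q.charge,
        fragment_mzs=q.fragment_mzs, expected_rt=q.expected_rt,
        rt_half_width=0.4 * spec.cycle_time, mz_half_width_ppm=q.mz_half_width_ppm,
    )
    region = extract_foreground(run, narrow)
    assert {t.scan_offset for t in region.triplets} == {0}


def test_precursor_outside_windows_errors(single_peptide_run):
    _, run, _, q = single_peptide_run
    outside = tf.PeptideQuery("X", 850.0, 2, np.array([300.0]), 70.0)
    with pytest.raises(WindowResolutionError):
        extract_foreground(run, outside)


def test_inject_factor_zero_is_identity(single_peptide_run, small_run):
    _, run, _, q = single_peptide_run
    _, bg, _ = small_run
    region = extract_foreground(run, q)
    out = inject(bg, region, 0.0, target_rt=60.0)
    assert out.equals(bg, rtol=0.0)


def test_inject_into_empty_background_conserves_total(single_peptide_run):
    _, run, _, q = single_peptide_run
    region = extract_foreground(run, q)
    bg, _ = tf.generate_run(tf.SyntheticSpec(seed=5, n_cycles=50, noise_rate=0.0))
    for factor in (1.0, 0.5, 0.3):
        out = inject(bg, region, factor, target_rt=80.0)
        expected = sum(
            int(round_half_away(factor * t.intensity)) for t in region.triplets
        )
        assert out.total_intensity() == expected


def test_inject_conserves_total_on_noisy_background(single_peptide_run, small_run):
    _, run, _, q = single_peptide_run
    _, bg, _ = small_run
    region = extract_foreground(run, q)
    out = inject(bg, region, 0.5, target_rt=60.0)
    scaled = sum(int(round_half_away(0.5 * t.intensity)) for t in region.triplets)
    assert out.total_intensity() == bg.total_intensity() + scaled


def test_double_injection_doubles_cells(single_peptide_run):
    _, run, _, q = single_peptide_run
    region = extract_foreground(run, q)
    bg, _ = tf.generate_run(tf.SyntheticSpec(seed=5, n_cycles=50, noise_rate=0.0))
    once = inject(bg, region, 1.0, target_rt=80.0)
    twice = inject(once, region, 1.0, target_rt=80.0)
    for w1, w2 in zip(once.windows, twice.windows):
        d1, d2 = csr_to_dict(w1.csr), csr_to_dict(w2.csr)
        assert set(d1) == set(d2)
        assert all(d2[k] == 2 * d1[k] for k in d1)


def test_untouched_cells_identical(single_peptide_run, small_run):
    _, run, _, q = single_peptide_run
    _, bg, _ = small_run
    region = extract_foreground(run, q)
    out = inject(bg, region, 1.0, target_rt=60.0)
    touched_windows = {"ms1", out.ms2_window_for(q.precursor_mz).name}
    for wb, wo in zip(bg.windows, out.windows):
        if wb.name not in touched_windows:
            assert wb.csr == wo.csr
        else:
            db, do = csr_to_dict(wb.csr), csr_to_dict(wo.csr)
            same = {k for k in db if k in do and do[k] == db[k]}
            # everything not hit by the foreground is unchanged
            assert all(k in do and do[k] >= db[k] for k in db)
            assert len(same) >= len(db) - len(region.triplets)


def test_apex_xic_linear_in_dilution_factor(single_peptide_run):
    _, run, _, q = single_peptide_run
    region = extract_foreground(run, q)
    bg, _ = tf.generate_run(tf.SyntheticSpec(seed=5, n_cycles=50, noise_rate=0.0))

    def apex(r):
        ms2 = r.ms2_window_for(q.precursor_mz)
        tot = np.zeros(ms2.n_scans, dtype=np.int64)
        for f in q.fragment_mzs:
            tot += tf.extract_xic(ms2, *q.mz_band(float(f))).intensity
        return int(tot.max())

    factors = [1.0, 0.5, 0.25, 0.125]
    apexes = [apex(inject(bg, region, f, 80.0)) for f in factors]
    base = apexes[0]
    min_count = 1.0  # integerisation quantum
    for f, a in zip(factors, apexes):
        rel_dev = abs(a - f * base) / (f * base)
        n_cells = len(region.triplets)
        assert rel_dev <= n_cells * min_count / (f * base)


@pytest.mark.parametrize(
    "det_rt, expected",
    [(75.0, (1, 0, 0)), (100.0, (0, 1, 1))],
)
def test_label_detection_threshold(single_peptide_run, det_rt, expected):
    _, _, _, q = single_peptide_run
    truth = [GroundTruthEntry(q, 70.0, 1.0)]
    counts = label_detections([(q.identifier, det_rt)], truth, rt_threshold=10.0)
    assert (counts.tp, counts.fp, counts.fn) == expected


def test_label_random_sets_match_all_pairs_oracle():
    rng = np.random.default_rng(6)
    queries = [
        tf.PeptideQuery(f"P{k}", 450.0 + k, 2, np.array([300.0]), 60.0)
        for k in range(8)
    ]
    for _ in range(20):
        truth = [
            GroundTruthEntry(q, float(rng.uniform(0, 300)), 1.0)
            for q in queries
            if rng.random() < 0.8
        ]
        ids = [t.peptide.identifier for t in truth]
        dets = [
            (ids[int(rng.integers(len(ids)))], float(rng.uniform(0, 300)))
            for _ in range(int(rng.integers(0, 15)))
            if ids
        ]
        got = label_detections(dets, truth, rt_threshold=20.0)

        # independent greedy oracle over explicit all-pairs distances
        used = set()
        tp = 0
        for t in truth:
            pairs = [
                (abs(d_rt - t.injected_rt), k)
                for k, (pid, d_rt) in enumerate(dets)
                if pid == t.peptide.identifier and k not in used
                and abs(d_rt - t.injected_rt) <= 20.0
            ]
            if pairs:
                used.add(min(pairs)[1])
                tp += 1
        assert (got.tp, got.fp, got.fn) == (tp, len(dets) - tp, len(truth) - tp)
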