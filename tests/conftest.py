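import numpy as np
import pytest

import toffee as tf


@pytest.fixture(scope="session")
def small_run():
    """A small noisy 3-window acquisition with 3 peptides."""
    spec = tf.default_spec(seed=11, n_cycles=40, n_peptides=3)
    run, truth = tf.generate_run(spec)
    return spec, run, truth


@pytest.fixture(scope="session")
def clean_run():
    """The same acquisition without background noise (exact peptide signal only)."""
    spec = tf.default_spec(seed=11, n_cycles=40, n_peptides=3, noise_rate=0.0)
    run, truth = tf.generate_run(spec)
    return spec, run, truth


def csr_to_dict(csr):
    """Brute-force oracle view of a CSR map: {(scan, coord): intensity}."""
    out = {}
    for si in range(csr.n_scans):
        coords, inten = tf.slice_scan(csr, si)
        for c, v in zip(coords, inten):
            out[(si, int(c))] = int(v)
    return out


def window_mz_of_scan(window, scan_index):
    h = window.header
    coords, inten = tf.slice_scan(window.csr, scan_index)
    mz = np.square(
        h.alphaPerScan[scan_index] * (coords.astype(np.float64) + h.gamma)
        + h.betaPerScan[scan_index]
    )
    return mz, inten
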