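import numpy as np
import pytest

import ankledyn as ad
from ankledyn import validation as vl


@pytest.fixture(scope="session")
def default_coeffs():
    """The standard ENF-rejecting design at the nominal sampling rate."""
    return ad.design_cheby2()


@pytest.fixture(scope="session")
def clean_measurement():
    """One clean synthetic measurement (recording + ground truth)."""
    return ad.generate_measurement(ad.SynthParams(rng_seed=7))


@pytest.fixture(scope="session")
def plantar_key():
    return ad.parse_folder_name("20210909-0001 Sub 01,LFT,+5,PFlex")


def run_chain(rec, coeffs, key, cfg=None):
    """Filter -> offset -> direction -> segment -> features -> validate,
    converting upstream failures into validation codes like the batch
    driver does."""
    filt = ad.apply_lowpass(rec, coeffs)
    pre = {}
    off = feats = stab = None
    try:
        off = ad.estimate_offset(filt, window=ad.default_window())
    except ad.errors.EmptyWindow as exc:
        pre[vl.OFFSET_UNDETECTABLE] = str(exc)
    if off is not None:
        try:
            direction = ad.detect_direction(filt, off)
        except ad.errors.IndeterminateDirection as exc:
            pre[vl.TECHNICAL_SIGNAL_FAULT] = str(exc)
            direction = None
        if direction is not None:
            segs = ad.segment_contractions(filt, off, direction)
            feats = ad.extract_mvic(filt, off, direction, segs)
            base = ad.baseline_intervals(filt, segs)
            try:
                stab = ad.offset_stability(filt, off, base)
            except ad.errors.NoBaselineSegments:
                pass
    report = ad.validate(filt, key, feats, stab,
                         cfg or vl.ValidationConfig(), precomputed_codes=pre)
    return filt, off, feats, stab, report


@pytest.fixture(scope="session")
def chain():
    return run_chain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
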