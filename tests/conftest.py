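import numpy as np
import pytest

from vorlab import synth


@pytest.fixture(scope="session")
def vor_spec() -> synth.ProtocolSpec:
    return synth.ProtocolSpec.vor("vor_increase")


@pytest.fixture(scope="session")
def clean_test(vor_spec):
    """Noise- and saccade-free gain-0.8 test recording."""
    truth = synth.GroundTruth(gain=0.8)
    return synth.synthesize_test(vor_spec, truth, rng=0)


def interval_oracle_excluded_fraction(event_spans_s, n, fs, margin_s=0.050,
                                      min_segment_s=0.010):
    """Independent interval-arithmetic oracle for the exclusion bookkeeping.

    ``event_spans_s``: list of (start_s, stop_s) spans whose residual exceeds
    the threshold.  Each span is widened by the margin, overlapping windows
    are merged, and retained gaps shorter than the minimum segment are added;
    the result is the excluded fraction on the n-sample grid at ``fs``.
    """
    widened = sorted((s - margin_s, e + margin_s) for s, e in event_spans_s)
    merged = []
    for s, e in widened:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    t = np.arange(n) / fs
    excluded = np.zeros(n, dtype=bool)
    for s, e in merged:
        excluded |= (t >= s - 1e-12) & (t < e - 1e-12)
    # retained gaps shorter than the minimum segment
    bounds = [(-np.inf, 0.0)] + [(s, e) for s, e in merged] + [(t[-1] + 1 / fs, np.inf)]
    for (_, gap_start), (gap_end, _) in zip(bounds[:-1], bounds[1:]):
        sel = (t >= gap_start - 1e-12) & (t < gap_end - 1e-12) & ~excluded
        if 0 < sel.sum() < round(min_segment_s * fs):
            excluded |= sel
    return float(excluded.mean())
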