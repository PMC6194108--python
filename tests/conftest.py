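"""Shared fixtures: fast protocols and cohort builders.

Recordings for cohort-level tests are generated at reduced sampling rates
(hundreds of Hz instead of the 10-kHz hardware rate); all detection
operations work on times, not sample indices, so this changes only the
quantization of detected times.
"""

from __future__ import annotations

import numpy as np
import pytest

from astrobarrage import (
    GeneratorSpec,
    RecordingBundle,
    analyze_recording,
    generate_recording,
    make_protocol,
)


def build_cohort(
    n: int,
    seed: int,
    sampling_rate: float = 500.0,
    **spec_kwargs,
) -> list[RecordingBundle]:
    spec = GeneratorSpec(**spec_kwargs)
    t0 = 120.0 if spec.include_calcium else 30.0
    ss = np.random.SeedSequence(seed)
    bundles = []
    for child in ss.spawn(n):
        protocol = make_protocol(sampling_rate=sampling_rate, t0=t0)
        bundles.append(
            generate_recording(spec, protocol, seed=int(child.generate_state(1)[0] % 2**31))
        )
    return bundles


def analyzed_cohort(n: int, seed: int, sampling_rate: float = 500.0, **spec_kwargs):
    bundles = build_cohort(n, seed, sampling_rate, **spec_kwargs)
    return [(b, analyze_recording(b)) for b in bundles]


@pytest.fixture(scope="session")
def strong_cohort_small():
    """Ten strong-condition bundles with analysis, reused across tests.

    1 kHz sampling so threshold-based spike detection resolves the 3-ms
    minimum inter-spike interval exactly.
    """
    return analyzed_cohort(10, seed=424242, sampling_rate=1000.0)


@pytest.fixture(scope="session")
def noiseless_strong_bundle():
    """One deterministic noiseless strong recording with a guaranteed event."""
    protocol = make_protocol(sampling_rate=1000.0)
    spec = GeneratorSpec(
        vm_noise_sd=0.0,
        dff_noise_sd=0.0,
        astro_event_probability=1.0,
        include_calcium=True,
    )
    protocol = make_protocol(sampling_rate=1000.0, t0=120.0)
    return generate_recording(spec, protocol, seed=7)
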