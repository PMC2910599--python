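import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lineamp.acgh import SampleProfile

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_profile(values, sample_id="S1", spacing=80_000, chrom="chr1",
                 missing=None, replicate_sd=None, snr=None, replicates=None):
    """Build a SampleProfile on a uniform clone grid from a 1-D log2 vector."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    start = np.arange(n) * spacing
    if missing is None:
        missing = np.zeros(n, dtype=bool)
    return SampleProfile(
        sample_id=sample_id,
        clone_ids=np.array([f"C{i:03d}" for i in range(n)]),
        chrom=np.full(n, chrom),
        start=start, end=start + spacing,
        log2=np.where(missing, np.nan, values),
        missing=np.asarray(missing, dtype=bool),
        replicates=replicates,
        replicate_sd=(np.asarray(replicate_sd, dtype=float)
                      if replicate_sd is not None else np.full(n, 0.01)),
        snr=(np.asarray(snr, dtype=float) if snr is not None else np.full(n, 20.0)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
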