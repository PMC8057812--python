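import numpy as np
import pytest

from nvjquant.synthetic import CellSpec, ImagingConfig, render_cell


@pytest.fixture
def demo_spec():
    """Standard single-cell geometry: 1.05 um nucleus, vacuole apposed from +x."""
    def make(enrichment=15.0, **kw):
        defaults = dict(
            nucleus_center=(6.4, 6.4),
            nucleus_radius=1.05,
            vacuole_center=(9.0, 6.4),
            vacuole_radius=1.5,
            enrichment_factor=enrichment,
        )
        defaults.update(kw)
        return CellSpec(**defaults)
    return make


@pytest.fixture
def noise_free_cfg():
    return ImagingConfig(poisson_noise=False, read_noise_sigma=0.0, psf_sigma=0.1)


@pytest.fixture
def render_noise_free(demo_spec, noise_free_cfg):
    def make(enrichment=15.0, **kw):
        return render_cell(demo_spec(enrichment, **kw), noise_free_cfg)
    return make
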