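import numpy as np
import pytest

import tagsync as ts


@pytest.fixture(scope="session")
def quiet_config():
    """Noise-free default phantom (synchronous, uniform 15% amplitudes)."""
    return ts.PhantomConfig(noise_sd=0.0).validate()


@pytest.fixture(scope="session")
def hypokinetic_config():
    """Noise-free phantom with two hypokinetic sectors."""
    return ts.PhantomConfig(sector_amplitudes=(15, 15, 15, 5, 5, 15), noise_sd=0.0).validate()


@pytest.fixture(scope="session")
def static_config():
    """Zero-motion, noise-free phantom."""
    return ts.PhantomConfig(sector_amplitudes=(0,) * 6, noise_sd=0.0).validate()


def _track_one_slice(cfg):
    series = tuple(ts.render_tagged_series(cfg, 0, e) for e in cfg.tag_directions)
    masks = ts.render_cine_masks(cfg)
    contour = ts.init_midwall_contour(masks.myocardium[0, 0], cfg.pixel_spacing,
                                      frame_times=cfg.frame_times)
    return ts.track_contour(series, contour)


@pytest.fixture(scope="session")
def tracked_uniform(quiet_config):
    """HARP track of slice 0 of the noise-free uniform phantom."""
    return _track_one_slice(quiet_config)


@pytest.fixture(scope="session")
def tracked_hypokinetic(hypokinetic_config):
    return _track_one_slice(hypokinetic_config)


@pytest.fixture(scope="session")
def tracked_static(static_config):
    return _track_one_slice(static_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_field(csh, frame_interval=45.0, avc_frame=None):
    """StrainField from a (slices, sectors, frames) array, frame 0 forced to 0."""
    csh = np.asarray(csh, dtype=float).copy()
    csh[:, :, 0] = 0.0
    n_frames = csh.shape[2]
    if avc_frame is None:
        avc_frame = n_frames - 1
    return ts.StrainField(csh=csh, frame_times=np.arange(n_frames) * frame_interval,
                          avc_frame=avc_frame)


def random_field(rng, n_slices=9, n_sectors=6, n_frames=10, avc_frame=None):
    csh = rng.normal(8.0, 4.0, size=(n_slices, n_sectors, n_frames))
    return make_field(csh, avc_frame=avc_frame)
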