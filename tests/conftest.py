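"""Shared fixtures: small synthetic recordings with known ground truth."""

import numpy as np
import pytest

from larvaquant.synthetic import (Episode, LarvaSimSpec, NeuronSimSpec,
                                  render_campari_image, render_larva_video)


@pytest.fixture(scope="session")
def contracting_larva():
    """150-frame 30 fps recording with one -20% episode from 2 s to 4 s."""
    spec = LarvaSimSpec(n_frames=150, frame_rate=30.0,
                        contraction_schedule=[Episode(2.0, 4.0, -0.20)], seed=7)
    stack, truth = render_larva_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def quiet_larva():
    """Short no-episode recording for baseline/identity checks."""
    spec = LarvaSimSpec(n_frames=60, frame_rate=30.0, seed=3)
    stack, truth = render_larva_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def stationary_larva():
    """Noise-free motionless larva: every frame is bit-identical."""
    spec = LarvaSimSpec(n_frames=40, frame_rate=30.0, crawl_speed=0.0,
                        turn_rate=0.0, bend_amplitude=0.0, noise_sd=0.0, seed=5)
    stack, truth = render_larva_video(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def ring_neuron():
    """Neuron whose red/green ratio is 2 inside radius 10 px and 1 beyond."""

    def red(r):
        return np.where(r <= 10, 200.0, 100.0)

    def green(r):
        return np.full_like(r, 100.0)

    spec = NeuronSimSpec(
        soma_radius=10, red_level_map=red, green_level_map=green,
        dendrite_segments=[((64.0, 64.0), (64.0, 120.0), 4.0),
                           ((64.0, 64.0), (20.0, 30.0), 4.0)],
        noise_sd=0.0, seed=2)
    img, truth = render_campari_image(spec)
    return spec, img, truth
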