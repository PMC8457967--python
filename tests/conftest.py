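import numpy as np
import pytest

from broilervision import ChromaThresholdSegmenter, ScenePalette


def draw_labelled_pixels(palette: ScenePalette, n_per_class: int = 100, seed: int = 0):
    """Labelled RGB pixel samples drawn around the palette base colours."""
    rng = np.random.default_rng(seed)

    def draw(base, n):
        return np.clip(rng.normal(0.0, palette.jitter_sigma, (n, 3)) + base, 0, 255)

    half = n_per_class // 2
    X = np.vstack([
        draw(palette.litter_dark, half),
        draw(palette.litter_light, n_per_class - half),
        draw(palette.plumage_primary, half),
        draw(palette.plumage_secondary, n_per_class - half),
        draw(palette.feeder, half),
        draw(palette.drinker, n_per_class - half),
    ])
    y = np.array(["litter"] * n_per_class + ["body"] * n_per_class
                 + ["feeder"] * n_per_class)
    return X, y


@pytest.fixture(scope="session")
def default_palette():
    return ScenePalette()


@pytest.fixture(scope="session")
def fitted_model(default_palette):
    X, y = draw_labelled_pixels(default_palette, n_per_class=100, seed=0)
    return ChromaThresholdSegmenter().fit(X, y)
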