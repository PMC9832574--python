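import numpy as np
import pytest

from microglia_morph import synthetic as syn


@pytest.fixture(scope="session")
def bench_table():
    """Rendered + measured 7-class morphology benchmark (25 cells/class)."""
    return syn.morphology_feature_table(n_per_class=25, seed=11)


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free field of five well-separated cells with two particles."""
    cells = (
        (syn.archetype("round", seed=1), (70.0, 70.0)),
        (syn.archetype("fried_egg", seed=2), (70.0, 240.0)),
        (syn.archetype("hypertrophic", seed=3), (240.0, 70.0)),
        (syn.archetype("bipolar", seed=4), (240.0, 240.0)),
        (syn.archetype("round", seed=5), (150.0, 155.0)),
    )
    particles = (
        syn.ParticleSpec(radius_um=2.0, engulfed_by=2),
        syn.ParticleSpec(radius_um=2.5, position=(30.0, 160.0)),
    )
    spec = syn.FieldSpec(image_size_px=(320, 320), cells=cells,
                         particles=particles, noise_sd=0.0, seed=9)
    return spec, syn.render_field(spec)
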