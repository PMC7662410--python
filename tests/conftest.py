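import numpy as np
import pytest

from ansrecall import LatentGroundTruth, default_model, generate_indicator_table

DEFAULT_BETAS = {("Sympathetic", "ANS"): 0.6, ("Vagal", "ANS"): -0.5,
                 ("ANS", "Recall"): 0.4}


@pytest.fixture
def model():
    return default_model()


def make_table(betas=None, loadings=1.0, noise_sd=0.0, n=1000, seed=7,
               spec=None, return_latents=False):
    """Indicator table from a latent ground truth with scalar defaults."""
    spec = spec or default_model()
    betas = DEFAULT_BETAS if betas is None else betas
    mvs = spec.all_mvs()
    truth = LatentGroundTruth(
        loadings={mv: loadings for mv in mvs} if np.isscalar(loadings)
        else loadings,
        path_coefficients=betas,
        noise_sd={mv: noise_sd for mv in mvs} if np.isscalar(noise_sd)
        else noise_sd,
        n_subjects=n, seed=seed)
    return generate_indicator_table(truth, spec,
                                    return_latents=return_latents)


@pytest.fixture
def make_table_factory():
    return make_table
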