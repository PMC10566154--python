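import numpy as np
import pytest

from wheatfvc import synth
from wheatfvc.pipeline import PipelineConfig
from wheatfvc.synth import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene():
    """Two small plots split by a 10 m corridor; fast to rasterize."""
    return SceneConfig.grid_layout(
        n_plot_rows=1,
        n_plot_cols=2,
        plot_w=45.0,
        plot_h=50.0,
        path_w=10.0,
        margin=0.0,
        pad_to=10.0,
        stage="jointing",
        uas_gsd=0.2,
        correlation_length_m=10.0,
        seed=7,
    )


def tiny_pipeline_config(seed=0):
    """Scaled-down two-stage pipeline config for smoke/integration tests."""
    scenes = {}
    for i, stage in enumerate(("jointing", "booting")):
        scenes[stage] = SceneConfig.grid_layout(
            n_plot_rows=1,
            n_plot_cols=2,
            plot_w=45.0,
            plot_h=50.0,
            path_w=10.0,
            margin=0.0,
            pad_to=10.0,
            stage=stage,
            uas_gsd=0.2,
            correlation_length_m=12.0,
            edge_taper_m=10.0,
            seed=seed * 1000 + i,
        )
    return PipelineConfig(
        scenes=scenes,
        n_sites=8,
        n_bare_sites=4,
        photo_size=(64, 64),
        rfr_mtry_grid=(1, 2),
        rfr_ntree_grid=(100,),
        cv_folds=5,
        seed=seed,
    )
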