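import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


from neurocult import masking, pipeline, simulate  # noqa: E402


@pytest.fixture(scope="session")
def small_frame_params():
    """A quarter-size field that keeps unit tests fast (~0.2 s/frame)."""
    return simulate.FrameSimParams(
        field_size_mm=0.5, n_cells=30, seed=3, distance_cutoff_um=120.0)


@pytest.fixture(scope="session")
def small_scene(small_frame_params):
    return simulate.generate_frame(small_frame_params)


@pytest.fixture(scope="session")
def small_config(small_frame_params):
    return pipeline.RunConfig(frame=small_frame_params, n_frames=2)


@pytest.fixture(scope="session")
def masking_config(small_frame_params):
    return masking.MaskingConfig(
        pixel_size_um=small_frame_params.pixel_size_um)
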