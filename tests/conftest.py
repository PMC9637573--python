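import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from hemodrop import marangoni, synthetic, thermography
from hemodrop.properties import BloodProperties, LogFitModel


@pytest.fixture(scope="session")
def props() -> BloodProperties:
    return BloodProperties()


@pytest.fixture(scope="session")
def sigma_fit() -> LogFitModel:
    return LogFitModel(a=-11.5, b=88.0)


@pytest.fixture(scope="session")
def record37() -> synthetic.StudyRecord:
    return synthetic.StudyRecord("T37_r00", 37.0, 11.0, 0, 20240901)


@pytest.fixture(scope="session")
def roundtrip37(record37, props):
    """Full noiseless 37 degC round trip: prescribed Ma -> frames -> Ma."""
    cfg = synthetic.default_scenario(37.0)
    t = synthetic.thermal_time_grid(record37, cfg)
    target = synthetic.ma_target_function(cfg)(t)
    R_m = 1e-3 * synthetic.base_diameter_from_volume(record37.V0_ul) / 2.0
    dT = synthetic.invert_marangoni_to_deltaT(
        target, R_m, props, record37.Ts + cfg.T_center_offset_degC)
    frames = synthetic.generate_thermal_frames(record37, dT, t, cfg, noise=0.0)
    ecs = thermography.edge_center_series(frames)
    traj = marangoni.marangoni_series(ecs, R_m, props)
    return {"cfg": cfg, "t": t, "target": target, "R_m": R_m, "dT": dT,
            "frames": frames, "ecs": ecs, "traj": traj}
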