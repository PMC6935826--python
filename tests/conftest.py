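import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spineload as sl
from spineload.skeleton import build_default_model, load_model_config

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_model() -> sl.SpineModel:
    return build_default_model()


@pytest.fixture(scope="session")
def base_config() -> dict:
    """A fresh parse of the packaged model config for mutation in tests."""
    return load_model_config()


def make_custom_model(
    fascicles: list[dict],
    thorax_mass_fraction: float = 0.42,
    thorax_com=(0.0, 0.22, 0.0),
    joint_x: float = 0.0,
    body_mass: float = 70.0,
    lumbar_mass_fraction: float = 1e-13,
) -> sl.SpineModel:
    """Toy-geometry builder: straight vertical chain with joints at
    ``joint_x`` and a caller-chosen fascicle table.  The 17-group census is
    kept by padding unused groups with far-from-sagittal stub fascicles of
    negligible strength (never recruited in sagittal balance)."""
    cfg = load_model_config()
    cfg = dict(cfg)
    cfg["segments"] = [
        {"name": "pelvis", "mass_fraction": 0.142, "com": [0.0, -0.05, 0.0]},
        *[
            {"name": n, "mass_fraction": lumbar_mass_fraction, "com": [0.0, 0.021, 0.0]}
            for n in ("L5", "L4", "L3", "L2", "L1")
        ],
        {"name": "thorax", "mass_fraction": thorax_mass_fraction,
         "com": list(thorax_com)},
    ]
    cfg["joints"] = [
        {"name": "L5S1", "parent": "pelvis", "center": [joint_x, 0.08, 0.0]},
        *[
            {"name": j, "parent": p, "center": [0.0, 0.042, 0.0]}
            for j, p in (
                ("L4L5", "L5"), ("L3L4", "L4"), ("L2L3", "L3"),
                ("L1L2", "L2"), ("T12L1", "L1"),
            )
        ],
    ]
    groups_used = {f["group"] for f in fascicles}
    stubs = []
    for g in cfg["muscle_groups"]:
        if g not in groups_used:
            stubs.append(
                {"name": f"stub_{g}", "group": g,
                 "origin": ["pelvis", 0.0, 0.0, 0.3],
                 "insertion": ["thorax", 0.0, 0.0, 0.3],
                 "strength": 1e-6}
            )
    cfg["fascicles"] = fascicles + stubs
    return build_default_model(cfg, body_mass=body_mass)


@pytest.fixture(scope="session")
def walking_subject() -> sl.SyntheticSubject:
    prof = sl.SubjectProfile(
        "h00", "healthy", 63.5, 1.70, np.array(sl.HEALTHY_RHYTHM), seed=11
    )
    return sl.generate_subject(prof, sl.level_walking())


@pytest.fixture(scope="session")
def ldh_subject() -> sl.SyntheticSubject:
    prof = sl.SubjectProfile(
        "p00", "ldh", 67.4, 1.70, np.array(sl.LDH_RHYTHM), seed=17
    )
    return sl.generate_subject(prof, sl.level_walking())


@pytest.fixture(scope="session")
def ldh_results(ldh_subject) -> sl.SpineLoadingResults:
    model = sl.SpineLoadingModel.from_markers(
        ldh_subject.markers, ldh_subject.events, baseline=ldh_subject.baseline,
        body_mass=ldh_subject.profile.mass, activity="level_walking",
    )
    return model.fit()
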