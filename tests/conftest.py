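import numpy as np
import pytest

import cetcem as c


def rotation_matrix(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def rigidly_moved(specimen, R, t):
    return c.KneeSpecimen(
        id=specimen.id,
        side=specimen.side,
        tibia=specimen.tibia.transformed(R, t),
        meniscus=specimen.meniscus.transformed(R, t),
    )


@pytest.fixture(scope="session")
def uniform_spec():
    """Identical tibial circles (R=25) with a uniform 3 mm meniscal offset."""
    return c.uniform_offset_spec(
        radius=25.0,
        baseline=3.0,
        slice_thickness=1.0,
        meniscus_support_deg=(-85.0, 85.0),
    )


@pytest.fixture(scope="session")
def uniform_phantom(uniform_spec):
    tibia, meniscus, truth = c.make_phantom(uniform_spec)
    return uniform_spec, tibia, meniscus, truth


@pytest.fixture(scope="session")
def uniform_specimen(uniform_phantom):
    _spec, tibia, meniscus, _truth = uniform_phantom
    return c.KneeSpecimen(id="uniform", side="right", tibia=tibia, meniscus=meniscus)


@pytest.fixture(scope="session")
def bump_spec():
    """Posteromedial 5 mm Gaussian bump on a 1.5 mm baseline, noiseless."""
    return c.PhantomSpec.standard(
        slice_thickness=0.5,
        noise_sd=0.0,
        extrusion=c.ExtrusionModel(
            baseline_mm=1.5, peak_amplitude_mm=5.0, peak_angle_deg=32.0, peak_width_deg=40.0
        ),
    )


@pytest.fixture(scope="session")
def bump_phantom(bump_spec):
    tibia, meniscus, truth = c.make_phantom(bump_spec)
    return bump_spec, tibia, meniscus, truth


@pytest.fixture(scope="session")
def bump_specimen(bump_phantom):
    _spec, tibia, meniscus, _truth = bump_phantom
    return c.KneeSpecimen(id="bump", side="right", tibia=tibia, meniscus=meniscus)


@pytest.fixture(scope="session")
def recovery_cohort():
    """The seeded 17-phantom recovery cohort (0.5 mm slices, 0.05 mm noise)."""
    return c.make_cohort(17, seed=1)


@pytest.fixture(scope="session")
def recovery_measurements(recovery_cohort):
    out = []
    for s in recovery_cohort:
        det = c.cetcem_analyse(s.specimen)
        cs = c.coronal_slices_measure(s.specimen, det.frame, det.landmarks)
        bl = c.bony_landmarks_measure(s.specimen, det.frame, det.landmarks)
        out.append((s, det, cs, bl))
    return out
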