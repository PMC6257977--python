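import numpy as np
import pytest

import pairscreen as ps


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale generation settings used by most imaging tests."""
    return ps.SynthSpec(shape=(48, 64), n_frames=6, n_untreated=2, seed=11)


@pytest.fixture(scope="session")
def control_plate(small_spec):
    """A plate of 20 i.i.d. untreated wells."""
    recipes = {f"c{i:02d}": ps.WellRecipe() for i in range(20)}
    return ps.synth_plate(small_spec, recipes)


@pytest.fixture(scope="session")
def mixed_plate(small_spec):
    """30 controls, 10 morphology-shifted treated wells, one noise outlier."""
    recipes = {f"c{i:02d}": ps.WellRecipe() for i in range(30)}
    for i in range(10):
        recipes[f"t{i:02d}"] = ps.WellRecipe(morphology=0.8)
    recipes["x00"] = ps.WellRecipe(outlier=True)
    return ps.synth_plate(small_spec, recipes)


@pytest.fixture()
def roles_for(request):
    def _roles(plate):
        return {
            w: ("growth_control" if w.startswith("c") else "treated")
            for w in plate.datastore
        }

    return _roles


@pytest.fixture(scope="session")
def background_model(control_plate, small_spec):
    return ps.estimate_background(control_plate.datastore, small_spec.n_untreated)


def make_tem(well, values):
    """Wrap a raw array in a TEMMatrix for analysis-level tests."""
    values = np.asarray(values, dtype=float)
    return ps.TEMMatrix(
        well=well,
        values=values,
        schedule=ps.build_schedule(max(2, values.shape[0])),
        mask_mode="foreground_normalized",
        times=tuple(range(values.shape[1])),
    )
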