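import pytest

from preyprimer import PanelSpec, generate_panel


@pytest.fixture
def small_panel():
    """A compact planted panel for unit tests: 120 columns, two planted
    12-nt windows, 3 confounders (1 range-overlapping)."""
    from preyprimer.fixtures import PlantedWindow

    spec = PanelSpec(
        n_confounders=3,
        n_overlapping=1,
        alignment_length=120,
        background_sub_rate=0.05,
        indel_rate=0.0,
        planted_windows=(
            PlantedWindow(30, 12, 2, 3),
            PlantedWindow(70, 12, 2, 3),
        ),
        conserved_footprints=((5, 15), (100, 15)),
        seed=11,
    )
    return generate_panel(spec)


@pytest.fixture
def default_panel():
    return generate_panel(PanelSpec(seed=7))
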