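import pytest

from forestcarbon.inventory import PlotInventory, TreeRecord
from forestcarbon.synthetic import LandscapeSpec, StandSpec, generate_landscape_pair, generate_stand


@pytest.fixture(scope="session")
def default_stand():
    """A full synthetic census under the default study conditions."""
    return generate_stand(StandSpec(seed=11))


@pytest.fixture(scope="session")
def small_stand():
    """A small, fast stand for I/O and structural tests."""
    return generate_stand(StandSpec(n_plots=4, stems_per_plot=40, species_pool=20, seed=3))


@pytest.fixture()
def two_class_landscape_spec():
    return LandscapeSpec(
        n_rows=100,
        n_cols=100,
        classes=("forest", "nonforest"),
        initial_proportions=(0.6, 0.4),
        true_transition=((0.9, 0.1), (0.2, 0.8)),
        autocorr_passes=0,
        seed=7,
    )


@pytest.fixture()
def two_class_pair(two_class_landscape_spec):
    return generate_landscape_pair(two_class_landscape_spec)


def make_plot(plot_id, species_dbh_height, area_ha=0.16, stratum=None, subplots=None):
    """Tiny hand-built plot: species_dbh_height is a list of (sp, dbh, h)."""
    records = [
        TreeRecord(
            plot_id=plot_id,
            species=sp,
            dbh=dbh,
            height=h,
            subplot_id=None if subplots is None else subplots[i],
        )
        for i, (sp, dbh, h) in enumerate(species_dbh_height)
    ]
    return PlotInventory(plot_id=plot_id, records=records, area_ha=area_ha, stratum=stratum)
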