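import numpy as np
import pytest
from hypothesis import settings

from dendrocomp import fitting, synthetic
from dendrocomp.morphology import Group, Morphology, Section

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def single_cable(length=100.0, diameter=1.0, soma_area=452.0, group=Group.WT,
                 arbor="apical"):
    """Soma plus one unbranched cylinder."""
    sec = Section(id=0, parent_id=None, arbor=arbor, order_label="shaft",
                  length=length, diameter=diameter)
    return Morphology(neuron_id="cable", group=group, soma_area=soma_area,
                      sections=[sec])


@pytest.fixture(scope="session")
def wt_profile():
    return synthetic.default_profile("WT")


@pytest.fixture(scope="session")
def tg_profile():
    return synthetic.default_profile("TG")


@pytest.fixture(scope="session")
def wt_pop(wt_profile):
    return synthetic.generate_population(wt_profile, 10, 1)


@pytest.fixture(scope="session")
def tg_pop(tg_profile):
    return synthetic.generate_population(tg_profile, 10, 1)


@pytest.fixture(scope="session")
def wt_uniform_fits(wt_pop):
    fits = [fitting.fit_rm(m, "uniform") for m in wt_pop]
    fitting.fit_cm(fits, 17.0, mode="continuous")
    return fits


@pytest.fixture(scope="session")
def tg_uniform_fits(tg_pop):
    fits = [fitting.fit_rm(m, "uniform") for m in tg_pop]
    fitting.fit_cm(fits, 16.9, mode="continuous")
    return fits
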