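import numpy as np
import pytest

from cyclosim.kinetics import (CellModel, Compartment, CyclaseSource, pde_isoform)


@pytest.fixture
def one_compartment_model():
    """Single compartment, one PDE, one source: J = Vmax/2 so S* = Km."""
    pde4 = pde_isoform("PDE4", density_factor=1.0)  # vmax_local 0.03
    comp = Compartment(name="CYT", volume_fraction=1.0,
                       pdes=((pde4, 1.0),),
                       cyclases=(CyclaseSource("cAMP", j_basal=0.015,
                                               max_stim_factor=4.0),))
    return CellModel(genotype="control", nucleotide="cAMP", compartments=(comp,))


@pytest.fixture
def two_compartment_model():
    """Cytosolic source, PDE8-only shell coupled by first-order exchange."""
    pde8 = pde_isoform("PDE8", density_factor=1.0)  # vmax_local 0.15
    cyt = Compartment(name="CYT", volume_fraction=0.9,
                      cyclases=(CyclaseSource("cAMP", j_basal=0.004,
                                              max_stim_factor=4.0),))
    omm = Compartment(name="OMM", volume_fraction=0.1,
                      pdes=((pde8, 1.0),), exchanges={"CYT": 0.5})
    return CellModel(genotype="control", nucleotide="cAMP", compartments=(cyt, omm))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
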