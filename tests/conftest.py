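import numpy as np
import pytest

from tribasin.structures import assign_charges, coarse_grain
from tribasin.contacts import classify_contacts, compute_contact_map, ligand_mediated_contacts
from tribasin.topology import ModelParams, build_topology
from tribasin.toy import ToySpec, build_toy_system, make_toy_three_state


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy_models(toy_spec):
    """The (open, apo-closed, holo-closed) synthetic conformer triple."""
    return make_toy_three_state(toy_spec)


@pytest.fixture(scope="session")
def toy_cgs(toy_models):
    return tuple(assign_charges(coarse_grain(m)) for m in toy_models)


@pytest.fixture(scope="session")
def toy_maps(toy_models, toy_cgs, toy_spec):
    cut = toy_spec.contact_cutoff
    return tuple(
        compute_contact_map(m, cutoff=cut, cg=cg)
        for m, cg in zip(toy_models, toy_cgs)
    )


@pytest.fixture(scope="session")
def toy_mixed(toy_maps, toy_cgs):
    return classify_contacts(*toy_maps, toy_cgs[0])


@pytest.fixture(scope="session")
def toy_ligand_contacts(toy_models, toy_cgs, toy_spec):
    return ligand_mediated_contacts(
        toy_models[2], toy_spec.domain_map(), cutoff=toy_spec.contact_cutoff,
        cg=toy_cgs[2])


@pytest.fixture(scope="session")
def toy_topology(toy_cgs, toy_mixed, toy_ligand_contacts):
    """Default-parameter topology (ε_L = 0.5 so ligand contacts are present)."""
    params = ModelParams(eps_ligand=0.5)
    return build_topology(*toy_cgs, toy_mixed, params,
                          ligand_contacts=toy_ligand_contacts)


@pytest.fixture(scope="session")
def toy_system():
    """(topology, references, mixed map, ligand contacts) with θ_OAH angles."""
    params = ModelParams(eps_ligand=0.5, angle_model="theta_OAH")
    return build_toy_system(ToySpec(), params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
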