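import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_structure(tmp_path):
    """Minimal single-model PDB: a LYS NZ/CA and a GLU CD at known coords."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(3)
    atoms.chain_id[:] = "A"
    atoms.res_id[:] = [745, 745, 762]
    atoms.res_name[:] = ["LYS", "LYS", "GLU"]
    atoms.atom_name[:] = ["NZ", "CA", "CD"]
    atoms.element[:] = ["N", "C", "C"]
    atoms.coord = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 2.0], [3.0, 4.0, 0.0]])
    path = tmp_path / "tiny.pdb"
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))
    from kinasecv.cv import StructureAtoms

    return StructureAtoms.from_pdb(path)
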