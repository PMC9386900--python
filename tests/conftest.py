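import numpy as np
import pytest

from lemnomics.homology import ProteinRecord
from lemnomics.synthetic import simulate

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA), size=length))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """One coupled synthetic study (genome + reference db + DE tables)."""
    outdir = tmp_path_factory.mktemp("sim")
    truth = simulate(preset="small", seed=7, outdir=outdir)
    return outdir, truth


def make_record(
    record_id: str,
    sequence: str = "MKVLAAGG",
    species: str = "plant_sp1",
    taxon: str = "plant",
    go: tuple[str, ...] = (),
) -> ProteinRecord:
    return ProteinRecord(
        record_id=record_id,
        species=species,
        taxon_group=taxon,
        aa_sequence=sequence,
        go_terms=frozenset(go),
        descriptor=f"protein {record_id}",
    )
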