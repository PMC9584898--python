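import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from phoscross.model import PhosphoSite, ProteinEntry, STANDARD_RESIDUES
from phoscross.seeds import default_seed_set, human_asyn_entry, mouse_asyn_entry


@pytest.fixture(scope="session")
def seeds():
    return default_seed_set()


@pytest.fixture(scope="session")
def seed_by_id(seeds):
    return {s.seed_id: s for s in seeds}


@pytest.fixture
def human_asyn():
    return human_asyn_entry()


@pytest.fixture
def mouse_asyn():
    return mouse_asyn_entry()


def random_entry(rng: random.Random, index: int = 0) -> ProteinEntry:
    """A small random but valid protein record for round-trip tests."""
    length = rng.randint(20, 90)
    sequence = "".join(rng.choices(STANDARD_RESIDUES + "BZX", k=length))
    positions = sorted(rng.sample(range(1, length + 1),
                                  rng.randint(0, min(4, length))))
    sites = []
    chars = list(sequence)
    for pos in positions:
        residue = rng.choice("SY")
        chars[pos - 1] = residue
        kind = "phosphoserine" if residue == "S" else "phosphotyrosine"
        sites.append(PhosphoSite(pos, residue, kind))
    sequence = "".join(chars)
    taxon = rng.choice([9606, 10090, 10116])
    suffix = {9606: "HUMAN", 10090: "MOUSE"}.get(taxon, "RAT")
    return ProteinEntry(
        entry_name=f"TST{index:03d}_{suffix}",
        accession=f"Q{index:05d}",
        sequence=sequence,
        organism_taxon=taxon,
        mw_da=rng.randint(2000, 200000),
        gene_name=rng.choice(["", f"GN{index}"]),
        secondary_accessions=tuple(f"A{index:04d}{j}" for j in range(rng.randint(0, 2))),
        phosphosites=tuple(sites),
        locations=tuple(rng.sample(
            ["Cytoplasm", "Nucleus", "Membrane", "Secreted"], rng.randint(0, 2))),
    )
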