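import numpy as np
import pytest

from mycocheck import (Checklist, OccurrenceRecord, SimulationConfig,
                       SynonymTable, simulate_checklist)


def make_records(rows):
    """rows: (species, country, publication[, extras dict])."""
    out = []
    for row in rows:
        extras = row[3] if len(row) > 3 else {}
        out.append(OccurrenceRecord(species_name=row[0], country=row[1],
                                    publication_id=row[2], **extras))
    return out


@pytest.fixture
def toy_checklist():
    """Four records, two publications, three species, two countries."""
    return Checklist(records=make_records([
        ("Meliola clerodendricola", "BJ", "pub1"),
        ("Puccinia graminis", "BJ", "pub1"),
        ("Puccinia graminis", "TG", "pub2"),
        ("Russula cellulata", "TG", "pub2"),
    ]), provenance="toy")


@pytest.fixture
def toy_synonyms():
    return SynonymTable({
        "Cercospora arachidicola": ("accepted", "Cercospora arachidicola"),
        "Cercosporina arachidicola": ("synonym", "Cercospora arachidicola"),
        "Puccinia graminis": ("accepted", "Puccinia graminis"),
    })


@pytest.fixture(scope="session")
def sim_small():
    """A small simulated checklist with ground truth (shared across tests)."""
    cfg = SimulationConfig(S_true=200, n_publications=60, seed=3)
    return simulate_checklist(cfg)


def random_incidence(rng, n_species=None, m=None):
    """A random presence matrix where every species occurs at least once."""
    n_species = n_species or int(rng.integers(3, 25))
    m = m or int(rng.integers(2, 12))
    presence = rng.random((n_species, m)) < rng.uniform(0.1, 0.7)
    for i in np.nonzero(presence.sum(axis=1) == 0)[0]:
        presence[i, rng.integers(m)] = True
    from mycocheck import IncidenceMatrix
    return IncidenceMatrix([f"s{i}" for i in range(n_species)],
                           [f"u{j}" for j in range(m)], presence)
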