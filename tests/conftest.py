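import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pnaprimers.insilico import TaxonGroupDef
from pnaprimers.synth import GroupSpec, ReferenceDBSpec, generate_reference_db, synthetic_primer_pair


@pytest.fixture(scope="session")
def synthetic_pairs():
    """Three degenerate primer pairs with known sequences."""
    return [synthetic_primer_pair(f"pp{i}", seed=100 + i) for i in range(3)]


@pytest.fixture(scope="session")
def planted_db(synthetic_pairs):
    """Small reference DB with per-group planted coverages and its truth table.

    Group labels are chosen so that no label is a substring of another
    (group membership uses substring rank patterns).
    """
    fractions = {"Alpha": 1.0, "Beta": 0.8, "Gamma": 0.25, "Delta": 0.0}
    groups = [
        GroupSpec(
            label=g, n=40, length=400,
            site_intact_fraction={p.name: f for p in synthetic_pairs},
            taxonomy=f"Bacteria;SyntheticPhylum;{g}",
        )
        for g, f in fractions.items()
    ]
    db, truth = generate_reference_db(ReferenceDBSpec(groups), synthetic_pairs, seed=2024)
    gdefs = [TaxonGroupDef(g, (g,)) for g in fractions]
    return db, truth, gdefs
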