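"""Shared fixtures: the bundled haplotype key, a seeded synthetic backbone,
the reconstructed silver carp panel, and assignment indices. Session-scoped
because everything downstream is deterministic and read-only."""

import pytest

import carpamp as C
from carpamp.detect import index_from_inserts
from carpamp.simulate import default_spacer_schemes


@pytest.fixture(scope="session")
def vt():
    return C.load_silver_carp_table()


@pytest.fixture(scope="session")
def amp():
    return C.default_amplicon()


@pytest.fixture(scope="session")
def backbone(vt, amp):
    return C.make_backbone(vt, amp, seed=1)


@pytest.fixture(scope="session")
def silver_haps(vt, backbone):
    return C.reconstruct_haplotypes(vt, backbone)


@pytest.fixture(scope="session")
def silver_panel(silver_haps):
    panel = C.ReferencePanel()
    for h in silver_haps:
        panel.add(h)
    return panel


@pytest.fixture(scope="session")
def silver_inserts(silver_haps, amp):
    return {h.label: C.extract_insert(h, amp)[0] for h in silver_haps}


@pytest.fixture(scope="session")
def bighead_inserts(silver_inserts, vt, amp):
    return C.build_synthetic_bighead_inserts(silver_inserts, vt, amp.insert_window)


@pytest.fixture(scope="session")
def panel_inserts(silver_inserts, bighead_inserts):
    keyed = {("silver carp", k): v for k, v in silver_inserts.items()}
    keyed.update({("bighead carp", k): v for k, v in bighead_inserts.items()})
    return keyed


@pytest.fixture(scope="session")
def panel_index(panel_inserts):
    return index_from_inserts(panel_inserts)


@pytest.fixture(scope="session")
def control_inserts(panel_inserts):
    return C.make_control_inserts(panel_inserts, n_species=10, seed=1)


@pytest.fixture(scope="session")
def cfg():
    return C.RunConfig()


def make_run_spec(panel_inserts, control_inserts, *, seed, compositions=None, roles=None,
                  reads_per_sample=2000, **rates):
    """Assemble a RunSimulationSpec for a small bait-shop-style run."""
    keyed = {f"{sp}|{lab}": seq for (sp, lab), seq in panel_inserts.items()}
    keyed.update({f"control|{lab}": seq for lab, seq in control_inserts.items()})
    if compositions is None:
        compositions = {
            "shop1": {"silver carp|A": 0.6, "silver carp|B": 0.4},
            "pc1": {f"control|{lab}": 1.0 / len(control_inserts) for lab in control_inserts},
            "ntc1": {},
        }
        roles = {"shop1": "sample", "pc1": "positive_control", "ntc1": "ntc"}
    schemes = default_spacer_schemes(sorted(compositions))
    return C.RunSimulationSpec(
        inserts=keyed,
        compositions=compositions,
        roles=roles,
        schemes=schemes,
        seed=seed,
        reads_per_sample=reads_per_sample,
        **rates,
    )
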