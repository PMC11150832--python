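"""Species construction, enumeration and labelling."""

import itertools

import pytest

from ethercdl import (
    ADDUCTS,
    CoreLipid,
    RadylChain,
    build_species,
    enumerate_species,
    monoisotopic_mass,
    parse_formula,
    parse_label,
    species_label,
)
from ethercdl.lipids import ETHER_ESTER_DELTA, enumerate_cores


def _chain(spec: str) -> RadylChain:
    linkage = "ether" if spec[0] == "e" else "ester"
    body = spec[1:]
    n, _, u = body.partition(":")
    return RadylChain(int(n), linkage, n_unsat=int(u or 0))


def _sp(head, *core_specs, variant=None):
    cores = [[_chain(c) for c in cs.split("/")] for cs in core_specs]
    return build_species(head, cores, dilyso_variant=variant)


# Expected formulas hand-counted atom by atom from the glycerol/head-group
# scaffolds and chain substituents (independent of the builder's arithmetic).
HAND_COUNTED = [
    ("PE", ("a16/a16",), None, "C37H74NO8P"),     # DPPE
    ("PG", ("a16/a16",), None, "C38H75O10P"),     # DPPG
    ("PE", ("e16/e16",), None, "C37H78NO6P"),
    ("PG", ("e17/e14",), None, "C37H77O8P"),
    ("PG", ("e16/e15",), None, "C37H77O8P"),      # mass isomer of the above
    ("PE", ("e16/a14",), None, "C35H72NO7P"),
    ("PE", ("a17/e15",), None, "C37H76NO7P"),
    ("PG", ("e16/a16",), None, "C38H77O9P"),
    ("PE", ("e14",), None, "C19H42NO6P"),         # lyso-PE, MEG core
    ("PE", ("a16",), None, "C21H44NO7P"),         # lyso-PE, MAG core
    ("PG", ("a16",), None, "C22H45O9P"),          # lyso-PG
    ("CDL", ("e17/e16", "e17/e14"), None, "C73H150O13P2"),  # tetraether
    ("CDL", ("a17/a16", "a17/a14"), None, "C73H142O17P2"),  # tetraester
    ("CDL", ("e17/e16", "a17/a14"), None, "C73H146O15P2"),  # diether/diester
    ("CDL", ("e17/a16", "a17/a14"), None, "C73H144O16P2"),  # monoether
    ("CDL", ("e17/e14", "e14"), None, "C54H112O13P2"),      # monolyso e3 C45
    ("CDL", ("e17/e14", "a14"), None, "C54H110O14P2"),      # monolyso with acyl
    ("CDL", ("e14", "e17"), "two-monolyso-cores", "C40H84O13P2"),
    ("CDL", ("e17/e14",), "intact-core+pgp", "C40H84O13P2"),  # same mass
    (None, ("e14/e14",), None, "C31H64O3"),       # free C28 diether glyceride
    (None, ("e17/e17:1",), None, "C37H74O3"),     # free C34:1 diether
    (None, ("e14",), None, "C17H36O3"),           # free monoether glyceride
]


@pytest.mark.parametrize("head,cores,variant,expected", HAND_COUNTED)
def test_neutral_formula_matches_hand_count(head, cores, variant, expected):
    sp = _sp(head, *cores, variant=variant)
    assert sp.neutral_formula == parse_formula(expected)


def test_flagship_species_and_printed_masses():
    cdl = _sp("CDL", "e17/e16", "e17/e14")
    assert ADDUCTS["[M+H]+"].ion_formula(cdl.neutral_formula) == parse_formula(
        "C73H151O13P2"
    )
    mlcl = _sp("CDL", "e17/e14", "e14")
    assert round(ADDUCTS["[M+H]+"].mz(mlcl.neutral_formula), 1) == 1031.8
    dlcl = _sp("CDL", "e14", "e17", variant="two-monolyso-cores")
    assert round(ADDUCTS["[M+H]+"].mz(dlcl.neutral_formula), 1) == 835.5
    free_deg = _sp(None, "e14/e14")
    assert ADDUCTS["[M+NH4]+"].ion_formula(free_deg.neutral_formula) == (
        parse_formula("C31H68NO3")
    )


def test_branch_note_is_mass_neutral():
    a = RadylChain(17, "ether", n_unsat=0, branch_note="10-Me")
    b = RadylChain(17, "ether", n_unsat=0, branch_note=None)
    assert a.formula == b.formula
    assert a == b  # annotation does not affect identity


def test_dilyso_variants_share_formula_but_are_distinct_species():
    va = _sp("CDL", "e14", "e17", variant="two-monolyso-cores")
    vb = _sp("CDL", "e17/e14", variant="intact-core+pgp")
    assert va.neutral_formula == vb.neutral_formula
    assert species_label(va) != species_label(vb)
    assert va.species_key == vb.species_key == "DLCL 31:0;e2"


def test_core_class_derivation():
    mk = lambda *specs: CoreLipid(tuple(_chain(s) for s in specs))
    assert mk("e16", "e14").core_class == "DEG"
    assert mk("e16", "a14").core_class == "AEG"
    assert mk("a16", "a14").core_class == "DAG"
    assert mk("e16").core_class == "MEG"
    assert mk("a16").core_class == "MAG"


def test_arity_validation():
    with pytest.raises(ValueError):
        _sp("PE", "e16/e14", "e16/e14")
    with pytest.raises(ValueError):
        build_species("CDL", [[_chain("e16")]])
    with pytest.raises(ValueError):
        CoreLipid(())


def test_label_round_trip_and_determinism(default_species):
    for sp in default_species:
        lab = species_label(sp)
        assert species_label(sp) == lab
        assert species_label(parse_label(lab)) == lab


def test_ether_ester_series_spacing():
    """Successive members of the C64 ether→ester ladder differ by −2H +1O."""
    chains = ["e17", "e16", "e17", "e14"]
    masses = []
    for n_esters in range(5):
        specs = ["a" + c[1:] if i < n_esters else c for i, c in enumerate(chains)]
        sp = _sp("CDL", f"{specs[0]}/{specs[1]}", f"{specs[2]}/{specs[3]}")
        masses.append(ADDUCTS["[M+H]+"].mz(sp.neutral_formula))
    for lo, hi in zip(masses, masses[1:]):
        assert hi - lo == pytest.approx(ETHER_ESTER_DELTA, abs=1e-3)
    assert [round(m, 2) for m in masses] == [
        1298.06, 1312.04, 1326.02, 1340.00, 1353.98
    ]


def test_enumeration_counts_and_ranges(default_species):
    cores_ordered = enumerate_cores(ordered=True, linkages=("ether",))
    assert len(cores_ordered) == 16  # 4 lengths x 4 lengths, (sn-1, sn-2)
    assert {c.n_carbons for c in cores_ordered} == set(range(28, 35))

    cdls = [s for s in default_species if s.class_token == "CDL"]
    assert {s.total_carbons for s in cdls} == set(range(56, 69))
    assert {s.total_ethers for s in cdls} == {0, 1, 2, 3, 4}

    # closed-form size check: unordered pairs of two-chain cores
    two_chain = enumerate_cores()
    expected = len(two_chain) * (len(two_chain) + 1) // 2
    assert len(cdls) == expected

    labels = [s.label for s in default_species]
    assert len(labels) == len(set(labels))


def test_enumeration_ether_count_filter():
    only_e4 = enumerate_species(head_groups=("CDL",), ether_counts=(4,))
    assert all(s.total_ethers == 4 for s in only_e4)
    all_cdl = enumerate_species(head_groups=("CDL",))
    assert {s.total_ethers for s in all_cdl} == {0, 1, 2, 3, 4}


def test_total_ethers_equals_sum_over_cores(default_species):
    for sp in default_species[::53]:
        assert sp.total_ethers == sum(c.ether_count for c in sp.cores)
        assert sp.total_carbons == sum(c.n_carbons for c in sp.cores)
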