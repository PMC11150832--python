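"""MS2 fragmentation rules: printed worked example, conservation, hints."""

import pytest

from ethercdl import (
    RadylChain,
    build_species,
    explain_peak,
    parse_formula,
    parse_label,
    ppm_error,
    predict_fragments,
)

# every printed peak of the tetraether CDL MS2 spectrum with its rule
FIG_WORKED_EXAMPLE = [
    ("R1", 1280.050),
    ("R2", 771.529),
    ("R2", 743.497),
    ("R3", 691.563),
    ("R3", 663.531),
    ("R4", 234.977),
    ("R4", 155.010),
    ("R5", 297.315),
    ("R5", 283.299),
    ("R5", 255.268),
]


@pytest.fixture(scope="module")
def tetraether_fragments(request):
    sp = parse_label("CDL 64:0;e4 [e17/e16 | e17/e14]")
    return predict_fragments(sp, "[M+H]+")


@pytest.mark.parametrize("rule,observed", FIG_WORKED_EXAMPLE)
def test_tetraether_worked_example_within_5ppm(tetraether_fragments, rule, observed):
    matches = explain_peak(observed, tetraether_fragments, tol_ppm=5.0)
    assert matches, f"no predicted ion near {observed}"
    assert any(e.rule_id == rule for e in matches)


def test_printed_neutral_losses(tetraether_fragments):
    losses = {
        str(e.formula): e.mz for e in tetraether_fragments.neutral_losses()
        if e.rule_id == "R2"
    }
    assert losses["C34H70O3"] == pytest.approx(526.533, abs=526.533 * 5e-6)
    assert losses["C36H74O3"] == pytest.approx(554.566, abs=554.566 * 5e-6)


def test_r2_pairs_conserve_mass(default_species):
    """mass(ion) + mass(neutral) = mass(precursor ion) to 1e-9 Da."""
    from ethercdl.formula import monoisotopic_mass

    for sp in default_species[::17]:
        fs = predict_fragments(sp, "[M+H]+")
        for loss in fs.neutral_losses():
            companion = fs.precursor_formula - loss.formula
            ion = next(e for e in fs.ions() if e.formula == companion)
            # neutral mass + (electron-corrected) ion m/z reconstruct the
            # precursor m/z exactly
            assert loss.mz + ion.mz == pytest.approx(fs.precursor_mz, abs=1e-9)
            assert loss.formula + ion.formula == fs.precursor_formula


def test_r5_formula_family(tetraether_fragments):
    r5 = {str(e.formula): round(e.mz, 3) for e in tetraether_fragments.ions()
          if e.rule_id == "R5"}
    assert r5 == {
        "C17H35O": 255.268, "C19H39O": 283.300, "C20H41O": 297.315,
    }


def test_tetraester_has_no_r5_entries():
    sp = parse_label("CDL 64:0;e0 [a17/a16 | a17/a14]")
    fs = predict_fragments(sp)
    assert not [e for e in fs.ions() if e.rule_id == "R5"]


def test_symmetric_cdl_deduplicates_core_losses():
    sp = parse_label("CDL 62:0;e4 [e17/e14 | e17/e14]")
    fs = predict_fragments(sp)
    assert len([e for e in fs.entries if e.rule_id == "R2" and e.kind == "ion"]) == 1
    assert len([e for e in fs.entries if e.rule_id == "R3" and e.kind == "ion"]) == 1


def test_monolyso_core_losses():
    sp = build_species(
        "CDL",
        [[RadylChain(14, "ether", 1)],
         [RadylChain(17, "ether", 1), RadylChain(14, "ether", 2)]],
    )
    fs = predict_fragments(sp)
    assert abs(ppm_error(1031.766, fs.precursor_mz)) < 5
    losses = {str(e.formula) for e in fs.neutral_losses() if e.rule_id == "R2"}
    assert losses == {"C17H36O3", "C34H70O3"}  # MEG C14 and DEG C31 cores


def test_abundance_hint_flags_acyl_core_loss_next_to_all_ether_core():
    mixed = parse_label("CDL 64:0;e2 [e17/e16 | a17/a14]")
    fs = predict_fragments(mixed)
    by_desc = {(e.rule_id, e.description): e.abundance_hint
               for e in fs.entries if e.rule_id in ("R2", "R3")}
    # ejecting the DAG while the DEG stays -> weak; ejecting the DEG -> not
    assert all(
        h == "low" for (r, d), h in by_desc.items() if "DAG" in d
    )
    assert all(
        h == "high" for (r, d), h in by_desc.items() if "DEG" in d
    )


def test_cdl_rules_require_protonated_precursor(tetraether_fragments):
    with pytest.raises(ValueError):
        predict_fragments(tetraether_fragments.species, "[M+Na]+")


def test_pe_pg_rules_are_optional_and_flagged():
    pe = parse_label("PE 31:0;e1 [e17/a14]")
    assert not predict_fragments(pe).entries
    fs = predict_fragments(pe, pe_pg_rules=True)
    assert fs.entries and all(e.rule_id == "R6" for e in fs.entries)
    assert all("extrapolated" in e.description for e in fs.entries)
    # fatty-acid loss for the acyl chain, alkyl ion for the ether chain
    assert any(str(e.formula) == "C14H28O2" for e in fs.neutral_losses())
    assert any(str(e.formula) == "C20H41O" for e in fs.ions())


def test_explain_peak_no_match_and_headgroup(tetraether_fragments):
    assert explain_peak(500.0, tetraether_fragments, 5.0) == []
    hits = explain_peak(234.977, tetraether_fragments, 5.0)
    assert [e.rule_id for e in hits] == ["R4"]


def test_ions_contained_in_precursor(default_species):
    for sp in default_species[::41]:
        fs = predict_fragments(sp, "[M+H]+")
        for e in fs.ions():
            assert fs.precursor_formula.contains(e.formula)
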