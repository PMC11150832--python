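"""XIC-based relative quantification and composition reports."""

import numpy as np
import pandas as pd
import pytest

from ethercdl import ADDUCTS, m1_ratio, parse_label, quantify
from ethercdl.quantify import composition_report, species_metadata


def _xic(rows):
    return pd.DataFrame(rows, columns=["species", "adduct", "area"])


CDL_A = "CDL 64:0;e4 [e17/e16 | e17/e14]"
CDL_B = "CDL 62:0;e4 [e17/e14 | e17/e14]"
PE_A = "PE 31:0;e2 [e17/e14]"


def test_single_species_is_100_percent():
    res = quantify(_xic([(CDL_A, "[M+H]+", 123.0), (CDL_A, "[M+Na]+", 7.0)]))
    assert len(res) == 1
    assert res.loc[0, "percent"] == pytest.approx(100.0)


def test_summed_adduct_ratio():
    res = quantify(_xic([
        (CDL_A, "[M+H]+", 200.0), (CDL_A, "[M+NH4]+", 100.0),
        (PE_A, "[M+H]+", 60.0), (PE_A, "[M+NH4]+", 40.0),
    ]))
    by = res.set_index("species")["percent"]
    assert by[CDL_A] == pytest.approx(75.0)
    assert by[PE_A] == pytest.approx(25.0)


def test_unconfigured_adducts_are_ignored_for_class():
    # [M+Na]+ is not a configured PE channel and must not count
    res = quantify(_xic([
        (PE_A, "[M+H]+", 50.0), (PE_A, "[M+Na]+", 1000.0),
        (CDL_A, "[M+H]+", 50.0),
    ]))
    by = res.set_index("species")["percent"]
    assert by[PE_A] == pytest.approx(50.0)


def test_species_without_configured_channels_raises():
    with pytest.raises(ValueError, match="configured adducts"):
        quantify(_xic([(PE_A, "[M+Na]+", 10.0)]))


def test_scale_policy_equals_dropping_m1_when_theoretical():
    """Substituting M+1/m1_ratio for the monoisotopic area is a no-op when
    the M+1 area is exactly theoretical."""
    sp = parse_label(CDL_A)
    r = m1_ratio(ADDUCTS["[M+H]+"].ion_formula(sp.neutral_formula))
    base = [
        (CDL_A, "[M+H]+", 100.0), (CDL_A, "[M+Na]+", 30.0),
        (CDL_A, "M+1", 100.0 * r),
        (CDL_B, "[M+H]+", 50.0),
    ]
    scaled = quantify(_xic(base), policy="scale")
    without_m1 = quantify(_xic([b for b in base if b[1] != "M+1"]), policy="sum")
    a = scaled.set_index("species")["percent"]
    b = without_m1.set_index("species")["percent"]
    assert a[CDL_A] == pytest.approx(b[CDL_A], abs=1e-9)


def test_sum_policy_adds_m1():
    res = quantify(_xic([
        (CDL_A, "[M+H]+", 100.0), (CDL_A, "M+1", 50.0),
        (CDL_B, "[M+H]+", 150.0),
    ]), policy="sum")
    by = res.set_index("species")["abundance"]
    assert by[CDL_A] == pytest.approx(150.0)


def test_scale_invariance():
    rows = [(CDL_A, "[M+H]+", 3.0), (CDL_B, "[M+H]+", 1.0),
            (PE_A, "[M+H]+", 4.0)]
    p1 = quantify(_xic(rows)).set_index("species")["percent"]
    p2 = quantify(
        _xic([(s, a, v * 1e6) for s, a, v in rows])
    ).set_index("species")["percent"]
    assert np.allclose(p1.sort_index(), p2.sort_index())


def test_negative_area_rejected():
    with pytest.raises(ValueError, match="negative"):
        quantify(_xic([(CDL_A, "[M+H]+", -1.0)]))


def test_composition_report_equal_series():
    """Five equal-abundance C64 CDL ether classes -> 20% each."""
    labels = [
        "CDL 64:0;e4 [e17/e16 | e17/e14]",
        "CDL 64:0;e3 [e17/e16 | e17/a14]",
        "CDL 64:0;e2 [e17/e16 | a17/a14]",
        "CDL 64:0;e1 [e17/a16 | a17/a14]",
        "CDL 64:0;e0 [a17/a16 | a17/a14]",
    ]
    ab = pd.DataFrame({"species": labels, "abundance": [10.0] * 5})
    rep = composition_report(ab, group_by=["total_ethers"])
    assert np.allclose(rep["percent"], 20.0)
    assert rep["percent"].sum() == pytest.approx(100.0)


def test_composition_report_marginal_consistency():
    rng = np.random.default_rng(11)
    labels = [CDL_A, CDL_B, PE_A, "PG 31:0;e2 [e17/e14]",
              "CDL 64:0;e2 [e17/e16 | a17/a14]"]
    ab = pd.DataFrame({"species": labels,
                       "abundance": rng.uniform(1, 10, len(labels))})
    joint = composition_report(ab, group_by=["total_ethers", "total_carbons"])
    marg = composition_report(ab, group_by=["total_ethers"])
    summed = joint.groupby("total_ethers")["percent"].sum()
    for _, row in marg.iterrows():
        assert summed[row["total_ethers"]] == pytest.approx(row["percent"])
    # per-group normalization sums to 100 within each 'within' cell
    per_class = composition_report(
        ab, group_by=["class_token", "total_ethers"], within=["class_token"]
    )
    sums = per_class.groupby("class_token")["percent"].sum()
    assert np.allclose(sums, 100.0)


def test_composition_report_empty_input_rejected():
    with pytest.raises(ValueError, match="empty"):
        composition_report(pd.DataFrame(columns=["species", "abundance"]),
                           group_by=["total_ethers"])


def test_species_metadata_parses_both_label_levels():
    meta = species_metadata([CDL_A, "DLCL 31:0;e2", "LPE 14:0;e1 [e14]"])
    assert list(meta["class_token"]) == ["CDL", "DLCL", "LPE"]
    assert list(meta["lyso_count"]) == [0, 2, 1]
    assert list(meta["total_ethers"]) == [4, 2, 1]
    assert meta.loc[1, "species_key"] == "DLCL 31:0;e2"
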