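"""Relative quantification from integrated extracted-ion-chromatogram areas.

Abundance of a species is the sum of the XIC areas of its configured
adducts; for cardiolipins the ¹³C first-isotopologue ("M+1") trace of the
[M+H]+ ion is used as well, either added as-is (policy ``"sum"``) or scaled
by the theoretical M+1/M ratio and substituted for the monoisotopic [M+H]+
area (policy ``"scale"``, the usual remedy when the monoisotopic trace is
saturated or interfered).

No cross-class response-factor correction is applied: phospholipid classes
(and core structures within a class) ionize with different efficiencies, so
the reported percentages are as-measured relative abundances, and output
metadata carries an explicit ``response_corrected = False`` flag.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence

import pandas as pd

from .formula import ADDUCTS, m1_ratio
from .lipids import parse_label

__all__ = [
    "DEFAULT_ADDUCT_POLICY",
    "species_metadata",
    "quantify",
    "composition_report",
]

# which XIC channels count toward each class's abundance; "M+1" is the
# 13C isotopologue trace of the [M+H]+ ion
DEFAULT_ADDUCT_POLICY: dict[str, tuple[str, ...]] = {
    "PE": ("[M+H]+", "[M+NH4]+"),
    "PG": ("[M+H]+", "[M+NH4]+"),
    "LPE": ("[M+H]+", "[M+NH4]+"),
    "LPG": ("[M+H]+", "[M+NH4]+"),
    "CDL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+", "M+1"),
    "MLCL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+", "M+1"),
    "DLCL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+", "M+1"),
}

_KEY_RE = re.compile(r"^(?P<cls>[A-Z]+)\s+(?P<c>\d+):(?P<u>\d+);e(?P<e>\d+)")

_LYSO = {"MLCL": 1, "DLCL": 2, "LPE": 1, "LPG": 1}
_HEAD = {"PE": "PE", "LPE": "PE", "PG": "PG", "LPG": "PG",
         "CDL": "CDL", "MLCL": "CDL", "DLCL": "CDL"}


def species_metadata(labels: Iterable[str]) -> pd.DataFrame:
    """Structural metadata parsed from molecular or species-level labels."""
    rows = []
    for lab in labels:
        m = _KEY_RE.match(lab.strip())
        if not m:
            raise ValueError(f"unparseable species label {lab!r}")
        cls = m.group("cls")
        rows.append(
            dict(
                label=lab,
                class_token=cls,
                head_group=_HEAD.get(cls),
                lyso_count=_LYSO.get(cls, 0),
                total_carbons=int(m.group("c")),
                total_unsat=int(m.group("u")),
                total_ethers=int(m.group("e")),
                species_key=f"{cls} {m.group('c')}:{m.group('u')};e{m.group('e')}",
            )
        )
    return pd.DataFrame(rows)


def _m1_ratio_for(label: str) -> float:
    sp = parse_label(label)
    return m1_ratio(ADDUCTS["[M+H]+"].ion_formula(sp.neutral_formula))


def quantify(
    xics: pd.DataFrame,
    policy: str = "sum",
    adduct_map: Optional[dict[str, tuple[str, ...]]] = None,
) -> pd.DataFrame:
    """Per-species abundances and relative percentages from XIC areas.

    ``xics`` needs columns ``species`` (label), ``adduct`` (adduct name or
    ``"M+1"``) and ``area``.  Only channels configured for the species'
    class are used.  Policy ``"sum"`` adds the M+1 area; ``"scale"``
    replaces the [M+H]+ area by area(M+1)/m1_ratio (requires a molecular
    label so the ion formula is known).
    """
    if policy not in ("sum", "scale"):
        raise ValueError(f"unknown policy {policy!r}")
    required = {"species", "adduct", "area"}
    if not required <= set(xics.columns):
        raise ValueError(f"XIC table needs columns {sorted(required)}")
    if (xics["area"] < 0).any():
        raise ValueError("negative XIC area")
    amap = adduct_map or DEFAULT_ADDUCT_POLICY

    meta = species_metadata(xics["species"].unique())
    meta_by_label = meta.set_index("label")

    out = []
    for label, grp in xics.groupby("species", sort=True):
        cls = meta_by_label.loc[label, "class_token"]
        allowed = amap.get(cls, ("[M+H]+",))
        used = grp[grp["adduct"].isin(allowed)]
        if used.empty:
            raise ValueError(
                f"species {label!r} has no XIC rows for its configured adducts {allowed}"
            )
        areas = used.groupby("adduct")["area"].sum()
        if policy == "scale" and "M+1" in areas.index:
            scaled = areas["M+1"] / _m1_ratio_for(label)
            abundance = areas.drop(["M+1", "[M+H]+"], errors="ignore").sum() + scaled
        else:
            abundance = areas.sum()
        out.append(dict(species=label, abundance=abundance))
    res = pd.DataFrame(out)
    total = res["abundance"].sum()
    if total <= 0:
        raise ValueError("all abundances are zero")
    res["percent"] = res["abundance"] / total * 100.0
    res = res.merge(meta, left_on="species", right_on="label").drop(columns="label")
    res.attrs["response_corrected"] = False
    res.attrs["policy"] = policy
    return res


def composition_report(
    abundances: pd.DataFrame,
    group_by: Sequence[str],
    within: Sequence[str] = (),
    value_column: str = "abundance",
) -> pd.DataFrame:
    """Marginal percentage distribution over the requested structural keys.

    ``group_by`` keys come from :func:`species_metadata` (``head_group``,
    ``class_token``, ``total_ethers``, ``total_carbons``, ``lyso_count``,
    ...).  Percentages are normalized within each combination of the
    ``within`` keys (a subset of ``group_by``); by default they sum to 100
    over the whole table.
    """
    if abundances.empty:
        raise ValueError("empty abundance table")
    df = abundances.copy()
    missing = [k for k in group_by if k not in df.columns]
    if missing:
        meta = species_metadata(df["species"].unique())
        df = df.merge(meta, left_on="species", right_on="label",
                      suffixes=("", "_meta"))
    bad = [k for k in within if k not in group_by]
    if bad:
        raise ValueError(f"'within' keys must be part of group_by: {bad}")
    g = df.groupby(list(group_by), sort=True)[value_column].sum().reset_index()
    if within:
        denom = g.groupby(list(within))[value_column].transform("sum")
    else:
        denom = g[value_column].sum()
    g["percent"] = g[value_column] / denom * 100.0
    g.attrs["normalized_within"] = tuple(within)
    g.attrs["response_corrected"] = False
    return g.drop(columns=value_column)
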