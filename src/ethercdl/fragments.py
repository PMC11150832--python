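"""Rule-based prediction of diagnostic MS² ions for ether/ester lipids.

The positive-mode fragmentation scheme of protonated cardiolipins is
encoded as five rules (with one optional extrapolated rule for PE/PG):

R1
    Loss of H2O from [M+H]+, attributed to the free hydroxyl of the
    central glycerol of the CDL backbone.
R2
    For each core, neutral loss of its free (di/mono)radylglycerol
    (glycerol + chains), leaving the complementary phosphatidyl-PG ion.
R3
    Each R2 ion further loses HPO3 (79.9663 Da), leaving the remaining
    core with a PG moiety.
R4
    Head-group ions from the phosphatidyl-glycero-phosphatidyl backbone:
    glycerophosphate C3H8O5P+ and glycerodiphosphate C3H9O8P2+.
R5
    For each ether-bound chain of n carbons, an alkyl(oxy)-derived ion
    C(n+3)H(2n+7)O+ (the chain with a C3H4O glycerol remnant).
R6 (off by default)
    Generic PE/PG chain-loss ions — fatty-acid and ketene losses for acyl
    chains, the R5-type ion for ether chains.  These follow common
    glycerophospholipid practice rather than a class-specific scheme
    observed here, and are flagged as an extrapolation.

Qualitatively, fragments that require ejecting an acyl-containing core
while an all-ether core is present are weak or absent in mixed ether/ester
CDLs; this is carried as ``abundance_hint="low"``, never as a quantitative
intensity model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .formula import ADDUCTS, Adduct, ElementalFormula, monoisotopic_mass, parse_formula, ppm_error
from .lipids import LipidSpecies

__all__ = ["FragmentEntry", "FragmentSet", "predict_fragments", "explain_peak"]

HPO3 = parse_formula("HPO3")
H2O = parse_formula("H2O")
GLYCEROPHOSPHATE_ION = parse_formula("C3H8O5P")
GLYCERODIPHOSPHATE_ION = parse_formula("C3H9O8P2")


@dataclass(frozen=True)
class FragmentEntry:
    rule_id: str
    kind: Literal["ion", "neutral_loss"]
    formula: ElementalFormula
    mz: float  # m/z for ions, Da for neutral losses
    abundance_hint: Literal["high", "low"] = "high"
    description: str = ""


@dataclass(frozen=True)
class FragmentSet:
    """Predicted diagnostic ions and neutral losses for one species+adduct."""

    species: LipidSpecies
    adduct: Adduct
    precursor_formula: ElementalFormula
    precursor_mz: float
    entries: tuple[FragmentEntry, ...] = field(default_factory=tuple)

    def ions(self) -> list[FragmentEntry]:
        return [e for e in self.entries if e.kind == "ion"]

    def neutral_losses(self) -> list[FragmentEntry]:
        return [e for e in self.entries if e.kind == "neutral_loss"]

    def ion_mz(self) -> np.ndarray:
        return np.array([e.mz for e in self.ions()])

    def to_records(self) -> list[dict]:
        base = dict(
            species=self.species.label,
            adduct=self.adduct.name,
            precursor_mz=round(self.precursor_mz, 4),
        )
        return [
            {**base, "rule": e.rule_id, "kind": e.kind, "formula": str(e.formula),
             "mz": round(e.mz, 4), "abundance_hint": e.abundance_hint,
             "description": e.description}
            for e in self.entries
        ]


def _ion(formula: ElementalFormula, rule: str, hint: str = "high", desc: str = "") -> FragmentEntry:
    return FragmentEntry(rule, "ion", formula, monoisotopic_mass(formula, 1), hint, desc)


def _loss(formula: ElementalFormula, rule: str, hint: str = "high", desc: str = "") -> FragmentEntry:
    return FragmentEntry(rule, "neutral_loss", formula, monoisotopic_mass(formula, 0), hint, desc)


def predict_fragments(
    species: LipidSpecies,
    adduct: Adduct | str = "[M+H]+",
    pe_pg_rules: bool = False,
) -> FragmentSet:
    """Predict the diagnostic MS² fragment set of one species under one adduct.

    CDL-family species are fragmented as [M+H]+ only (the scheme is defined
    for the protonated ion).  PE/PG emit chain-informative entries only when
    ``pe_pg_rules`` (rule R6) is enabled.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unknown adduct {adduct!r}") from None

    hg = species.head_group
    if hg == "CDL" and adduct.name != "[M+H]+":
        raise ValueError(
            f"CDL-family MS² rules are defined for [M+H]+ only, got {adduct.name}"
        )
    neutral = species.neutral_formula
    prec = adduct.ion_formula(neutral)
    prec_mz = monoisotopic_mass(prec, 1)
    entries: list[FragmentEntry] = []
    seen: set[tuple[str, ElementalFormula]] = set()

    def add(entry: FragmentEntry) -> None:
        key = (entry.rule_id, entry.formula)
        if key not in seen:
            seen.add(key)
            entries.append(entry)

    if hg == "CDL":
        # R1: single water loss from the central glycerol hydroxyl
        add(_ion(prec - H2O, "R1", desc="loss of H2O"))
        add(_loss(H2O, "R1", desc="water"))

        for i, core in enumerate(species.cores):
            lost = core.formula
            core_has_acyl = core.ether_count < len(core.chains)
            # weak when an acyl-containing core must leave while an
            # all-ether partner stays behind
            partner_all_ether = any(
                c.ether_count == len(c.chains)
                for j, c in enumerate(species.cores) if j != i
            )
            hint = "low" if (core_has_acyl and partner_all_ether) else "high"
            desc = f"loss of {core.core_class} C{core.n_carbons} core"
            # R2: radylglycerol loss
            add(_loss(lost, "R2", hint, desc))
            r2_ion = prec - lost
            add(_ion(r2_ion, "R2", hint, f"precursor minus {core.core_class} C{core.n_carbons}"))
            # R3: further HPO3 loss from the R2 ion
            add(_loss(lost + HPO3, "R3", hint, desc + " + HPO3"))
            add(_ion(r2_ion - HPO3, "R3", hint, "remaining core with PG moiety"))

        # R4: PGP head-group ions
        add(_ion(GLYCEROPHOSPHATE_ION, "R4", desc="glycerophosphate"))
        add(_ion(GLYCERODIPHOSPHATE_ION, "R4", desc="glycerodiphosphate"))

        # R5: one ion per distinct ether chain
        for ch in species.chains:
            if ch.linkage == "ether":
                n, u = ch.n_carbons, ch.n_unsat
                f = ElementalFormula(C=n + 3, H=2 * n + 7 - 2 * u, O=1)
                add(_ion(f, "R5", desc=f"alkyl C{n} glycerol-remnant ion"))

    elif hg in ("PE", "PG"):
        if pe_pg_rules:
            for ch in species.chains:
                n, u = ch.n_carbons, ch.n_unsat
                if ch.linkage == "ester":
                    fa = ElementalFormula(C=n, H=2 * n - 2 * u, O=2)
                    ketene = ElementalFormula(C=n, H=2 * n - 2 - 2 * u, O=1)
                    for lost, what in ((fa, "fatty acid"), (ketene, "ketene")):
                        if prec.contains(lost):
                            add(_loss(lost, "R6", desc=f"{what} C{n}:{u} (extrapolated)"))
                            add(_ion(prec - lost, "R6", desc=f"loss of {what} C{n}:{u} (extrapolated)"))
                else:
                    f = ElementalFormula(C=n + 3, H=2 * n + 7 - 2 * u, O=1)
                    add(_ion(f, "R6", desc=f"alkyl C{n} glycerol-remnant ion (extrapolated)"))
    elif hg is None:
        # free glycerides: Table 2-style monoether fragments under [M+NH4]+
        for ch in species.chains:
            if ch.linkage == "ether":
                n, u = ch.n_carbons, ch.n_unsat
                # monoradylglycerol minus OH, as protonated dehydrated species
                f = ElementalFormula(C=n + 3, H=2 * n + 7 - 2 * u, O=3)
                add(_ion(f, "G1", desc=f"glycerol monoether C{n} fragment"))
    else:  # pragma: no cover - guarded by LipidSpecies validation
        raise ValueError(f"unsupported class {hg!r}")

    # structural invariant: every ion is contained in the precursor ion
    for e in entries:
        if e.kind == "ion" and not prec.contains(e.formula):
            raise AssertionError(f"ion {e.formula} exceeds precursor {prec}")

    return FragmentSet(species, adduct, prec, prec_mz, tuple(entries))


def explain_peak(
    observed_mz: float, fs: FragmentSet, tol_ppm: float = 5.0
) -> list[FragmentEntry]:
    """All ion entries whose theoretical m/z lies within ``tol_ppm``."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    return [
        e for e in fs.ions()
        if abs(ppm_error(observed_mz, e.mz)) <= tol_ppm
    ]
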