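"""Structural model of ether/ester glycerophospholipids and cardiolipins.

The lipidome modelled here is that of an anaerobic sulfate-reducing
bacterium whose membranes mix ether-bound alkyl and ester-bound acyl chains
on the same glycerol cores: mono-/di-alkyl and -acyl glycerols (MEG/MAG,
DEG/AEG/DAG) carrying PE or PG head groups, and cardiolipins (CDLs) built
from two such cores around a central glycerol — including the fully
ether-linked tetraether CDLs and their mono-/dilyso forms.

Chain-count convention: an acyl chain of *n* carbons includes its carbonyl
carbon, so an ether↔ester substitution at fixed *n* preserves the total
carbon number and changes the neutral formula by −2H +1O (+13.9793 Da).

Neutral formulas are assembled from head-group scaffold constants plus
per-chain substituent contributions:

====================  ============  =====================================
scaffold              formula       contains
====================  ============  =====================================
free glyceride        C3H8O3        glycerol
PE                    C5H14NO6P     glycerol + phosphoethanolamine
PG                    C6H15O8P      glycerol + phosphoglycerol
CDL family            C9H22O13P2    3 glycerols + 2 phosphodiesters
====================  ============  =====================================

plus, per chain of *n* carbons with *u* double-bond equivalents:
ether +CnH(2n−2u), acyl +CnH(2n−2−2u)O.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

from .formula import ElementalFormula, parse_formula

__all__ = [
    "RadylChain",
    "CoreLipid",
    "LipidSpecies",
    "build_species",
    "enumerate_cores",
    "enumerate_species",
    "species_label",
    "parse_label",
    "DEFAULT_CHAIN_LENGTHS",
    "ETHER_ESTER_DELTA",
]

Linkage = Literal["ether", "ester"]

DEFAULT_CHAIN_LENGTHS: tuple[int, ...] = (14, 15, 16, 17)

SCAFFOLDS: dict[Optional[str], ElementalFormula] = {
    None: parse_formula("C3H8O3"),
    "PE": parse_formula("C5H14NO6P"),
    "PG": parse_formula("C6H15O8P"),
    "CDL": parse_formula("C3H9O8P2") + parse_formula("C6H13O5"),  # C9H22O13P2
}

# ether↔ester substitution at fixed chain length: −2H +1O, +13.9793 Da
ETHER_ESTER_DELTA = 13.97926456


@dataclass(frozen=True)
class RadylChain:
    """One glycerol-bound chain: ether-linked alkyl or ester-linked acyl.

    ``branch_note`` is a mass-neutral annotation (e.g. "10-Me" for
    methyl-branched chains inferred from GC–MS of hydrolysed cores); it
    never alters the formula.  ``sn_position`` is likewise metadata: MS
    cannot distinguish sn-1 from sn-2.
    """

    n_carbons: int
    linkage: Linkage = "ether"
    sn_position: Optional[int] = None
    n_unsat: int = 0
    branch_note: Optional[str] = field(default=None, compare=False)

    def __post_init__(self):
        if self.n_carbons < 1:
            raise ValueError("chain needs at least one carbon")
        if self.linkage not in ("ether", "ester"):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.n_unsat < 0:
            raise ValueError("negative unsaturation")

    @property
    def formula(self) -> ElementalFormula:
        n, u = self.n_carbons, self.n_unsat
        if self.linkage == "ether":
            return ElementalFormula(C=n, H=2 * n - 2 * u)
        return ElementalFormula(C=n, H=2 * n - 2 - 2 * u, O=1)

    @property
    def token(self) -> str:
        t = ("e" if self.linkage == "ether" else "a") + str(self.n_carbons)
        if self.n_unsat:
            t += f":{self.n_unsat}"
        return t


_CORE_CLASS = {
    ("ether", "ether"): "DEG",
    ("ether", "ester"): "AEG",
    ("ester", "ester"): "DAG",
    ("ether",): "MEG",
    ("ester",): "MAG",
}


@dataclass(frozen=True)
class CoreLipid:
    """A glycerol core carrying one (lyso) or two radyl chains."""

    chains: tuple[RadylChain, ...]

    def __post_init__(self):
        if len(self.chains) not in (1, 2):
            raise ValueError("core lipids carry 1 or 2 chains")

    @property
    def core_class(self) -> str:
        key = tuple(sorted((c.linkage for c in self.chains), reverse=False))
        # canonical order ether before ester
        key = tuple(sorted(key, key=lambda x: x != "ether"))
        return _CORE_CLASS[key]

    @property
    def ether_count(self) -> int:
        return sum(c.linkage == "ether" for c in self.chains)

    @property
    def n_carbons(self) -> int:
        return sum(c.n_carbons for c in self.chains)

    @property
    def n_unsat(self) -> int:
        return sum(c.n_unsat for c in self.chains)

    @property
    def formula(self) -> ElementalFormula:
        """Neutral formula of the free (di)radylglycerol — also the
        diagnostic neutral-loss formula of this core in CDL MS²."""
        f = SCAFFOLDS[None]
        for c in self.chains:
            f = f + c.formula
        return f

    @property
    def token(self) -> str:
        return "/".join(c.token for c in self.chains)

    def sort_key(self):
        return (-self.n_carbons, -self.ether_count, self.token)


@dataclass(frozen=True)
class LipidSpecies:
    """A phospholipid (or free glyceride) with a derived neutral formula.

    ``head_group`` ∈ {None, "PE", "PG", "CDL"}; lyso state is derived from
    the chain count.  A dilyso-CDL occurs in two mass-isomeric structural
    variants: two single-chain cores ("two-monolyso-cores") or one intact
    two-chain core with a bare phosphatidylglycerophosphate arm
    ("intact-core+pgp").
    """

    head_group: Optional[str]
    cores: tuple[CoreLipid, ...]
    dilyso_variant: Optional[str] = None

    def __post_init__(self):
        hg = self.head_group
        nch = [len(c.chains) for c in self.cores]
        if hg in ("PE", "PG"):
            if len(self.cores) != 1:
                raise ValueError(f"{hg} carries exactly one core")
        elif hg == "CDL":
            if self.dilyso_variant == "intact-core+pgp":
                if nch != [2]:
                    raise ValueError("intact-core+pgp variant needs one 2-chain core")
            elif sorted(nch, reverse=True) not in ([2, 2], [2, 1], [1, 1]):
                raise ValueError(f"invalid CDL core arity {nch}")
            if self.dilyso_variant == "two-monolyso-cores" and nch != [1, 1]:
                raise ValueError("two-monolyso-cores variant needs two 1-chain cores")
        elif hg is None:
            if len(self.cores) != 1:
                raise ValueError("free glyceride is a single core")
        else:
            raise ValueError(f"unknown head group {hg!r}")

    # -- derived quantities -------------------------------------------
    @property
    def chains(self) -> tuple[RadylChain, ...]:
        return tuple(c for core in self.cores for c in core.chains)

    @property
    def total_carbons(self) -> int:
        return sum(c.n_carbons for c in self.chains)

    @property
    def total_unsat(self) -> int:
        return sum(c.n_unsat for c in self.chains)

    @property
    def total_ethers(self) -> int:
        return sum(c.linkage == "ether" for c in self.chains)

    @property
    def lyso_count(self) -> int:
        full = 4 if self.head_group == "CDL" else 2
        if self.head_group is None:
            return 0
        return full - len(self.chains)

    @property
    def neutral_formula(self) -> ElementalFormula:
        f = SCAFFOLDS[self.head_group]
        for c in self.chains:
            f = f + c.formula
        return f

    @property
    def class_token(self) -> str:
        hg = self.head_group
        if hg is None:
            return self.cores[0].core_class
        if hg in ("PE", "PG"):
            return ("L" + hg) if self.lyso_count else hg
        return {0: "CDL", 1: "MLCL", 2: "DLCL"}[self.lyso_count]

    @property
    def species_key(self) -> str:
        """Species-level identity (no chain splits): class, C:U, ether count."""
        return f"{self.class_token} {self.total_carbons}:{self.total_unsat};e{self.total_ethers}"

    @property
    def label(self) -> str:
        return species_label(self)


def species_label(s: LipidSpecies, level: str = "molecular") -> str:
    """Canonical text label, e.g. ``"CDL 64:0;e4 [e17/e16 | e17/e14]"``.

    ``level="species"`` drops the chain-split detail.  Labelling is
    deterministic and round-trips through :func:`parse_label`.
    """
    if level == "species":
        return s.species_key
    cores = " | ".join(c.token for c in s.cores)
    if s.dilyso_variant == "intact-core+pgp":
        cores += " | -"
    return f"{s.species_key} [{cores}]"


_LABEL_RE = re.compile(
    r"^(?P<cls>[A-Z]+)\s+(?P<c>\d+):(?P<u>\d+);e(?P<e>\d+)(?:\s+\[(?P<cores>.+)\])?$"
)
_CHAIN_RE = re.compile(r"^([ea])(\d+)(?::(\d+))?$")

_CLS_TO_HEAD = {
    "PE": "PE", "LPE": "PE", "PG": "PG", "LPG": "PG",
    "CDL": "CDL", "MLCL": "CDL", "DLCL": "CDL",
    "DEG": None, "AEG": None, "DAG": None, "MEG": None, "MAG": None,
}


def parse_label(text: str) -> LipidSpecies:
    """Inverse of :func:`species_label` (molecular level only)."""
    m = _LABEL_RE.match(text.strip())
    if not m or m.group("cores") is None:
        raise ValueError(f"unparseable species label {text!r}")
    cls = m.group("cls")
    if cls not in _CLS_TO_HEAD:
        raise ValueError(f"unknown class token {cls!r} in {text!r}")
    head = _CLS_TO_HEAD[cls]
    core_tokens = [t.strip() for t in m.group("cores").split("|")]
    variant = None
    if core_tokens and core_tokens[-1] == "-":
        core_tokens = core_tokens[:-1]
        variant = "intact-core+pgp"
    cores = []
    for tok in core_tokens:
        chains = []
        for ct in tok.split("/"):
            cm = _CHAIN_RE.match(ct.strip())
            if not cm:
                raise ValueError(f"bad chain token {ct!r} in {text!r}")
            chains.append(
                RadylChain(
                    n_carbons=int(cm.group(2)),
                    linkage="ether" if cm.group(1) == "e" else "ester",
                    n_unsat=int(cm.group(3) or 0),
                )
            )
        cores.append(CoreLipid(tuple(chains)))
    if cls == "DLCL" and variant is None:
        variant = "two-monolyso-cores"
    sp = LipidSpecies(head, tuple(cores), dilyso_variant=variant)
    if (sp.total_carbons, sp.total_unsat, sp.total_ethers) != (
        int(m.group("c")), int(m.group("u")), int(m.group("e"))
    ):
        raise ValueError(f"label summary disagrees with chain detail: {text!r}")
    return sp


def build_species(
    head_group: Optional[str],
    cores: Sequence[CoreLipid] | Sequence[Sequence[RadylChain]],
    dilyso_variant: Optional[str] = None,
) -> LipidSpecies:
    """Validate arity and assemble a :class:`LipidSpecies`.

    Cores may be given as :class:`CoreLipid` or as bare chain sequences.
    CDL-family cores are put in canonical order (larger core first).
    """
    built = tuple(
        c if isinstance(c, CoreLipid) else CoreLipid(tuple(c)) for c in cores
    )
    if head_group == "CDL" and len(built) == 2:
        built = tuple(sorted(built, key=CoreLipid.sort_key))
    if head_group == "CDL" and dilyso_variant is None:
        if [len(c.chains) for c in built] == [1, 1]:
            dilyso_variant = "two-monolyso-cores"
    return LipidSpecies(head_group, built, dilyso_variant=dilyso_variant)


# ---------------------------------------------------------------------
# Enumeration


def _canonical_chain_order(chains: Sequence[RadylChain]) -> tuple[RadylChain, ...]:
    """Assign sn positions by the strain's convention: the methyl-branched
    (odd-carbon) chain sits at sn-1; ties broken longer-first, ether-first."""
    ordered = sorted(
        chains,
        key=lambda c: (c.n_carbons % 2 == 0, -c.n_carbons, c.linkage != "ether"),
    )
    return tuple(
        replace(c, sn_position=i + 1) for i, c in enumerate(ordered)
    )


def _make_chain(n: int, linkage: Linkage, u: int) -> RadylChain:
    note = "10-Me" if n % 2 == 1 else None
    return RadylChain(n_carbons=n, linkage=linkage, n_unsat=u, branch_note=note)


def enumerate_cores(
    chain_lengths: Iterable[int] = DEFAULT_CHAIN_LENGTHS,
    n_chains: int = 2,
    unsat: Iterable[int] = (0,),
    linkages: Iterable[Linkage] = ("ether", "ester"),
    ordered: bool = False,
) -> list[CoreLipid]:
    """All glycerol cores over the given chain space.

    With ``ordered=True`` every (sn-1, sn-2) permutation is emitted
    (4 lengths → 16 DEG combinations); by default chains are reduced to the
    canonical sn assignment, so each chain multiset appears once.
    """
    lengths = sorted(set(chain_lengths))
    us = sorted(set(unsat))
    singles = [
        _make_chain(n, lk, u)
        for n in lengths for lk in linkages for u in us
    ]
    if n_chains == 1:
        return [CoreLipid((replace(c, sn_position=1),)) for c in singles]
    if n_chains != 2:
        raise ValueError("cores carry 1 or 2 chains")
    out, seen = [], set()
    for a, b in itertools.product(singles, repeat=2):
        pair = (a, b) if ordered else _canonical_chain_order((a, b))
        core = CoreLipid(
            tuple(replace(c, sn_position=i + 1) for i, c in enumerate(pair))
        )
        key = core.token if not ordered else (a.token, b.token)
        if key in seen:
            continue
        seen.add(key)
        out.append(core)
    return out


def enumerate_species(
    head_groups: Iterable[str] = ("PE", "PG", "CDL", "MLCL", "DLCL", "LPE", "LPG"),
    chain_lengths: Iterable[int] = DEFAULT_CHAIN_LENGTHS,
    ether_counts: Optional[Iterable[int]] = None,
    unsat: Iterable[int] = (0,),
) -> list[LipidSpecies]:
    """Exhaustive, duplicate-free species list over the configured space.

    ``head_groups`` uses class tokens (CDL, MLCL = monolyso-CDL, DLCL =
    dilyso-CDL, LPE/LPG = lyso-PE/PG, and DEG/AEG/DAG/MEG/MAG for free
    glycerides).  ``ether_counts`` filters on the species' total number of
    ether bonds.  Mass-degenerate but structurally distinct species (chain
    splits, the two dilyso variants) are distinct entries sharing a formula.
    """
    efilter = None if ether_counts is None else set(ether_counts)
    duos = enumerate_cores(chain_lengths, 2, unsat)
    monos = enumerate_cores(chain_lengths, 1, unsat)
    out: list[LipidSpecies] = []

    def keep(sp: LipidSpecies) -> bool:
        return efilter is None or sp.total_ethers in efilter

    for hg in head_groups:
        if hg in ("PE", "PG"):
            cand = (LipidSpecies(hg, (c,)) for c in duos)
        elif hg in ("LPE", "LPG"):
            cand = (LipidSpecies(hg[1:], (c,)) for c in monos)
        elif hg == "CDL":
            cand = (
                build_species("CDL", pair)
                for pair in itertools.combinations_with_replacement(duos, 2)
            )
        elif hg == "MLCL":
            cand = (
                build_species("CDL", (d, m))
                for d in duos for m in monos
            )
        elif hg == "DLCL":
            cand = itertools.chain(
                (
                    build_species("CDL", pair, "two-monolyso-cores")
                    for pair in itertools.combinations_with_replacement(monos, 2)
                ),
                (
                    build_species("CDL", (d,), "intact-core+pgp")
                    for d in duos
                ),
            )
        elif hg in ("DEG", "AEG", "DAG"):
            cand = (
                LipidSpecies(None, (c,))
                for c in duos if c.core_class == hg
            )
        elif hg in ("MEG", "MAG"):
            cand = (
                LipidSpecies(None, (c,))
                for c in monos if c.core_class == hg
            )
        else:
            raise ValueError(f"unknown head-group token {hg!r}")
        out.extend(sp for sp in cand if keep(sp))

    # duplicate-free by construction, but guard against regressions
    labels = [species_label(s) for s in out]
    assert len(labels) == len(set(labels)), "duplicate species enumerated"
    return out
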