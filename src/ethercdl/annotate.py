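"""ppm-tolerance assignment of lipid species to MS¹ features and MS² spectra.

Candidates are drawn from an enumerated species×adduct index by exact-mass
match of the precursor (default 3 ppm), then scored by the number of
predicted diagnostic MS² ions found in the spectrum (default 5 ppm).  Chain
splits are claimed only when fragment evidence pins them; mass-degenerate
candidates that the evidence cannot separate are reported together as an
isomer set — exactly the situation of co-trapped structural isomers in the
source data.  Retention-time ordering (more ether bonds elute earlier at
fixed class and carbon number) is available as a post-hoc consistency
check, never as a scoring term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .formula import ADDUCTS, Adduct, MassMatch, monoisotopic_mass, ppm_error
from .fragments import FragmentEntry, FragmentSet, predict_fragments
from .lipids import LipidSpecies

__all__ = [
    "Peak",
    "Spectrum",
    "SpeciesIndex",
    "AnnotationCandidate",
    "Annotation",
    "match_precursor",
    "annotate_spectrum",
    "annotate_feature_table",
    "link_isotope_features",
    "check_rt_ordering",
    "DEFAULT_INDEX_ADDUCTS",
]

# adducts considered when matching precursor/feature masses, per class token
DEFAULT_INDEX_ADDUCTS: dict[str, tuple[str, ...]] = {
    "PE": ("[M+H]+", "[M+NH4]+"),
    "PG": ("[M+H]+", "[M+NH4]+"),
    "LPE": ("[M+H]+", "[M+NH4]+"),
    "LPG": ("[M+H]+", "[M+NH4]+"),
    "CDL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+"),
    "MLCL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+"),
    "DLCL": ("[M+H]+", "[M+H-H2O]+", "[M+NH4]+", "[M+Na]+"),
    "DEG": ("[M+NH4]+",), "AEG": ("[M+NH4]+",), "DAG": ("[M+NH4]+",),
    "MEG": ("[M+NH4]+",), "MAG": ("[M+NH4]+",),
}


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float = 1.0

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class Spectrum:
    """A centroided spectrum; peaks are kept sorted by m/z and unique."""

    peaks: tuple[Peak, ...]
    precursor_mz: Optional[float] = None
    retention_time: Optional[float] = None  # minutes
    level: int = 2
    title: str = ""

    def __post_init__(self):
        ordered = tuple(sorted(self.peaks, key=lambda p: p.mz))
        dedup: list[Peak] = []
        for p in ordered:
            if dedup and p.mz == dedup[-1].mz:
                dedup[-1] = Peak(p.mz, dedup[-1].intensity + p.intensity)
            else:
                dedup.append(p)
        object.__setattr__(self, "peaks", tuple(dedup))

    @property
    def mz_array(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity_array(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])


class SpeciesIndex:
    """Sorted (theoretical m/z → species, adduct) lookup over a species list."""

    def __init__(
        self,
        species: Sequence[LipidSpecies],
        adducts_by_class: Optional[dict[str, tuple[str, ...]]] = None,
    ):
        if not species:
            raise ValueError("empty species index")
        amap = adducts_by_class or DEFAULT_INDEX_ADDUCTS
        rows = []
        for sp in species:
            for aname in amap.get(sp.class_token, ("[M+H]+",)):
                add = ADDUCTS[aname]
                rows.append((add.mz(sp.neutral_formula), sp, add))
        rows.sort(key=lambda r: r[0])
        self._mz = np.array([r[0] for r in rows])
        self._entries: list[tuple[LipidSpecies, Adduct]] = [(r[1], r[2]) for r in rows]
        self.species = list(species)
        self._fragment_cache: dict[tuple[str, str], FragmentSet] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def match_precursor(
        self, mz: float, tol_ppm: float = 3.0
    ) -> list[tuple[LipidSpecies, Adduct, MassMatch]]:
        """All (species, adduct) within ``tol_ppm``, sorted by |Δppm|."""
        half = mz * tol_ppm * 1e-6
        lo = np.searchsorted(self._mz, mz - half, side="left")
        hi = np.searchsorted(self._mz, mz + half, side="right")
        out = [
            (sp, add, MassMatch(mz, theo))
            for theo, (sp, add) in zip(
                self._mz[lo:hi], self._entries[lo:hi]
            )
        ]
        out.sort(key=lambda r: (abs(r[2].delta_ppm), r[0].label, r[1].name))
        return out

    def fragments_for(self, sp: LipidSpecies, adduct: Adduct) -> Optional[FragmentSet]:
        key = (sp.label, adduct.name)
        if key not in self._fragment_cache:
            try:
                self._fragment_cache[key] = predict_fragments(sp, adduct)
            except ValueError:
                # class/adduct pairing without an MS² rule set
                self._fragment_cache[key] = None
        return self._fragment_cache[key]


def match_precursor(
    mz: float,
    index: SpeciesIndex,
    tol_ppm: float = 3.0,
) -> list[tuple[LipidSpecies, Adduct, MassMatch]]:
    """Module-level convenience over :meth:`SpeciesIndex.match_precursor`."""
    return index.match_precursor(mz, tol_ppm)


@dataclass(frozen=True)
class AnnotationCandidate:
    species: LipidSpecies
    adduct: Adduct
    precursor_match: MassMatch
    matched_entries: tuple[FragmentEntry, ...] = ()

    @property
    def score(self) -> int:
        return len(self.matched_entries)

    @property
    def sn_violations(self) -> int:
        """Avoidable breaches of the branched-chain-at-sn-1 convention.

        A core with two odd (methyl-branched) chains must place one at
        sn-2; only the excess over that forced minimum counts, so species
        are never penalized for their chain composition itself.
        """
        n = 0
        for core in self.species.cores:
            odd_at_sn2 = sum(
                1 for ch in core.chains
                if ch.n_carbons % 2 == 1 and ch.sn_position == 2
            )
            n_odd = sum(1 for ch in core.chains if ch.n_carbons % 2 == 1)
            forced = max(0, n_odd - (len(core.chains) - 1))
            n += max(0, odd_at_sn2 - forced)
        return n

    def sort_key(self):
        return (
            -self.score,
            self.sn_violations,
            round(abs(self.precursor_match.delta_ppm), 4),
        )


@dataclass(frozen=True)
class Annotation:
    """Ranked candidate species for one spectrum."""

    spectrum: Spectrum
    candidates: tuple[AnnotationCandidate, ...]
    status: Literal["unambiguous", "isomer_set", "unassigned"]

    @property
    def top(self) -> Optional[AnnotationCandidate]:
        return self.candidates[0] if self.candidates else None

    @property
    def top_group(self) -> tuple[AnnotationCandidate, ...]:
        """All candidates tied with the best after score and tie-breaks
        (competition rank 1); an isomer set when longer than one."""
        if not self.candidates:
            return ()
        best = self.candidates[0].sort_key()
        return tuple(c for c in self.candidates if c.sort_key() == best)

    def rank_of(self, species: LipidSpecies | str) -> Optional[int]:
        """Competition rank of a species (1 = member of the top tie group)."""
        label = species if isinstance(species, str) else species.label
        keys = sorted({c.sort_key() for c in self.candidates})
        for c in self.candidates:
            if c.species.label == label:
                return keys.index(c.sort_key()) + 1
        return None

    @property
    def species_key(self) -> Optional[str]:
        """Species-level call, when the whole top group agrees on it."""
        keys = {c.species.species_key for c in self.top_group}
        return keys.pop() if len(keys) == 1 else None

    @property
    def claim_level(self) -> Optional[str]:
        if not self.candidates:
            return None
        if len(self.top_group) == 1:
            return "molecular"
        return "species" if self.species_key else "ambiguous"


def annotate_spectrum(
    spectrum: Spectrum,
    index: SpeciesIndex,
    tol_ppm_ms1: float = 3.0,
    tol_ppm_ms2: float = 5.0,
) -> Annotation:
    """Annotate one MS² spectrum (or precursor-only feature spectrum).

    Candidates within ``tol_ppm_ms1`` of the precursor are scored by the
    count of predicted diagnostic ions present within ``tol_ppm_ms2``; ties
    are broken by sn-convention violations then precursor |Δppm|, and
    remaining ties form an isomer set.
    """
    if spectrum.precursor_mz is None:
        raise ValueError("spectrum has no precursor m/z")
    hits = index.match_precursor(spectrum.precursor_mz, tol_ppm_ms1)
    mz = spectrum.mz_array
    cands = []
    for sp, add, match in hits:
        fs = index.fragments_for(sp, add)
        matched: tuple[FragmentEntry, ...] = ()
        if fs is not None and len(mz):
            matched = tuple(
                e for e in fs.ions()
                if np.any(np.abs(mz - e.mz) <= e.mz * tol_ppm_ms2 * 1e-6)
            )
        cands.append(AnnotationCandidate(sp, add, match, matched))
    cands.sort(key=lambda c: (c.sort_key(), c.species.label, c.adduct.name))
    if not cands:
        return Annotation(spectrum, (), "unassigned")
    best = cands[0].sort_key()
    top = [c for c in cands if c.sort_key() == best]
    status = "unambiguous" if len(top) == 1 else "isomer_set"
    return Annotation(spectrum, tuple(cands), status)


def annotate_feature_table(
    features: pd.DataFrame,
    index: SpeciesIndex,
    tol_ppm: float = 3.0,
    mz_column: str = "mz",
) -> pd.DataFrame:
    """Annotate an MS¹ feature table by precursor mass alone.

    Returns a copy with ``label``, ``species_key``, ``adduct``, ``ppm``,
    ``status`` and ``n_candidates`` columns; chain-split ambiguity that
    leaves the species-level call intact is still reported as that call.
    """
    rows = []
    for _, feat in features.iterrows():
        hits = index.match_precursor(float(feat[mz_column]), tol_ppm)
        rec = dict(feat)
        if not hits:
            rec.update(label=None, species_key=None, adduct=None, ppm=np.nan,
                       status="unassigned", n_candidates=0)
        else:
            best_ppm = round(abs(hits[0][2].delta_ppm), 4)
            top = [h for h in hits if round(abs(h[2].delta_ppm), 4) == best_ppm]
            keys = {sp.species_key for sp, _, _ in top}
            sp, add, match = top[0]
            rec.update(
                label=sp.label,
                species_key=sp.species_key if len(keys) == 1 else None,
                adduct=add.name,
                ppm=match.delta_ppm,
                status="unambiguous" if len(top) == 1 else "isomer_set",
                n_candidates=len(hits),
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def link_isotope_features(
    annotated: pd.DataFrame,
    tol_ppm: float = 3.0,
    mz_column: str = "mz",
    shift: float = 1.00335484,
) -> pd.DataFrame:
    """Attach unassigned features to the ¹³C M+1 channel of an assigned
    [M+H]+ feature one isotope spacing below (CDL-family species only).

    Returns a copy where matched rows get that species' label with adduct
    ``"M+1"``.
    """
    df = annotated.copy()
    assigned = df[
        df["label"].notna() & (df["adduct"] == "[M+H]+")
    ]
    cdl_assigned = assigned[
        assigned["label"].str.match(r"^(CDL|MLCL|DLCL)\b")
    ]
    base_mz = cdl_assigned[mz_column].to_numpy()
    order = np.argsort(base_mz)
    base_mz = base_mz[order]
    base_idx = cdl_assigned.index.to_numpy()[order]
    for i in df.index[df["label"].isna()]:
        target = df.at[i, mz_column] - shift
        half = abs(target) * tol_ppm * 1e-6
        lo = np.searchsorted(base_mz, target - half)
        hi = np.searchsorted(base_mz, target + half)
        if lo < hi:
            j = base_idx[lo + int(np.argmin(np.abs(base_mz[lo:hi] - target)))]
            df.at[i, "label"] = df.at[j, "label"]
            df.at[i, "species_key"] = df.at[j, "species_key"]
            df.at[i, "adduct"] = "M+1"
            df.at[i, "status"] = df.at[j, "status"]
    return df


def check_rt_ordering(
    features: Iterable[tuple[LipidSpecies | str, float]],
) -> list[dict]:
    """Flag pairs violating "more ether bonds elute earlier".

    ``features`` is (species or molecular label, retention time in minutes).
    Within each (class, total carbons, unsaturation) group, a pair where the
    member with more ether bonds elutes *later* is a violation.
    """
    from .lipids import parse_label

    parsed = []
    for sp, rt in features:
        if isinstance(sp, str):
            sp = parse_label(sp)
        parsed.append((sp, float(rt)))
    violations = []
    groups: dict[tuple, list] = {}
    for sp, rt in parsed:
        groups.setdefault(
            (sp.class_token, sp.total_carbons, sp.total_unsat), []
        ).append((sp, rt))
    for key, members in groups.items():
        for i, (a, rt_a) in enumerate(members):
            for b, rt_b in members[i + 1:]:
                if a.total_ethers == b.total_ethers:
                    continue
                hi, lo = ((a, rt_a), (b, rt_b))
                if b.total_ethers > a.total_ethers:
                    hi, lo = lo, hi
                if hi[1] > lo[1]:
                    violations.append(
                        dict(
                            group=key,
                            more_ethers=hi[0].label, rt_more=hi[1],
                            fewer_ethers=lo[0].label, rt_fewer=lo[1],
                        )
                    )
    return violations
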