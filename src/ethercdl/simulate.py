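"""Seedable ground-truth lipidome and MS¹/MS² peak-list simulator.

The generator emulates the membrane lipidome of an anaerobic
sulfate-reducing bacterium rich in ether lipids: PE, PG and CDL classes of
roughly equal share plus minor lyso classes, saturated C14–C17 chains
(odd-numbered chains annotated as 10-methyl-branched), 0–4 ether bonds per
species, and a CDL ether-class profile matching the measured one
(tetraester→tetraether 9/12/28/18/33%).  Mass accuracy is modelled as
multiplicative (ppm-scaled) Gaussian noise, the way instrument accuracy is
specified; decoy peaks are uniform in m/z with no chemical structure.

Each species' total signal is split across its class's quantification
adduct channels with fixed shares summing to one (the ¹³C M+1 trace is
carved out of the [M+H]+ channel at its theoretical ratio), so that in the
noiseless limit the simulate → annotate → quantify round trip recovers the
ground-truth composition exactly under the default summing policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import Peak, Spectrum
from .formula import ADDUCTS, m1_ratio, monoisotopic_mass
from .fragments import predict_fragments
from .lipids import LipidSpecies, enumerate_species, parse_label
from .quantify import DEFAULT_ADDUCT_POLICY

__all__ = [
    "LipidomeProfile",
    "NoiseModel",
    "simulate_lipidome",
    "simulate_spectra",
    "C13_MASS_SHIFT",
    "retention_time_model",
]

C13_MASS_SHIFT = 1.00335484  # 13C − 12C, Da


def _norm(weights: dict) -> dict:
    total = float(sum(weights.values()))
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return {k: v / total for k, v in weights.items()}


@dataclass
class LipidomeProfile:
    """Ground-truth composition the simulator draws from.

    Defaults follow the measured strain composition where one was reported
    (class thirds, PE/PG core-class percentages, the CDL ether-class
    profile); the chain-length weights are a generator choice tuned to put
    the bulk of two-chain cores at 31, 33 and 30 total carbons.
    """

    class_fractions: dict = field(default_factory=lambda: {
        "PE": 0.30, "PG": 0.29, "CDL": 0.27,
        "MLCL": 0.04, "DLCL": 0.02, "LPE": 0.05, "LPG": 0.03,
    })
    # tetraester (e0) → tetraether (e4), measured CDL profile
    cdl_ether_weights: Sequence[float] = (0.09, 0.12, 0.28, 0.18, 0.33)
    mlcl_ether_weights: Sequence[float] = (0.05, 0.15, 0.35, 0.45)
    dlcl_ether_weights: Sequence[float] = (0.10, 0.35, 0.55)
    # measured intact-core percentages (DAG/AEG/DEG) per head group
    pe_core_weights: dict = field(default_factory=lambda: {
        "DAG": 54.0, "AEG": 7.5, "DEG": 25.0})
    pg_core_weights: dict = field(default_factory=lambda: {
        "DAG": 9.3, "AEG": 17.0, "DEG": 66.2})
    # lyso cores: MEG dominates in both classes, MAG-PG not detected
    lpe_core_weights: dict = field(default_factory=lambda: {"MEG": 13.5, "MAG": 0.2})
    lpg_core_weights: dict = field(default_factory=lambda: {"MEG": 7.4, "MAG": 0.0})
    chain_weights: dict = field(default_factory=lambda: {
        14: 0.35, 15: 0.07, 16: 0.25, 17: 0.33})
    chain_lengths: tuple[int, ...] = (14, 15, 16, 17)
    n_species: Optional[int] = None  # None = every enumerated species
    abundance_cv: float = 0.3

    def ether_weights_for(self, cls: str) -> dict[int, float]:
        if cls == "CDL":
            w = dict(enumerate(self.cdl_ether_weights))
        elif cls == "MLCL":
            w = dict(enumerate(self.mlcl_ether_weights))
        elif cls == "DLCL":
            w = dict(enumerate(self.dlcl_ether_weights))
        elif cls in ("PE", "PG"):
            cw = self.pe_core_weights if cls == "PE" else self.pg_core_weights
            w = {0: cw.get("DAG", 0), 1: cw.get("AEG", 0), 2: cw.get("DEG", 0)}
        elif cls in ("LPE", "LPG"):
            cw = self.lpe_core_weights if cls == "LPE" else self.lpg_core_weights
            w = {0: cw.get("MAG", 0), 1: cw.get("MEG", 0)}
        else:
            raise ValueError(f"no ether weights for class {cls!r}")
        return {e: v for e, v in _norm(w).items() if v > 0}


@dataclass
class NoiseModel:
    """Instrument imperfections applied to simulated peak lists."""

    ppm_sigma: float = 1.0
    intensity_cv: float = 0.1
    decoy_rate: float = 0.1          # decoy peaks per real MS² peak
    isotope_peaks: bool = True       # emit the 13C M+1 channel for CDLs
    co_isolation_window_da: float = 1.0
    rt_sigma_min: float = 0.02

    def __post_init__(self):
        for name in ("ppm_sigma", "intensity_cv", "decoy_rate",
                     "co_isolation_window_da", "rt_sigma_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative jitter with unit mean and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1 + cv * cv))
    return rng.lognormal(mean=-sigma * sigma / 2, sigma=sigma, size=size)


def simulate_lipidome(
    profile: LipidomeProfile | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw a ground-truth abundance table over the enumerated species space.

    Within each class, abundance mass is allocated by the class's
    ether-class weights and, within an ether class, by the product of the
    chain-length weights, then jittered log-normally and renormalized to
    100%.  Fixed seed → identical table.
    """
    profile = profile or LipidomeProfile()
    rng = np.random.default_rng(seed)
    classes = {c: f for c, f in _norm(profile.class_fractions).items() if f > 0}
    species = enumerate_species(
        head_groups=tuple(classes), chain_lengths=profile.chain_lengths
    )
    cw = _norm(profile.chain_weights)

    rows = []
    for cls, cfrac in classes.items():
        ew = profile.ether_weights_for(cls)
        members: dict[int, list[tuple[LipidSpecies, float]]] = {}
        for sp in species:
            if sp.class_token != cls or sp.total_ethers not in ew:
                continue
            w = 1.0
            for ch in sp.chains:
                w *= cw.get(ch.n_carbons, 0.0)
            if w > 0:
                members.setdefault(sp.total_ethers, []).append((sp, w))
        for e, group in members.items():
            wsum = sum(w for _, w in group)
            for sp, w in group:
                rows.append(dict(
                    species=sp.label,
                    species_key=sp.species_key,
                    class_token=cls,
                    total_carbons=sp.total_carbons,
                    total_unsat=sp.total_unsat,
                    total_ethers=e,
                    abundance=cfrac * ew[e] * w / wsum,
                ))
    truth = pd.DataFrame(rows)
    if profile.n_species is not None and profile.n_species < len(truth):
        truth = truth.nlargest(profile.n_species, "abundance").reset_index(drop=True)
    truth["abundance"] *= _lognormal_factor(rng, profile.abundance_cv, len(truth))
    truth["abundance"] = truth["abundance"] / truth["abundance"].sum() * 100.0
    truth = truth.sort_values("species", ignore_index=True)
    return truth


def retention_time_model(sp: LipidSpecies) -> float:
    """Qualitative normal-phase retention model (minutes): retention grows
    with carbon number, shrinks with each ether bond and with lyso state.
    Anchored so a C64 tetraether CDL elutes at 19.75 min."""
    return (
        19.75
        + 0.15 * (sp.total_carbons - 64)
        - 0.22 * (sp.total_ethers - 4)
        - 0.50 * sp.lyso_count
        + {"PE": -4.0, "PG": -2.0, "CDL": 0.0, None: -8.0}[sp.head_group]
    )


def _adduct_shares(cls: str, species: LipidSpecies, isotope: bool) -> dict[str, float]:
    """Split of a species' total signal across its class's XIC channels."""
    channels = [a for a in DEFAULT_ADDUCT_POLICY.get(cls, ("[M+H]+",)) if a != "M+1"]
    shares = {}
    for a in channels:
        shares[a] = 0.6 if a == "[M+H]+" else 0.4 / max(1, len(channels) - 1)
    total = sum(shares.values())
    shares = {a: s / total for a, s in shares.items()}
    wants_m1 = "M+1" in DEFAULT_ADDUCT_POLICY.get(cls, ())
    if isotope and wants_m1:
        r = m1_ratio(ADDUCTS["[M+H]+"].ion_formula(species.neutral_formula))
        h = shares["[M+H]+"]
        shares["[M+H]+"] = h / (1 + r)
        shares["M+1"] = h * r / (1 + r)
    return shares


def simulate_spectra(
    truth: pd.DataFrame,
    noise: NoiseModel | None = None,
    seed: int = 0,
    pe_pg_rules: bool = False,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Simulate an MS¹ feature table and MS² spectra for a truth table.

    Every species yields one feature per configured adduct channel (areas
    split per :func:`_adduct_shares`) and one [M+H]+ MS² spectrum built
    from the class's fragmentation rules, with ppm-scaled mass noise,
    intensity jitter, uniform decoy peaks and optional co-isolated
    contaminant peaks from species within the isolation window.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    def jitter_mz(mz: float) -> float:
        if noise.ppm_sigma == 0:
            return mz
        return mz * (1 + rng.normal(0, noise.ppm_sigma) * 1e-6)

    species_by_label = {
        lab: parse_label(lab) for lab in truth["species"]
    }

    # ---- MS1 features -----------------------------------------------
    feat_rows = []
    for row in truth.itertuples():
        sp = species_by_label[row.species]
        rt = retention_time_model(sp) + (
            rng.normal(0, noise.rt_sigma_min) if noise.rt_sigma_min else 0.0
        )
        mh = ADDUCTS["[M+H]+"].mz(sp.neutral_formula)
        for channel, share in _adduct_shares(
            row.class_token, sp, noise.isotope_peaks
        ).items():
            mz = mh + C13_MASS_SHIFT if channel == "M+1" else ADDUCTS[channel].mz(
                sp.neutral_formula
            )
            feat_rows.append(dict(
                mz=jitter_mz(mz),
                rt=rt,
                area=row.abundance * share * float(
                    _lognormal_factor(rng, noise.intensity_cv)
                ),
                true_species=row.species,
                true_channel=channel,
            ))
    features = pd.DataFrame(feat_rows).sort_values(
        ["rt", "mz"], ignore_index=True
    )

    # ---- MS2 spectra -------------------------------------------------
    prec_mz = {
        lab: ADDUCTS["[M+H]+"].mz(sp.neutral_formula)
        for lab, sp in species_by_label.items()
    }
    abundance = dict(zip(truth["species"], truth["abundance"]))
    labels_sorted = sorted(prec_mz, key=prec_mz.get)
    mz_sorted = np.array([prec_mz[lab] for lab in labels_sorted])

    def theoretical_peaks(lab: str) -> list[tuple[float, float]]:
        sp = species_by_label[lab]
        fs = predict_fragments(sp, "[M+H]+", pe_pg_rules=pe_pg_rules)
        pk = [(fs.precursor_mz, 500.0)]
        pk += [
            (e.mz, 1000.0 if e.abundance_hint == "high" else 50.0)
            for e in fs.ions()
        ]
        return pk

    spectra = []
    for lab in truth["species"]:
        sp = species_by_label[lab]
        own = theoretical_peaks(lab)
        peaks = [(jitter_mz(mz), i * float(_lognormal_factor(rng, noise.intensity_cv)))
                 for mz, i in own]
        # co-isolated contaminants
        if noise.co_isolation_window_da > 0:
            half = noise.co_isolation_window_da / 2
            lo = np.searchsorted(mz_sorted, prec_mz[lab] - half)
            hi = np.searchsorted(mz_sorted, prec_mz[lab] + half)
            for other in labels_sorted[lo:hi]:
                if other == lab:
                    continue
                ratio = abundance[other] / max(abundance[lab], 1e-12)
                scale = min(ratio, 1.0) * 0.5
                if scale < 0.01:
                    continue
                peaks += [
                    (jitter_mz(mz), i * scale * float(
                        _lognormal_factor(rng, noise.intensity_cv)))
                    for mz, i in theoretical_peaks(other)
                ]
        if noise.isotope_peaks and sp.head_group == "CDL":
            r = m1_ratio(ADDUCTS["[M+H]+"].ion_formula(sp.neutral_formula))
            peaks.append((jitter_mz(prec_mz[lab] + C13_MASS_SHIFT), 500.0 * r))
        n_decoys = int(rng.poisson(noise.decoy_rate * len(own)))
        for _ in range(n_decoys):
            peaks.append((
                float(rng.uniform(100.0, prec_mz[lab] + 50.0)),
                float(rng.uniform(5.0, 100.0)),
            ))
        spectra.append(Spectrum(
            peaks=tuple(Peak(mz, inten) for mz, inten in peaks),
            precursor_mz=jitter_mz(prec_mz[lab]),
            retention_time=retention_time_model(sp),
            level=2,
            title=lab,
        ))
    return spectra, features
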