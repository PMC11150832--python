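# Methods

## Mass arithmetic and conventions

All masses derive from embedded monoisotopic constants (C 12.0,
H 1.00782503207, N 14.0030740048, O 15.9949146196, P 30.97376163,
Na 22.9897692809 Da; electron 0.00054857991 Da). Printed low-ppm error
annotations on kilodalton ions only reproduce with at least six decimals,
which is why the constants are embedded rather than rounded.

Ion compositions include the adduct atoms: [M+H]⁺ of a neutral with formula
F is the formula F+H, and its m/z is the monoisotopic mass of F+H minus one
electron mass. This matches how high-resolution instruments print ion
compositions (e.g. C73H151O13P2 for a protonated C73H150O13P2 lipid) and is
required for sub-ppm agreement at m/z ≈ 1300, where the electron alone is
0.4 ppm. ppm errors are signed, (observed − theoretical)/theoretical × 10⁶.

The M+1/M intensity ratio uses the linear single-substitution
approximation Σ n·r over the +1 Da isotopes (¹³C 0.010816, ²H 0.000156,
¹⁵N 0.003676, ¹⁷O 0.000380 minor/major ratios; P and Na are monoisotopic).
For lipid-sized formulas the one-substitution peak dominates M+1 and the
approximation is exact for it; tests verify it against a brute-force
enumeration over all isotopologue configurations of small formulas.

## Structural model

Chain-count convention: an acyl chain of n carbons **includes the carbonyl
carbon**, so replacing an ester by an ether linkage at fixed n preserves
the total carbon count and changes the neutral formula by −2H +1O
(+13.9793 Da) — the spacing of the observed ether→ester ladders. Neutral
formulas are head-group scaffolds (glycerol C3H8O3; PE C5H14NO6P; PG
C6H15O8P; the CDL backbone C9H22O13P2 = three glycerols + two
phosphodiesters) plus per-chain substituents (ether Cn: +CnH2n; saturated
acyl Cn: +CnH2n−2O; each double-bond equivalent −H2).

sn-position and methyl branching carry no mass. They are kept as metadata
following the organism's GC–MS-derived convention: odd-carbon chains are
10-methyl-branched and sit at sn-1. The default enumeration emits one
canonical sn-assignment per chain multiset (branched chain at sn-1, ties
longer-then-ether first) rather than all (sn-1, sn-2) permutations —
sn-swapped twins are indistinguishable by MS, and enumerating both would
make self-annotation ill-defined. Ordered enumeration remains available
(`enumerate_cores(ordered=True)`).

Dilyso-CDLs exist in two mass-isomeric structural variants (two
single-chain cores, or one intact core with a bare
phosphatidylglycerophosphate arm); both are enumerated as distinct species
sharing one formula, and their disambiguation is deferred to fragment or
retention evidence.

Default chain space: saturated C14–C17. The builder supports
unsaturation (needed for C34:1 diethers) but the strain's lipidome is
saturated, so 0 is the default everywhere.

## Fragmentation rules

Rules R1–R5 (water loss; per-core radylglycerol neutral loss; further HPO₃
loss; glycerophosphate/glycerodiphosphate head-group ions; alkyl
C(n+3)H(2n+7)O⁺ ions of ether chains) encode the interpretation scheme for
protonated CDL-family spectra; symmetric CDLs emit each entry once. The
qualitative observation that fragments requiring ejection of an
acyl-containing core next to an all-ether partner are weak or absent is
carried as an `abundance_hint` flag; no intensity model is attempted.

R6 (PE/PG fatty-acid/ketene losses and ether-chain ions) is an
extrapolation from common glycerophospholipid practice — the source scheme
is CDL-specific — and is therefore off by default and flagged
"extrapolated" in every entry it produces.

A single water loss is applied to lyso-CDLs even though they carry
additional free hydroxyls; multiple water losses are not emitted because
the observed spectra do not establish them.

## Annotation

Precursor matching defaults to 3 ppm (the identification tolerance of the
source workflow); fragment matching to 5 ppm, since MS² deviations up to
~3.5 ppm occur in the interpreted spectra and 3 ppm would clip them.
Score = number of predicted diagnostic ions found; ties break by avoidable
sn-convention violations, then precursor |Δppm|; remaining ties form an
isomer set. "Avoidable" matters: a core with two branched chains must put
one at sn-2 and is not penalized for its composition.

Chain-level (molecular) identification is claimed only when a single
candidate tops the ranking; otherwise the annotation reports the
species-level call (class, total carbons:unsaturation, ether count) when
the top group agrees on it. This mirrors how ester-containing CDLs are
identified in practice — core carbon numbers from neutral losses, chain
splits often unresolvable. Throughout the package, "species level" means
exactly this granularity; precision/recall figures are defined on it.

Retention ordering (more ether bonds ⇒ shorter retention at fixed class
and carbon number) is a post-hoc consistency check only; no quantitative
retention model exists for these data, so it never enters scoring.

## Quantification

Abundance = sum of configured adduct-channel XIC areas (PE/PG: [M+H]⁺,
[M+NH₄]⁺; CDL family additionally [M+H−H₂O]⁺, [M+Na]⁺ and the ¹³C M+1
trace of [M+H]⁺ — the "as appropriate" channel choice is a per-class map,
fully overridable). The M+1 trace is either added as-is (policy `sum`,
default) or divided by the theoretical M+1 ratio and substituted for the
monoisotopic [M+H]⁺ area (policy `scale`); the substitution reading is the
one under which scaling with exact theoretical M+1 areas is equivalent to
ignoring the isotope channel, which is the invariant the tests pin.
Percentages are never response-corrected — classes and core structures
ionize differently, and the output flags `response_corrected = False`.
Raw-trace peak integration is out of scope; the module consumes integrated
areas.

## Condensation model

Parent ether-count distributions are taken over **intact** cores only
(DAG→0, AEG→1, DEG→2, renormalized after dropping MEG/MAG): only two-chain
cores can form a four-chain CDL. With the measured intact-core percentages
this choice reproduces both ~50% anchors (PG+PG tetraethers 51.2%, PE+PG
diether/diesters 49.2%). Scenario `mix` averages PE+PG and PG+PG with
50–50 default weights; weights are configurable but never fitted — the
comparison to the measured distribution is a single fixed L1 evaluation,
as in the original exercise. A carbon-resolved joint mode exists
(convolution over both coordinates) but has no numeric inputs to validate
against, so the ether-count marginal is the default granularity.

## Simulator

The generator emulates the strain's lipidome: class fractions with PE, PG
and CDL near one third each plus minor lyso classes; CDL ether-class
weights at the measured 9/12/28/18/33% (tetraester→tetraether); PE/PG core
classes at the measured percentages; chain-length weights
{14: 0.35, 15: 0.07, 16: 0.25, 17: 0.33}, a generator choice that puts the
bulk of two-chain cores at 31, 30 and 33 total carbons. Within a class,
abundance mass is allocated by ether-class weight and, within an ether
class, by the product of chain weights, then jittered log-normally
(CV 0.30) and renormalized to 100%.

Mass noise is multiplicative (ppm-scaled Gaussian, default σ = 1 ppm),
matching how instrument accuracy is specified; decoy peaks are uniform in
m/z with no chemical structure (0.1 per real peak by default); the ¹³C M+1
channel is emitted at its theoretical ratio; co-isolation adds the
fragments of species whose precursors fall within a 1.0 Da window
(a guessed default — the true isolation width is unstated). Retention
times follow a linear qualitative model anchored at 19.75 min for the C64
tetraether CDL (+0.15 min/carbon, −0.22 min/ether bond, −0.5 min/lyso
chain, class offsets), built to respect the observed elution ordering, not
to predict absolute retention.

Each species' total signal is split across its class's quantification
channels with fixed shares summing to one ([M+H]⁺ 60%, the rest split
evenly; the M+1 share carved out of the [M+H]⁺ channel at r/(1+r)). This
is a deliberate modelling choice: it makes the noiseless
simulate→annotate→quantify round trip exactly identity under the default
summing policy, so quantification errors in tests are attributable to
noise, never to an arbitrary response model.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real data: chromatographic peak shapes and
integration, in-source fragmentation, class- and structure-dependent
ionization response, chemically plausible interferences (decoys are
uniform), chain-length/branching correlations between the two chains of a
core, and MS³⁺ behaviour.

## Numerical choices

- Annotation and index lookups use binary search on sorted theoretical m/z
  arrays; candidate ordering is made fully deterministic by appending the
  species label and adduct name to every sort key.
- ppm tie-breaks compare |Δppm| rounded to 4 decimals, so floating-point
  dust cannot split genuinely mass-degenerate candidates.
- MGF output is written with fixed formatting (m/z to 4 decimals,
  intensities to 4 decimals, sorted peaks), making simulation outputs
  byte-identical under a fixed seed.
- Degenerate inputs raise: empty formulas have no mass, subtraction
  producing a negative count signals an impossible neutral loss, empty
  compositions and all-zero parent distributions are rejected.

## Known limitations

- Positive ion mode and charge +1 only; no plasmalogens, sphingolipids or
  head groups beyond PE/PG/CDL; no branch-position inference (ether/ester
  MS cannot see it).
- The M+1 model covers single +1 substitutions, not full fine structure.
- Printed observed masses carry instrument error; a few deviate from their
  own printed compositions by >3 ppm, so theoretical masses are reported
  and reconciliation is left to tolerance settings.
- Chain totals span 28–34 for two-chain species over C14–C17; a quoted
  upper endpoint of 36 is not reconstructable from that chain range and is
  not enumerated by default.
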