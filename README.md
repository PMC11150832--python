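# ethercdl

Identification, relative quantification and biosynthesis modelling of
**mono- to tetra-alkyl-ether cardiolipins** (CDLs) from positive-mode
UHPLC-HRMSⁿ peak lists.

Some anaerobic sulfate-reducing bacteria build their membranes largely from
*ether* lipids: glycerol cores whose C14–C17 chains are alkyl-ether-bound
rather than acyl-ester-bound, carried on PE and PG head groups and — most
unusually — on cardiolipins with zero to four ether bonds, up to the fully
ether-linked tetraether CDL. `ethercdl` packages the computational machinery
needed to find and interpret these species in high-resolution MS data:

- **Exact-mass arithmetic** — elemental formulas with Hill rendering,
  monoisotopic and electron-corrected cation m/z, the positive-mode adduct
  set ([M+H]⁺, [M+H−H₂O]⁺, [M+NH₄]⁺, [M+Na]⁺), signed ppm errors, and
  first-isotopologue (M+1) intensity ratios.
- **Species enumeration** — every PE/PG/CDL and lyso species over a
  configurable chain space, with neutral formulas derived from head-group
  scaffolds plus per-chain substituents (ether Cₙ: +CₙH₂ₙ; acyl Cₙ:
  +CₙH₂ₙ₋₂O, carbonyl carbon included).
- **Rule-based MS² prediction** — diagnostic ions of protonated CDLs:
  water loss (R1), per-core radylglycerol neutral loss (R2), further HPO₃
  loss (R3), the glycerophosphate/glycerodiphosphate head-group ions (R4)
  and the C(n+3)H(2n+7)O⁺ alkyl-chain ions of ether chains (R5).
- **Annotation** — precursor matching at 3 ppm, fragment scoring at 5 ppm,
  chain splits claimed only when fragments pin them, unresolvable
  mass-degenerate candidates reported as isomer sets, and a retention-order
  consistency check (more ether bonds ⇒ earlier elution).
- **Quantification** — summed adduct XIC areas per class, with the ¹³C
  M+1 trace of CDL [M+H]⁺ ions included (summed or ratio-scaled), and
  marginal composition reports; percentages are as-measured (no
  response-factor correction).
- **Condensation model** — CDLs arise by synthase-mediated condensation of
  two PGs or a PE with a PG. With per-core ether counts DAG→0, AEG→1,
  DEG→2, the predicted CDL ether-class distribution over {0..4} is the
  discrete convolution of the two parents' distributions:
  q[E] = Σ_{e₁+e₂=E} a[e₁]·b[e₂].
- **Simulator** — seeded ground-truth lipidomes with MS¹ feature tables and
  MGF MS² spectra (ppm-scaled mass noise, decoy peaks, isotope channels,
  co-isolation), so the whole pipeline is testable without any raw data.

## Worked example

The flagship species is a tetraether CDL with 64 alkyl carbons, built from
a C33 DEG core (ether 17+16) and a C31 DEG core (ether 17+14):

```python
from ethercdl import parse_label, predict_fragments

species = parse_label("CDL 64:0;e4 [e17/e16 | e17/e14]")
fs = predict_fragments(species, "[M+H]+")
print(round(fs.precursor_mz, 4))          # 1298.0624
for e in fs.ions():
    print(e.rule_id, e.formula, round(e.mz, 4))
```

```
R1  C73H149O12P2   1280.0519   water loss
R2  C37H77O10P2     743.4986   precursor minus DEG C33 core
R3  C37H76O7P       663.5323     ... further HPO3 loss
R2  C39H81O10P2     771.5299   precursor minus DEG C31 core
R3  C39H80O7P       691.5636     ... further HPO3 loss
R4  C3H8O5P         155.0104   glycerophosphate
R4  C3H9O8P2        234.9767   glycerodiphosphate
R5  C20H41O         297.3152   alkyl C17 ion
R5  C19H39O         283.2995   alkyl C16 ion
R5  C17H35O         255.2682   alkyl C14 ion
```

The ion [M+H]⁺ composition is C73H151O13P2 at m/z 1298.0624; the two R2
neutral losses (526.5325 and 554.5638 Da) are the C31 and C33
dialkylglycerol cores. Annotating the packaged observed peak list of this
spectrum recovers the species unambiguously at chain-split level:

```sh
ethercdl annotate --mgf src/ethercdl/data/fig4_tetraether_cdl.mgf
# label = "CDL 64:0;e4 [e17/e16 | e17/e14]", score 10/10, status unambiguous
```

The condensation model, fed the measured intact-core percentages
(PE: DAG 54.0 / AEG 7.5 / DEG 25.0; PG: DAG 9.3 / AEG 17.0 / DEG 66.2):

```sh
ethercdl condense --scenario mix --measured 9,12,28,18,33
```

```
# scenario mix  L1 distance 0.1867
ether_count,percent,measured_percent
0,3.64,9.0
1,8.02,12.0
2,33.47,28.0
3,18.91,18.0
4,35.95,33.0
```

Condensing two PGs predicts 51.2% tetraether CDLs; PE+PG predicts 49.2%
diether/diester CDLs; the 50–50 mix of both pathways fits the measured CDL
ether-class distribution far better (L1 = 0.19) than either pathway alone —
the computational signature that both synthase routes are active.

## Layout

| module | contents |
| --- | --- |
| `ethercdl.formula` | elemental formulas, adducts, masses, ppm, M+1 ratios |
| `ethercdl.lipids` | chains, cores, species, enumeration, labels |
| `ethercdl.fragments` | MS² rules R1–R5 (+ optional PE/PG rule R6) |
| `ethercdl.annotate` | precursor/spectrum annotation, isomer sets, RT check |
| `ethercdl.quantify` | XIC-based abundances and composition reports |
| `ethercdl.condense` | the condensation convolution model |
| `ethercdl.simulate` | seeded lipidome/spectrum simulator |
| `ethercdl.io`, `ethercdl.cli` | MGF/table/config I/O and the `ethercdl` CLI |

See `docs/methods.md` for the scientific conventions, parameter defaults
and known limitations.
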