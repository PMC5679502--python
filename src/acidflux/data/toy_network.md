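# The bundled toy network

A deliberately small, hand-checkable fermentation network used throughout the
test-suite as a desk-scale stand-in for a genome-scale fungal reconstruction.
The structural tables are shipped alongside this file
(`toy_reactions.tsv`, `toy_metabolites.tsv`); `make_toy_network()` is the
canonical constructor and the TSVs are regenerated from it.

## Design

* **One carbon currency.** All catabolism is collapsed into a single C1
  currency metabolite `cc`; glucose yields 6, xylose 5.  Every internal
  reaction is exactly carbon-balanced, so whole-trajectory carbon
  conservation can be checked to solver precision.
* **Phosphate.** External phosphate enters through `T_PIE` (capped by the
  Michaelis–Menten uptake rule).  The reversible `PI` reaction exchanges the
  cytosolic phosphate pool with a stored-phosphate pool: forward flux is
  release (capped by the stored-phosphate kinetics), reverse flux is storage
  (the phosphate-storage objective maximises the reverse direction).
* **Acids.** Each of the seven acids has a secretion reaction
  (`SEC_*`, cytosol → undissociated secreted form) paired with a dissociation
  reaction (`DISS_*`, secreted form → external pool + a pH-dependent
  fractional number of protons, rewritten by the engine every step).  Only
  citrate and oxalate have internal synthesis routes (`SYN_CIT`, `SYN_OXA`);
  gluconate is produced exclusively by the forced extracellular
  glucose-oxidase reaction `GOX_E`; the remaining four acids are structurally
  present (their secretion/dissociation pairs carry the acid hierarchy) but
  have no toy synthesis route.
* **Shared secretion capacity.** Citrate and oxalate secretion both consume
  one unit of a secretion-capacity pseudo-metabolite (`sec_cap`, supplied by
  `SEC_BUDGET`, sized each step by the citrate output cap).  They act as a
  single proton-production response: knocking out the oxalate branch
  reroutes capacity to citrate, reproducing the directional knockout
  behaviour.  Individual caps (citrate cap, oxalate cap with the pH < 2
  shut-off) still apply on top.
* **Protons.** `HPE` exports external protons and is the proton-production
  objective.

## Biomass

Mass fractions per gDW (sum = 1):

| class         | mass fraction | g C / g | g P / g |
|---------------|--------------:|--------:|--------:|
| protein       | 0.45          | 0.53    | 0       |
| carbohydrate  | 0.26          | 0.444   | 0       |
| phospholipid  | 0.05          | 0.65    | 0.031   |
| nucleic_acid  | 0.04          | 0.34    | 0.094   |
| glycerol      | 0.10          | 0.391   | 0       |
| other         | 0.10          | 0       | 0       |

Structural carbon = 0.43904 g C/gDW = 36.55 mmol `cc`; phosphorus =
0.00531 g P/gDW = 0.1714 mmol phosphate.  A growth-associated respiration
overhead of 213 mmol `cc` per gDW (released as CO2) is added, giving a total
carbon-currency demand of 249.6 mmol/gDW.  The overhead is chosen so that at
160 g/L glucose the carbon-limited growth rate (~0.076 h⁻¹) sits *below* the
externally-fed phosphate-limited growth rate before the 8-h phosphate-rate
switch and *above* it afterwards — which is what produces the
store-then-starve diauxic behaviour at a sensible time-scale.

Biomass adjustment rescales the nucleic-acid and phospholipid mass fractions
(internal ratios fixed), the glycerol fraction absorbs the mass difference,
and the carbon/phosphate coefficients of `BIOMASS` are recomputed from the
adjusted composition.
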