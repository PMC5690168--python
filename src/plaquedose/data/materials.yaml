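# Materials database.
#
# Ocular media, water and dry air: elemental compositions (% by mass) and
# densities (g/cm^3) of the heterogeneous human-eye phantom. Retina and
# choroid are modelled as water (their density and composition are assumed
# identical to water). Seed and plaque construction materials follow the
# standard COMS / model-6711 literature: Modulay gold alloy
# (Au 77 / Ag 14 / Cu 8 / Pd 1) at 15.8 g/cm^3 and Silastic silicone
# elastomer at 1.12 g/cm^3.
water:
  density: 0.9980
  fractions: {H: 11.11901, O: 88.8099}
dry_air:
  density: 0.0012
  fractions: {O: 23.17812, C: 0.012425, N: 75.52673, Ar: 1.282725}
lens:
  density: 1.07
  fractions: {H: 9.60, O: 64.60, C: 19.50, N: 5.70, Na: 0.10, P: 0.10, S: 0.30, Cl: 0.10}
sclera:
  density: 1.09
  fractions: {H: 9.60, O: 74.40, C: 9.90, N: 2.20, Mg: 0.50, P: 2.20, S: 0.90, Cl: 0.30}
vitreous:
  density: 1.00
  fractions: {H: 11.0867, O: 88.052, C: 0.068, Na: 0.2647, Mg: 0.0025, P: 0.002,
              Cl: 0.502, K: 0.0171, Ca: 0.005}
aqueous_humor:
  density: 1.01
  fractions: {H: 11.085, O: 88.06, C: 0.056, N: 0.00001, Na: 0.348, Mg: 0.0025,
              P: 0.0018, S: 0.00001, Cl: 0.432, K: 0.00798, Ca: 0.0067}
optic_nerve:
  density: 1.039
  fractions: {H: 10.70, O: 76.70, C: 9.50, N: 1.80, Na: 0.20, P: 0.30, S: 0.20,
              Cl: 0.30, K: 0.30}
skull_bone:
  density: 1.61
  fractions: {H: 5.00, O: 43.50, C: 21.20, N: 4.00, Na: 0.10, Mg: 0.20, P: 8.10,
              S: 0.30, Ca: 17.60}
tumor:
  density: 1.03
  fractions: {H: 10.8, O: 83.2, C: 4.10, N: 1.10, Mg: 0.30, S: 0.10, Cl: 0.40}
modulay:
  density: 15.8
  fractions: {Au: 77.0, Ag: 14.0, Cu: 8.0, Pd: 1.0}
silastic:
  density: 1.12
  fractions: {H: 6.3, C: 24.9, O: 28.89, Si: 39.9, Pt: 0.01}
titanium:
  density: 4.54
  fractions: {Ti: 100.0}
silver:
  density: 10.5
  fractions: {Ag: 100.0}
gold:
  density: 19.32
  fractions: {Au: 100.0}
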