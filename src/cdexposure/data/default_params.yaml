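# Default coefficient catalogue for the cadmium toxicokinetic model.
#
# All transfer coefficients are first-order daily fractions (day^-1) moving
# cadmium between the compartments of a classic multi-compartment disposition
# scheme: three blood pools (B1 fast uptake, B2 bound, B3 systemic), liver (L),
# kidney (K), other tissue (T), with urinary (U) and fecal (F) elimination.
# Values are literature-shaped defaults: gut absorption higher in females
# (lower iron stores promote uptake), kidney elimination half-life ~19 years
# (k_KU = ln2 / (19 * 365)), liver acting as a slow redistribution depot, and
# the kidney+liver pair holding most of the long-term body burden.  Absolute
# output levels are expected to be calibrated per population group against a
# measured (intake, urinary cadmium) anchor pair before quantitative use.
absorption:
  gut:                     # fraction of cadmium reaching the gut that is absorbed
    male: 0.05
    female: 0.10
  lung: 0.10               # fraction of inhaled cadmium absorbed through the lung
  mucociliary_to_gut: 0.40 # inhaled fraction cleared to the gut; rest is exhaled

transfer_coefficients:     # day^-1
  k_B1B2: 0.05             # fast blood pool -> bound blood pool
  k_B2B1: 0.02             # bound blood pool -> fast blood pool
  k_B1B3: 0.15             # fast blood -> systemic blood
  k_B1L: 0.25              # fast blood -> liver
  k_B1K: 0.05              # fast blood -> kidney
  k_B1T: 0.04              # fast blood -> other tissue
  k_TB1: 0.00003           # other tissue -> fast blood (slow return)
  k_B1F: 0.01              # fast blood -> feces (biliary/gut secretion)
  k_B3K: 0.01              # systemic blood -> kidney
  k_B3U: 0.00005           # systemic blood -> urine (direct filtration)
  k_LB3: 0.0001            # liver -> systemic blood (slow depot release)
  k_LF: 0.00003            # liver -> feces
  k_KU: 0.0001             # kidney -> urine; half-life ~19 y
  k_KB1: 0.000025          # kidney -> fast blood (recycling)

# Daily creatinine excretion (g/day) as piecewise-linear [age_years, g/day]
# control points; adult male plateau 1.5 g/day, female 1.0 g/day, declining
# with muscle mass in old age, ramping up through childhood.
creatinine_curve:
  male: [[0, 0.2], [3, 0.2], [20, 1.5], [50, 1.5], [80, 1.0], [100, 1.0]]
  female: [[0, 0.2], [3, 0.2], [20, 1.0], [50, 1.0], [80, 0.7], [100, 0.7]]

# Multiplier on the adult dietary intake as a function of age (caloric-intake
# scaling): children eat less, adults (>= 18 y) take the full amount.
diet_age_scaling: [[0, 0.3], [18, 1.0], [100, 1.0]]

timestep: 1                # days per explicit integration step
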