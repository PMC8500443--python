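# Localized winter-wheat parameter set (potential production, reduced model).
# Sensitive tables: specific leaf area (ha leaf kg-1 leaf) at DVS 0/0.5/2 and
# maximum gross CO2 assimilation (kg CO2 ha-1 h-1) at DVS 1/1.3, clamped outside.
slatb:
  - [0.0, 0.0018]
  - [0.5, 0.0017]
  - [2.0, 0.00095]
amaxtb:
  - [1.0, 38.83]
  - [1.3, 45.0]

# Phenology: thermal time (deg C d) sowing->emergence, emergence->anthesis,
# anthesis->maturity; base temperature deg C.
tsumem: 110.0
tsum1: 680.0
tsum2: 900.0
t_base: 0.0

# Assimilate-to-dry-matter conversion efficiency (kg DM per kg CH2O).
cvs: 0.70

# Canopy light extinction coefficient.
k_ext: 0.6

# Dry-matter partitioning fractions vs DVS (shared knot grid so fractions sum
# to 1 at every development stage).
partition_dvs: [0.0, 0.5, 0.7, 0.95, 1.0, 1.3, 2.0]
partition_root:    [0.40, 0.20, 0.10, 0.00, 0.00, 0.00, 0.00]
partition_leaf:    [0.40, 0.45, 0.40, 0.20, 0.00, 0.00, 0.00]
partition_stem:    [0.20, 0.35, 0.50, 0.70, 0.20, 0.00, 0.00]
partition_storage: [0.00, 0.00, 0.00, 0.10, 0.80, 1.00, 1.00]

# Post-anthesis remobilisation of stem reserves to the grain (d-1); over a
# ~50-day grain fill this moves roughly half of the anthesis stem mass.
stem_trans_rate: 0.012

# Post-anthesis leaf senescence: relative death rate rdr_base * max(0, DVS-1).
rdr_base: 0.025

# Green leaf area index assigned at emergence.
lai_init: 0.05

# Assimilation scaling: effective photosynthetically active hours per day and
# the daily global-radiation level (MJ m-2 d-1) above which light saturates.
f_day: 12.0
r_ref: 10.0

# Maintenance respiration: reference coefficients (kg CH2O per kg DM per day)
# at t_ref with a Q10 temperature response.
q10: 2.0
t_ref: 25.0
maint_leaf: 0.030
maint_stem: 0.015
maint_storage: 0.010
maint_root: 0.010
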