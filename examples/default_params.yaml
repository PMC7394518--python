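# Default risk-model parameters. Loading this file reproduces the built-in
# RiskParams() exactly.
#
# Provenance notes:
# - alpha, delta_t, delta_s: environmental-similarity establishment kernel
#   (peak probability, temperature width in deg C, salinity width in ppt).
# - gamma: biofouling en-route survival decay per (km/day) of velocity.
# - beta_tropical / beta_temperate: cubic accumulation coefficients
#   (b1, b2, b3) for b1*d^3 - b2*d^2 + b3*d, d = days at the source port;
#   tropical band is |latitude| <= 35 deg, boundary inclusive.
# - mu, lam: ballast in-tank daily mortality and introduction potential
#   per m^3 of discharge.
# - antifouling: share of ships of each type without an operational
#   antifouling system (commercial fleet survey values); unmapped types
#   fall back to "other".
# - discharge_coeff: nominal ballast discharge per tonne of gross weight
#   tonnage (m^3/tonne) by type. These are package defaults standing in for
#   fleet-survey discharge/size fits; override them with values fitted to
#   your own discharge records when available.
# - rho_default: ballast-water management efficacy factor; 1 means no
#   management practices are modeled.
alpha: 0.00015
delta_t: 2.0
delta_s: 10.0
gamma: 0.008
beta_tropical: [1.29e-07, 8.316e-05, 0.0149]
beta_temperate: [1.4e-09, 1.6566e-05, 5.193e-03]
mu: 0.02
lam: 3.22e-06
rho_default: 1.0
antifouling:
  Container: 0.19
  Auto: 0.20
  Tanker: 0.30
  Passenger: 0.31
  Bulk: 0.42
  General: 0.53
  other: 0.60
discharge_coeff:
  Container: 0.10
  Auto: 0.20
  Bulk: 0.35
  General: 0.15
  Tanker: 0.30
  Passenger: 0.20
  other: 0.15
type_aliases:
  container: Container
  auto: Auto
  automobile: Auto
  bulk: Bulk
  general: General
  tanker: Tanker
  tanker/oil: Tanker
  oil: Tanker
  chemical: Tanker
  gas: Tanker
  passenger: Passenger
clamp_accumulation: true
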