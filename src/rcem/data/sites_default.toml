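# Default titratable-site and redox-cofactor definitions.
#
# Titratable sites: the side-chain polar group carries the two state charge
# vectors (state 1 = deprotonated for acids, protonated for bases); vectors
# supersede the base parameter table on the member atoms, and their sums
# differ by exactly -1 (acid) or +1 (base).
#
# Redox templates carry the one-electron reference midpoint potentials
# (mV vs NHE) measured for the isolated cofactors: BChl b -665 mV,
# BPheo b -429 mV, menaquinone -256 mV.  RESP-quality state charge files
# must be supplied per run (charges_state0/charges_state1 keys).

[titratable.ASP]
kind = "acid"
model_pka = 4.0
atoms = ["CG", "OD1", "OD2"]
state0 = [0.55, -0.55, 0.00]
state1 = [0.10, -0.55, -0.55]

[titratable.GLU]
kind = "acid"
model_pka = 4.4
atoms = ["CD", "OE1", "OE2"]
state0 = [0.55, -0.55, 0.00]
state1 = [0.10, -0.55, -0.55]

[titratable.HIS]
kind = "base"
model_pka = 6.3
atoms = ["CG", "ND1", "CD2", "CE1", "NE2", "HE2"]
state0 = [0.10, -0.40, 0.10, 0.30, -0.49, 0.39]
state1 = [0.10, 0.15, 0.10, 0.50, -0.30, 0.45]

[titratable.CYS]
kind = "acid"
model_pka = 9.5
atoms = ["CB", "SG", "HG"]
state0 = [0.12, -0.50, 0.38]
state1 = [0.00, -1.00, 0.00]

[titratable.TYR]
kind = "acid"
model_pka = 9.6
atoms = ["CZ", "OH", "HH"]
state0 = [0.25, -0.65, 0.40]
state1 = [0.10, -1.10, 0.00]

[titratable.LYS]
kind = "base"
model_pka = 10.4
atoms = ["CE", "NZ", "HZ1", "HZ2", "HZ3"]
state0 = [0.00, -0.70, 0.35, 0.35, 0.00]
state1 = [0.10, -0.45, 0.45, 0.45, 0.45]

[titratable.ARG]
kind = "base"
model_pka = 12.0
atoms = ["NE", "HE", "CZ", "NH1", "HH11", "HH12", "NH2", "HH21", "HH22"]
state0 = [-0.40, 0.40, 0.20, -0.70, 0.45, 0.00, -0.70, 0.45, 0.20]
state1 = [-0.40, 0.40, 0.30, -0.60, 0.45, 0.45, -0.60, 0.45, 0.45]

[redox.BCB]  # bacteriochlorophyll b
em_ref = -665.0
required = false

[redox.BPB]  # bacteriopheophytin b
em_ref = -429.0
required = false

[redox.MQ9]  # menaquinone (Q_A)
em_ref = -256.0
required = false
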