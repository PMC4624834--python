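# Constructed 1-compartment IV-bolus test model, q6 dosing, 4 occasions.
# IIV and IOV act on the same parameters (CL, V).  The dose is printed
# as 1 unit; pass dose_scale to the loader to resolve the dose/error
# scale (see docs/methods.md).

model = "onecomp"

[theta]
CL = 9.0   # L/h
V = 40.0   # L

[error]
add_var = 1.0    # additive residual error variance
prop_var = 0.04  # proportional residual error variance (combined model)

[omega]
names = ["CL", "V"]
variances = [0.0625, 0.0625]

[omega_star]  # omega*^2 = omega^2 + pi^2 (Inflate method)
variances = [0.125, 0.125]

[pi]
names = ["CL", "V"]
variances = [0.0625, 0.0625]

[dosing]
tau = 6.0
n_occasions = 4
horizon = 24.0

[[dosing.doses]]
time = 0.0
amount = 1.0

[[dosing.doses]]
time = 6.0
amount = 1.0

[[dosing.doses]]
time = 12.0
amount = 1.0

[[dosing.doses]]
time = 18.0
amount = 1.0

[channels]
names = ["DV"]
log_scale = [false]

[constraints]
forbidden = []
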