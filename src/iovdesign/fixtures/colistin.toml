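# Population PK model of colistin and its prodrug CMS.
# Units: hours, litres, micromol, microM.  Variances are authoritative;
# CV% columns of the source table correspond to sqrt(variance).

model = "colistin"

[theta]
CL_CMS = 13.1   # L/h, CMS clearance (fully converted to colistin)
V_CMS1 = 11.8   # L, CMS central volume
Q = 206.0       # L/h, intercompartmental clearance (fast distribution)
V_CMS2 = 28.4   # L, CMS peripheral volume
CL_col = 8.276  # L/h, colistin clearance (CL/fm)
V_col = 218.0   # L, colistin volume (V/fm)
sc = 1.81       # scaling of shared eta_CL for colistin (SD scale)

[error]
CMS_add = 0.0715  # microM, additive part of CMS residual SD
CMS_prop = 0.23   # proportional part (log scale) of CMS residual SD
col_add = 0.044   # microM, additive part of colistin residual SD
col_prop = 0.082  # proportional part (log scale) of colistin residual SD
denominator = "conc"  # additive-part denominator: "conc" or "logconc"

[omega]
names = ["CL", "Q", "ER"]
variances = [0.17, 1.23, 0.27]

[omega_star]  # IIV re-estimated with IOV removed (Inflate method)
variances = [0.20, 3.26, 1.8]
sc = 1.8708   # sqrt(0.70 / 0.20): inflated colistin-CL IIV on SD scale

[pi]
names = ["CL_CMS", "V_CMS2", "FM"]
variances = [0.09, 0.35, 0.35]

[dosing]
tau = 12.0
n_occasions = 3
horizon = 36.0

[[dosing.doses]]  # 9 MU CMS loading dose, 30-min infusion
time = 0.0
amount = 413.0
duration = 0.5

[[dosing.doses]]  # 4.5 MU maintenance q12h
time = 12.0
amount = 206.5
duration = 0.5

[[dosing.doses]]
time = 24.0
amount = 206.5
duration = 0.5

[channels]
names = ["DV_CMS1", "DV_Col"]
log_scale = [true, true]

[constraints]
# sampling prohibited during each infusion and for 15 min after
forbidden = [[0.0, 0.75], [12.0, 12.75], [24.0, 24.75]]
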