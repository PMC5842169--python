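# Atomic parameter table, version 1.
# Per-row: electronegativity (chi) and hardness (eta) parameters of the
# electronegativity equalization method, and the rule-based atomic
# lipophilicity contribution. All values dimensionless, on the published
# calibration scale (EEM solved with interatomic distances in Bohr).
# Row keys:
#   H_polar  - hydrogen with at least one neighbour outside {C, H}
#   H_CH     - hydrogen bonded only to carbon or hydrogen
#   elements Li B Na Mg Si P K Ca Fe Cu Zn share one row (listed separately)
#   OTHER    - fallback for any element without its own row
# columns: key, chi, eta, lipophilicity
H_polar	0.206	0.660	-0.374
H_CH	0.206	0.660	-0.018
Li	0.362	0.330	-0.175
B	0.362	0.330	-0.175
Na	0.362	0.330	-0.175
Mg	0.362	0.330	-0.175
Si	0.362	0.330	-0.175
P	0.362	0.330	-0.175
K	0.362	0.330	-0.175
Ca	0.362	0.330	-0.175
Fe	0.362	0.330	-0.175
Cu	0.362	0.330	-0.175
Zn	0.362	0.330	-0.175
C	0.362	0.330	0.271
N	0.493	0.345	-0.137
O	0.730	0.544	-0.321
F	0.721	0.727	0.217
S	0.620	0.206	0.385
Cl	0.362	0.330	0.632
Br	0.701	0.546	0.815
I	0.681	0.307	0.198
OTHER	0.206	0.660	-0.175
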