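step	k_rho	k_tau	rho0	tau0
AA	0.2	0.406	0.76	-1.84
AT	0.124	0.641	-1.39	0
AG	0.077	0.28	3.15	-1.48
AC	0.085	0.302	0.91	-0.64
TA	0.064	0.365	5.25	0
TG	0.059	0.393	5.95	-0.05
TC	0.097	0.408	3.87	-1.52
GG	0.075	0.218	3.86	0.4
GC	0.057	0.256	0.67	0
CG	0.04	0.255	4.25	0
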