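# Clinicopathological features and copy-number status at the Met and
# Cdkn2a/2b loci for 13 primary iron-induced rat renal cell carcinomas.
case_id	size_mm	metastasis	invasion	atypia	growth	met_status	cdkn2a_status
FB7-1	20	None	None	Low	Intermediate	None	Loss
FB32-4	15	Lung	None	Intermediate	Intermediate	None	Loss
FB7-7	60	Lung	None	Intermediate	Expansive	Amplification	None
FB59-1	15	Lung	Peritoneal	Intermediate	Infiltrating	None	HD
FB14-3	15	None	None	High	Expansive	Amplification	Loss
FB28-7	30	None	None	High	Intermediate	None	Loss
BF51-1	28	None	None	High	Intermediate	Amplification	None
FB14-6	30	Lung	Peritoneal	High	Intermediate	Amplification	Loss
FB21-2	40	None	None	High	Infiltrating	Amplification	HD
FB45-4	40	Lung	None	High	Infiltrating	Amplification	HD
FB30-5	60	Lung	Peritoneal	High	Infiltrating	Amplification	Loss
FB33-7	70	Lung	Peritoneal	High	Infiltrating	Amplification	None
BF57-5	25	Lung	Peritoneal	High	Infiltrating	Amplification	HD
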