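sample_id	group
K1	keto
K2	keto
K3	keto
K4	keto
K5	keto
K6	keto
K7	keto
K8	keto
N1	normal
N2	normal
N3	normal
N4	normal
N5	normal
N6	normal
N7	normal
N8	normal
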