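# Named molecular-descriptor sets for ABC-transporter substrate models.
# One set per block: "[set-name]" followed by one descriptor name per line.
# DD17 is the union of uncorrelated (|r| < 0.9) descriptors drawn from the
# three single-transporter binary models.

[P-gp]
apol
chi0_C
chi0v_C
chi1_C
rings
PEOE_VSA-5
PEOE_VSA_POL
PEOE_VSA_PPOS
SlogP_VSA0
SMR_VSA2
TPSA
opr_brigid

[MRP1]
a_count
a_hyd
chi1v
opr_nring
PEOE_VSA+3
PEOE_VSA+5
PEOE_VSA-4
PEOE_VSA-6
Q_VSA_PNEG
vsa_acc

[BCRP]
a_count
a_hyd
a_nC
a_nH
chi1v
SlogP_VSA1
SlogP_VSA2
SlogP_VSA8
SMR_VSA1
SMR_VSA6
VDistMa

[DD17]
apol
opr_brigid
PEOE_VSA+3
PEOE_VSA+5
PEOE_VSA-4
PEOE_VSA-5
PEOE_VSA-6
PEOE_VSA_POL
Q_VSA_PNEG
SlogP_VSA0
SlogP_VSA1
SlogP_VSA2
SlogP_VSA8
SMR_VSA1
SMR_VSA2
SMR_VSA6
vsa_acc
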