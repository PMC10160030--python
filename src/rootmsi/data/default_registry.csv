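name,formula,adduct,verified
succinate,C4H6O4,[M-H]-,yes
malate,C4H6O5,[M-H]-,yes
fumarate,C4H4O4,[M-H]-,yes
aconitate,C6H6O6,[M-H]-,yes
citrate/isocitrate,C6H8O7,[M-H]-,yes
alpha-ketoglutarate,C5H6O5,[M-H]-,yes
oxaloacetate,C4H4O5,[M-H]-,yes
quinate,C7H12O6,[M-H]-,yes
hexose,C6H12O6,[M-H]-,yes
MBOA,C8H7NO3,[M-H]-,yes
hexose-hexose,C12H22O11,[M-H]-,no
fatty acid (18:2),C18H32O2,[M-H]-,no
PG(16:0/18:2),C40H75O10P,[M-H]-,no
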