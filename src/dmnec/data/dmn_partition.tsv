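roi_label	subcomponent
mPFC_01	mPFC
mPFC_02	mPFC
mPFC_03	mPFC
mPFC_04	mPFC
mPFC_05	mPFC
mPFC_06	mPFC
mPFC_07	mPFC
mPFC_08	mPFC
mPFC_09	mPFC
mPFC_10	mPFC
mPFC_11	mPFC
mPFC_12	mPFC
PCC_01	PCC
PCC_02	PCC
PCC_03	PCC
PCC_04	PCC
PCC_05	PCC
PCC_06	PCC
PCC_07	PCC
PCC_08	PCC
PCC_09	PCC
PCC_10	PCC
PCC_11	PCC
LPC_01	LPC
LPC_02	LPC
LPC_03	LPC
LPC_04	LPC
LPC_05	LPC
LPC_06	LPC
RPC_01	RPC
RPC_02	RPC
RPC_03	RPC
RPC_04	RPC
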