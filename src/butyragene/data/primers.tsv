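name	iupac	orientation	set
buk_1F	atcaaYccDggWtcWacWtcWac	forward	BUK_F
buk_2F	atWaatccWggttcWacWtcWacMaa	forward	BUK_F
buk_3F	atMaaTccWggBtcKacMtcaact	forward	BUK_F
buk_1R	acHgcYttYtgRtttaaWgcatg	reverse	BUK_R
buk_2R	tgcYttYtggttgagygc	reverse	BUK_R
buk_3R	gccttctgRttMagKgcatg	reverse	BUK_R
but_1F	cagctIggYatYggIgS	forward	BUT_F
but_2F	ggWatWggMgsYatgcc	forward	BUT_F
but_3F	gHatYggIgStatgcc	forward	BUT_F
but_1R	aaRtccaIYtgIccVcc	reverse	BUT_R
but_2R	aaRtcaaSctgKccDc	reverse	BUT_R
but_3R	aagtcWaaYtgwccRcc	reverse	BUT_R
G_buk_F	tgctgtWgttggWagaggYgga	forward	G_buk
G_buk_R	gcaacIgcYttttgatttaatgcatgg	reverse	G_buk
G_Acida_F	cgcagaagaacattgacaagg	forward	G_Acida
G_Acida_R	atggcagggttattgtctacataatc	reverse	G_Acida
G_Fprsn_F	gacaagggccgtcaggtcta	forward	G_Fprsn
G_Fprsn_R	ggacaggcagatRaagctcttgc	reverse	G_Fprsn
G_RosEub_F	tcaaatcMggIgactgggtWga	forward	G_RosEub
G_Ros_R	tcgataccggacatatgccaKgag	reverse	G_RosEub
G_Eub_R	tcataaccgcccatatgccatgag	reverse	G_RosEub
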