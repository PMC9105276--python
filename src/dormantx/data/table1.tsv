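ltl_id	ar	psa	syp	erg	tmprss2_erg_fusion	pten_protein	pten_status
LTL313B	+	+	-	+	+	-	-/-
LTL313H	+	+	-	+	+	-	-/-
LTL412	+	+	-	-	-	-	+/-
LTL471	+	+	-	-	-	+	+/+
LTL556	+	+	-	+	+	-	-/-
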