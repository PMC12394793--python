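name	formula	delta_mass	targets	position_rule	lability_class
myristoyl	C14H26O	210.19837	C	anywhere	thioester_acyl
palmitoyl	C16H30O	238.22967	C	anywhere	thioester_acyl
stearoyl	C18H34O	266.26097	C	anywhere	thioester_acyl
farnesyl	C15H24	204.18780	C	anywhere	thioether_prenyl
geranylgeranyl	C20H32	272.25040	C	anywhere	thioether_prenyl
NEM	C6H7NO2	125.04768	C	anywhere	stable
carbamidomethyl	C2H3NO	57.02146	C	anywhere	stable
acetyl-protein-N-term	C2H2O	42.01056	*	protein-N-term	stable
oxidation-M	O	15.99491	M	anywhere	stable
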