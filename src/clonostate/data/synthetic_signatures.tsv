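# Synthetic stand-in gene sets aligned with the simulator's default state
# programs. The published innateness / TILneo4-8 / exhaustion gene lists are
# third-party resources and are deliberately not reproduced here; users
# should drop in their own lists via the same two-column format.
innateness_up	NKG7
innateness_up	CST7
innateness_up	CCL5
innateness_up	GZMA
innateness_up	IL32
innateness_up	CTSW
innateness_down	SOX4
innateness_down	LEF1
innateness_down	TCF7
innateness_down	SELL
innateness_down	IL7R
innateness_down	BACH2
tilneo	ENTPD1
tilneo	CXCL13
tilneo	NKG7
tilneo	CST7
tilneo	IL32
exhaustion	LAG3
exhaustion	HAVCR2
exhaustion	PDCD1
exhaustion	TOX
exhaustion	TIGIT
exhaustion	CTLA4
antigen_presentation	CD74
antigen_presentation	HLA-DRA
antigen_presentation	HLA-DRB1
antigen_presentation	HLA-DPA1
antigen_presentation	LAMP3
antigen_presentation	HSPA8
s_phase	MCM2
s_phase	MCM4
s_phase	PCNA
s_phase	RRM2
s_phase	GINS2
g2m	MKI67
g2m	TOP2A
g2m	CCNB1
g2m	CDK1
g2m	AURKB
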