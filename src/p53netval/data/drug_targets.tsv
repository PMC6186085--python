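gene	drug	status	target_type
FEN1	Epinephrine	approved	direct
FEN1	Gentian violet	approved	direct
FEN1	Methyldopa	approved	direct
FEN1	Dopamine	approved	direct
FEN1	Idarubicin	approved	direct
FEN1	Norepinephrine	approved	direct
FEN1	Masoprocol	approved	direct
FEN1	Quinacrine	approved	direct
FEN1	Mitoxantrone	approved	direct
FEN1	Levodopa	approved	direct
MMP2	Captopril	approved	direct
MMP2	Marimastat	approved	direct
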