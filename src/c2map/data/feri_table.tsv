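Ferlin	Length	FerI Span	Sequence	pI
Dysferlin	31	346–376	PGDEAPLERKDPSEDKEDIESNLLRPTGVAL--	4.21
Otoferlin	31	382–414	KGDNIKTPHKANETDEDDIEGNLLLPEGVPPER	3.93
Myoferlin	33	325–355	TGDEPPPERRDRDNDSDDVESNLLLPAGIAL--	4.40
Fer1L4	33	154–186	RGDLPPPMLPPAPGHCSDIEKNLLLPRGVPAER	6.75
Fer1L5	30	293–322	VGDQALIDQKLLY-GTDDTDIQIFKSAVVPI--	3.97
Fer1L6	32	209–240	KGDVLKTSPKTS-DTEEPIEKNLLIPNGFPLER	5.06
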