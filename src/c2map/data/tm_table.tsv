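Ferlin	Length	Transmembrane Span	Conserved Proline	Extracellular
Dysferlin	23	2045–2067	Pro–2068	2068–2080 (12)
Otoferlin	23	1969–1991	Pro–1987	1992–1997 (5)
Myoferlin	23	2026–2046	Pro–2049	2048–2061 (13)
Fer1L4	23	1758–1780	Pro–1781	1781–1794 (13)
Fer1L5	20	1962–1981	Pro–1983	1982–2047 (75)
Fer1L6	23	1824–1846	Pro–1846	1847–1857 (10)
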